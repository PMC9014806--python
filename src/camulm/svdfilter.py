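"""Spatiotemporal SVD clutter filtering, noise equalization, and
diffraction-limited power imaging.

Tissue moves slowly and coherently across the field, so in the Casorati
matrix (space × slow-time reshaping of the frame stack) it concentrates in
the first few singular components; microbubbles, being sparse and fast,
spread across the high-order components.  Zeroing the low-order singular
values therefore suppresses tissue while retaining bubble echoes.

Casorati orientation is fixed throughout: space along rows
(n_axial·n_lateral, C order), time along columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .iq import IQEnsemble

__all__ = [
    "SingularSpectrum",
    "NoiseProfile",
    "svd_clutter_filter",
    "adaptive_cutoff",
    "estimate_noise_profile",
    "apply_noise_equalization",
    "power_doppler",
]


@dataclass
class SingularSpectrum:
    """Singular values of a Casorati matrix and the applied low-order cutoff."""

    values: np.ndarray        # descending, non-negative
    cutoff: int               # number of leading components zeroed

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12) or np.any(np.diff(self.values) > 1e-9 * self.values[0]):
            raise ValueError("singular values must be non-negative and non-increasing")
        if not (0 <= self.cutoff < len(self.values)):
            raise ValueError("cutoff must lie in [0, n_values)")


@dataclass
class NoiseProfile:
    """Per-pixel multiplicative gain normalizing expected noise power to 1."""

    gain: np.ndarray          # (n_axial, n_lateral), strictly positive

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if not np.isfinite(self.gain).all() or np.any(self.gain <= 0):
            raise ValueError("noise gains must be strictly positive and finite")


def _casorati(iq: IQEnsemble) -> np.ndarray:
    """(space, time) matrix: frames flattened C-order along rows."""
    return iq.data.reshape(iq.n_frames, -1).T


def adaptive_cutoff(singular_values: np.ndarray, bounds: tuple[int, int] = (2, 40),
                    tol: float = 1e-6) -> int:
    """Low-order cutoff at the knee of the log singular-value curve.

    The tissue components form a steep initial decay; the bubble/noise
    floor is nearly flat.  The knee is taken as the index of maximum
    discrete curvature (largest second difference) of log10 of the
    spectrum, clamped to ``bounds``.  A flat spectrum (no curvature above
    ``tol``) falls back to the lower bound with a warning.
    """
    s = np.asarray(singular_values, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 singular values")
    lo, hi = bounds
    if lo < 0 or hi < lo:
        raise ValueError("invalid cutoff bounds")
    logs = np.log10(np.maximum(s, np.finfo(float).tiny * s[0] if s[0] > 0 else 1.0))
    d2 = logs[:-2] - 2.0 * logs[1:-1] + logs[2:]  # curvature at interior index i+1
    if not np.any(np.abs(d2) > tol):
        warnings.warn("flat singular spectrum: no knee found, using minimum cutoff")
        return lo
    knee = int(np.argmax(d2)) + 1
    return int(np.clip(knee, lo, min(hi, len(s) - 1)))


def svd_clutter_filter(iq: IQEnsemble, cutoff: int | str = "adaptive",
                       bounds: tuple[int, int] = (2, 40)) -> tuple[IQEnsemble, SingularSpectrum]:
    """Zero the ``cutoff`` leading singular components of the Casorati matrix.

    ``cutoff`` may be an explicit component count or ``"adaptive"``, in
    which case :func:`adaptive_cutoff` picks the knee of the spectrum.
    ``cutoff=0`` returns the input unchanged.  The sum of squared singular
    values equals the stack's total energy (Frobenius identity), so
    filtered-out and retained energy always partition the input energy.
    """
    if iq.n_frames < 2:
        raise ValueError("SVD filtering needs at least 2 frames")
    C = _casorati(iq)
    U, s, Vh = np.linalg.svd(C, full_matrices=False)
    if cutoff == "adaptive":
        k = adaptive_cutoff(s, bounds=bounds)
    else:
        k = int(cutoff)
    if not (0 <= k < len(s)):
        raise ValueError(f"cutoff {k} out of range [0, {len(s)})")
    if k == 0:
        return iq.with_data(iq.data.copy()), SingularSpectrum(values=s, cutoff=0)
    s_f = s.copy()
    s_f[:k] = 0.0
    filtered = (U * s_f) @ Vh
    out = filtered.T.reshape(iq.data.shape)
    return iq.with_data(out), SingularSpectrum(values=s, cutoff=k)


def estimate_noise_profile(noise_iq: IQEnsemble, data_iq: IQEnsemble | None = None,
                           cutoff: int | str = "adaptive",
                           smooth_rows: int = 9) -> NoiseProfile:
    """Noise-equalization gain from a bubble-free noise reference stack.

    The reference is SVD-filtered exactly like the data, its temporal-mean
    power is computed per pixel, averaged laterally (the dominant noise
    gradient is axial), smoothed with a moving average along depth, and
    inverted: gain = 1/sqrt(power), normalizing expected noise power to 1.
    """
    if data_iq is not None and not noise_iq.same_geometry(data_iq):
        raise ValueError("noise reference geometry does not match the data")
    filtered, _ = svd_clutter_filter(noise_iq, cutoff=cutoff)
    power = np.mean(np.abs(filtered.data) ** 2, axis=0)     # (n_ax, n_lat)
    row_power = power.mean(axis=1)
    kernel = np.ones(smooth_rows) / smooth_rows
    pad = smooth_rows // 2
    padded = np.pad(row_power, pad, mode="edge")
    row_power = np.convolve(padded, kernel, mode="valid")
    if np.any(row_power <= 0):
        raise ValueError("non-positive noise power: reference stack degenerate")
    gain_rows = 1.0 / np.sqrt(row_power)
    gain = np.repeat(gain_rows[:, None], noise_iq.n_lateral, axis=1)
    return NoiseProfile(gain=gain)


def apply_noise_equalization(iq: IQEnsemble, profile: NoiseProfile) -> IQEnsemble:
    """Pixel-wise multiplication of every frame by the equalization gain."""
    if profile.gain.shape != iq.frame_shape:
        raise ValueError("profile geometry does not match the IQ stack")
    return iq.with_data(iq.data * profile.gain[None, :, :])


def power_doppler(iq: IQEnsemble) -> np.ndarray:
    """Diffraction-limited contrast power image: per-pixel sum over frames
    of the squared signal magnitude."""
    return np.sum(np.abs(iq.data) ** 2, axis=0)
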