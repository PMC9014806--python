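"""Microbubble localization on the super-resolved grid.

The clutter-filtered IQ stack is spline-interpolated onto a 5 µm grid,
optionally split into three overlapping-population subsets by a conical
Fourier-domain filter (separating bubbles by apparent axial speed), and
each frame's envelope is matched against a Gaussian PSF by normalized 2-D
cross-correlation.  Regional maxima of the correlation map above a score
threshold become sub-diffraction bubble centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline
from skimage.feature import match_template
from skimage.morphology import local_maxima

from .iq import IQEnsemble

__all__ = [
    "PSFModel",
    "upsample_iq",
    "build_psf",
    "fit_psf_sigma",
    "separate_mb_subsets",
    "localize_frame",
    "localize_stack",
]

SR_PITCH_UM = 5.0  # reconstruction pitch of the study


# ---------------------------------------------------------------------------
# spline upsampling
# ---------------------------------------------------------------------------

def upsample_iq(iq: IQEnsemble, target_pitch_um: float = SR_PITCH_UM) -> IQEnsemble:
    """Interpolate every frame onto a grid of the requested pitch.

    Uses a 2-D cubic interpolating spline (real and imaginary parts
    separately), so values at the original grid nodes are preserved
    exactly.  The target pitch must not exceed the native pitch.
    """
    if target_pitch_um > min(iq.pitch_axial_um, iq.pitch_lateral_um):
        raise ValueError("target pitch must be <= native pitch")
    if (target_pitch_um == iq.pitch_axial_um == iq.pitch_lateral_um):
        return iq.with_data(iq.data.copy())

    z = np.arange(iq.n_axial) * iq.pitch_axial_um
    x = np.arange(iq.n_lateral) * iq.pitch_lateral_um
    z_new = np.arange(0.0, z[-1] + 1e-9, target_pitch_um)
    x_new = np.arange(0.0, x[-1] + 1e-9, target_pitch_um)

    out = np.empty((iq.n_frames, len(z_new), len(x_new)), dtype=np.complex128)
    for t in range(iq.n_frames):
        sp_r = RectBivariateSpline(z, x, iq.data[t].real, kx=3, ky=3, s=0)
        sp_i = RectBivariateSpline(z, x, iq.data[t].imag, kx=3, ky=3, s=0)
        out[t] = sp_r(z_new, x_new) + 1j * sp_i(z_new, x_new)

    return IQEnsemble(
        data=out,
        pitch_axial_um=target_pitch_um,
        pitch_lateral_um=target_pitch_um,
        frame_rate_hz=iq.frame_rate_hz,
        center_freq_mhz=iq.center_freq_mhz,
    )


# ---------------------------------------------------------------------------
# PSF model
# ---------------------------------------------------------------------------

@dataclass
class PSFModel:
    """Separable Gaussian PSF rendered on the super-resolved grid.

    The kernel is truncated at ±3σ and normalized to unit peak.
    """

    sigma_axial_um: float
    sigma_lateral_um: float
    pitch_um: float
    kernel: np.ndarray

    @property
    def fwhm_axial_um(self) -> float:
        return 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.sigma_axial_um

    @property
    def fwhm_lateral_um(self) -> float:
        return 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.sigma_lateral_um


def build_psf(sigma_axial_um: float, sigma_lateral_um: float,
              pitch_um: float = SR_PITCH_UM) -> PSFModel:
    """Render the Gaussian bubble PSF on a grid of the given pitch."""
    if sigma_axial_um <= 0 or sigma_lateral_um <= 0:
        raise ValueError("PSF widths must be positive")
    if sigma_axial_um < pitch_um or sigma_lateral_um < pitch_um:
        raise ValueError("PSF width below one pixel pitch: kernel unresolvable")
    hz = int(np.ceil(3.0 * sigma_axial_um / pitch_um))
    hx = int(np.ceil(3.0 * sigma_lateral_um / pitch_um))
    gz = np.exp(-0.5 * (np.arange(-hz, hz + 1) * pitch_um / sigma_axial_um) ** 2)
    gx = np.exp(-0.5 * (np.arange(-hx, hx + 1) * pitch_um / sigma_lateral_um) ** 2)
    kernel = gz[:, None] * gx[None, :]   # peak value exactly 1 at the center
    return PSFModel(sigma_axial_um, sigma_lateral_um, pitch_um, kernel)


def fit_psf_sigma(frame_env: np.ndarray, pitch_um: float) -> tuple[float, float]:
    """Least-squares Gaussian widths of the brightest isolated blob.

    Objective stand-in for the manual per-dataset PSF adjustment: take the
    brightest pixel of the envelope frame, cut a window around it, and fit
    axial/lateral Gaussian σ by least squares on the window's marginals.
    """
    from scipy.optimize import curve_fit

    frame_env = np.asarray(frame_env, dtype=float)
    iz, ix = np.unravel_index(np.argmax(frame_env), frame_env.shape)
    h = max(4, min(frame_env.shape) // 8)
    win = frame_env[max(iz - h, 0):iz + h + 1, max(ix - h, 0):ix + h + 1]

    def gauss(u, a, mu, sigma):
        return a * np.exp(-0.5 * ((u - mu) / sigma) ** 2)

    sigmas = []
    for axis in (1, 0):
        prof = win.max(axis=axis)
        u = np.arange(len(prof)) * pitch_um
        p0 = (prof.max(), u[np.argmax(prof)], 3 * pitch_um)
        try:
            popt, _ = curve_fit(gauss, u, prof, p0=p0, maxfev=2000)
            sigmas.append(abs(popt[2]))
        except RuntimeError:
            sigmas.append(3 * pitch_um)
    return float(sigmas[0]), float(sigmas[1])


# ---------------------------------------------------------------------------
# conical Fourier subset separation
# ---------------------------------------------------------------------------

def separate_mb_subsets(iq: IQEnsemble, speed_bounds_mm_s: tuple[float, float]
                        ) -> tuple[IQEnsemble, IQEnsemble, IQEnsemble]:
    """Split the stack into slow/middle/fast apparent-speed populations.

    A 3-D FFT over (slow-time, axial, lateral) maps each voxel to a
    temporal frequency f_t (Hz) and an axial spatial frequency k_z
    (cycles/mm); the ratio |f_t| / |k_z| is an apparent axial speed in
    mm/s (a bubble moving axially at speed v puts its energy on the plane
    f_t = −v·k_z, where the ratio equals v at every lateral frequency).
    Voxels are assigned to exactly one of three cones by comparing that
    speed with the two thresholds, with the k_z = 0 plane assigned to the
    slow cone, and each cone is inverse-transformed.  The assignment is a
    partition of the spectrum, so the three subsets sum to the input
    exactly.
    """
    v1, v2 = speed_bounds_mm_s
    if not (0 < v1 < v2):
        raise ValueError("speed thresholds must be strictly increasing and positive")
    if iq.n_frames < 8:
        raise ValueError("need at least 8 frames for a usable temporal spectrum")

    F = np.fft.fftn(iq.data, axes=(0, 1, 2))
    f_t = np.fft.fftfreq(iq.n_frames, d=1.0 / iq.frame_rate_hz)          # Hz
    k_z = np.fft.fftfreq(iq.n_axial, d=iq.pitch_axial_um / 1000.0)       # cyc/mm

    with np.errstate(divide="ignore", invalid="ignore"):
        speed = np.abs(f_t)[:, None] / np.abs(k_z)[None, :]              # mm/s
    speed[:, k_z == 0] = 0.0          # k_z = 0 plane -> slow cone
    speed = np.broadcast_to(speed[:, :, None],
                            (iq.n_frames, iq.n_axial, iq.n_lateral)).copy()

    slow = speed < v1
    mid = (speed >= v1) & (speed < v2)
    fast = speed >= v2

    subsets = []
    for mask in (slow, mid, fast):
        subsets.append(iq.with_data(np.fft.ifftn(F * mask, axes=(0, 1, 2))))
    return tuple(subsets)


# ---------------------------------------------------------------------------
# per-frame localization
# ---------------------------------------------------------------------------

def localize_frame(frame: np.ndarray, psf: PSFModel, min_corr: float = 0.6,
                   min_sep_um: float | None = None, subset: int = 0) -> pd.DataFrame:
    """Centroids of one super-resolved frame.

    The frame envelope (magnitude) is matched against the PSF kernel by
    normalized cross-correlation; pixels scoring below ``min_corr`` are
    discarded; 8-connected regional maxima of the surviving map become
    centroids (a flat plateau contributes its centroid once); centroids
    closer than ``min_sep_um`` keep only the higher score.

    Returns a DataFrame with columns frame-independent columns
    ``z_um, x_um, score, subset`` (empty for an empty frame).
    """
    env = np.abs(np.asarray(frame))
    columns = ["z_um", "x_um", "score", "subset"]
    if env.size == 0 or not np.any(env > 0):
        return pd.DataFrame(columns=columns)
    if psf.kernel.shape[0] > env.shape[0] or psf.kernel.shape[1] > env.shape[1]:
        raise ValueError("PSF kernel larger than the frame")
    if min_sep_um is None:
        min_sep_um = 0.5 * min(psf.fwhm_axial_um, psf.fwhm_lateral_um)

    corr = match_template(env, psf.kernel, pad_input=True, mode="constant")
    corr = np.nan_to_num(corr, nan=-1.0)
    # the fast NCC is numerically unstable where the local window is nearly
    # constant (e.g. the empty margins of a frame): denominators underflow
    # and |scores| explode past 1.  Those pixels carry no bubble evidence;
    # invalidate them and clamp the rest to the legal score range.
    corr[np.abs(corr) > 1.0 + 1e-6] = -1.0
    win = ndimage.uniform_filter(env, size=psf.kernel.shape)
    win_sq = ndimage.uniform_filter(env ** 2, size=psf.kernel.shape)
    local_var = np.maximum(win_sq - win ** 2, 0.0)
    corr[local_var <= 1e-12 * float(env.max()) ** 2] = -1.0
    corr = np.clip(corr, -1.0, 1.0)

    peaks = local_maxima(corr, connectivity=2, allow_borders=True)
    peaks &= corr >= min_corr
    if not peaks.any():
        return pd.DataFrame(columns=columns)

    labels, n_lab = ndimage.label(peaks, structure=np.ones((3, 3), dtype=int))
    centroids = ndimage.center_of_mass(peaks, labels, range(1, n_lab + 1))
    scores = ndimage.maximum(corr, labels, range(1, n_lab + 1))

    rows = sorted(
        ((float(s), cz * psf.pitch_um, cx * psf.pitch_um) for s, (cz, cx) in zip(scores, centroids)),
        reverse=True,
    )
    kept: list[tuple[float, float, float]] = []
    for s, z_um, x_um in rows:
        if all(np.hypot(z_um - kz, x_um - kx) >= min_sep_um for _, kz, kx in kept):
            kept.append((s, z_um, x_um))

    return pd.DataFrame(
        {"z_um": [z for _, z, _ in kept],
         "x_um": [x for _, _, x in kept],
         "score": [s for s, _, _ in kept],
         "subset": subset},
    )


def localize_stack(iq: IQEnsemble, psf: PSFModel, min_corr: float = 0.6,
                   min_sep_um: float | None = None, subset: int = 0) -> pd.DataFrame:
    """Run :func:`localize_frame` over every frame of a stack.

    Returns the pooled centroid table with a ``frame`` column — the
    CentroidSet of the pipeline, written to CSV as
    ``frame, z_um, x_um, score, subset``.
    """
    tables = []
    for t in range(iq.n_frames):
        df = localize_frame(iq.data[t], psf, min_corr=min_corr,
                            min_sep_um=min_sep_um, subset=subset)
        df.insert(0, "frame", t)
        tables.append(df)
    if not tables:
        return pd.DataFrame(columns=["frame", "z_um", "x_um", "score", "subset"])
    return pd.concat(tables, ignore_index=True)
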