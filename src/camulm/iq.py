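"""Complex IQ frame-stack container and its on-disk HDF5 representation.

The in-phase/quadrature (IQ) ensemble is the transport type of the whole
pipeline: a stack of complex beamformed frames on a regular axial/lateral
grid, together with the physical metadata (pixel pitch, frame rate, center
frequency) every downstream stage needs.

Conventions used throughout the package: axial = depth, increasing
downward; lateral = width.  Physical positions are in millimetres, pixel
pitches in micrometres, and positions refer to pixel centers (pixel ``i``
is at ``i * pitch``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np

__all__ = ["IQEnsemble"]

_UM_PER_MM = 1000.0


@dataclass
class IQEnsemble:
    """Complex frame stack ``[n_frames, n_axial, n_lateral]`` with geometry.

    Parameters
    ----------
    data
        Complex array, frames along axis 0.
    pitch_axial_um, pitch_lateral_um
        Pixel pitch in micrometres (> 0).
    frame_rate_hz
        Effective (post-compounding) frame rate in Hz.
    center_freq_mhz
        Transmit center frequency in MHz (used for wavelength bookkeeping).
    """

    data: np.ndarray
    pitch_axial_um: float
    pitch_lateral_um: float
    frame_rate_hz: float
    center_freq_mhz: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D stack, got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("IQ ensemble needs at least one frame")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        if self.pitch_axial_um <= 0 or self.pitch_lateral_um <= 0:
            raise ValueError("pixel pitches must be strictly positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be strictly positive")
        if not np.isfinite(self.data).all():
            raise ValueError("IQ data must be finite")

    # -- geometry -----------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_axial(self) -> int:
        return self.data.shape[1]

    @property
    def n_lateral(self) -> int:
        return self.data.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def axial_coords_mm(self) -> np.ndarray:
        """Pixel-center depths in mm."""
        return np.arange(self.n_axial) * self.pitch_axial_um / _UM_PER_MM

    def lateral_coords_mm(self) -> np.ndarray:
        """Pixel-center lateral positions in mm."""
        return np.arange(self.n_lateral) * self.pitch_lateral_um / _UM_PER_MM

    @property
    def wavelength_um(self) -> float:
        """Acoustic wavelength in µm assuming soft-tissue sound speed 1540 m/s."""
        return 1540.0 / self.center_freq_mhz  # (1540e6 µm/s) / (f MHz * 1e6)

    def same_geometry(self, other: "IQEnsemble") -> bool:
        return (
            self.frame_shape == other.frame_shape
            and np.isclose(self.pitch_axial_um, other.pitch_axial_um)
            and np.isclose(self.pitch_lateral_um, other.pitch_lateral_um)
        )

    def with_data(self, data: np.ndarray) -> "IQEnsemble":
        """New ensemble sharing this one's metadata."""
        return replace(self, data=data)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Write to HDF5 with /iq_real, /iq_imag datasets and scalar attrs."""
        with h5py.File(path, "w") as f:
            f.create_dataset("iq_real", data=self.data.real, compression="gzip")
            f.create_dataset("iq_imag", data=self.data.imag, compression="gzip")
            f.attrs["pitch_axial_um"] = self.pitch_axial_um
            f.attrs["pitch_lateral_um"] = self.pitch_lateral_um
            f.attrs["frame_rate_hz"] = self.frame_rate_hz
            f.attrs["center_freq_mhz"] = self.center_freq_mhz

    @classmethod
    def load(cls, path) -> "IQEnsemble":
        with h5py.File(path, "r") as f:
            data = f["iq_real"][()] + 1j * f["iq_imag"][()]
            return cls(
                data=data,
                pitch_axial_um=float(f.attrs["pitch_axial_um"]),
                pitch_lateral_um=float(f.attrs["pitch_lateral_um"]),
                frame_rate_hz=float(f.attrs["frame_rate_hz"]),
                center_freq_mhz=float(f.attrs["center_freq_mhz"]),
            )
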