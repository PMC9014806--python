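"""Scene and pipeline configuration.

``SceneConfig`` defaults reproduce the acquisition geometry of the CAM
(chorioallantoic membrane) tumor study the package emulates: a ~2.93 mm
deep × 8.82 mm wide field imaged at 20 MHz with a post-compounding
effective frame rate of 1000 Hz, in acquisitions of 1600 frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["SceneConfig"]


@dataclass
class SceneConfig:
    """Parameters of the synthetic tumor-microvasculature scene.

    Attributes
    ----------
    field_depth_mm, field_width_mm
        Physical field of view (axial × lateral), mm.
    pitch_axial_um, pitch_lateral_um
        Native beamforming grid pitch, µm.  Default is λ/2 at 20 MHz
        (λ ≈ 77 µm in soft tissue).
    frame_rate_hz
        Effective frame rate after angle compounding (emulated), Hz.
    n_frames
        Frames per acquisition.
    center_freq_mhz
        Transmit center frequency, MHz.
    morphology
        Vessel-network preset: ``"chaotic"`` (tortuous tumor-like tree),
        ``"columnar"`` (straight columns rising from the membrane), or
        ``"pruned"`` (chaotic tree with an avascular region carved out,
        emulating anti-angiogenic vascular disruption).
    branching_depth, children_per_node
        Tree generations below the root and branches spawned per tip.
    root_radius_um, radius_decay
        Root vessel radius and per-generation multiplicative decay.
    root_speed_mm_s, speed_decay
        Root flow speed and per-generation decay.
    n_bubbles
        Simultaneously circulating microbubbles.
    mb_amplitude_sigma_ln
        Log-normal sigma of the per-bubble echo amplitude (median 1).
    psf_sigma_axial_um, psf_sigma_lateral_um
        Gaussian point-spread-function standard deviations, µm.
    clutter_rank
        Number of spatiotemporal tissue-clutter modes.  Default 15: an SVD
        filter on in vivo CAM-tumor ensembles typically removes the first
        10–20 singular values, so the emulated tissue occupies that range.
    clutter_to_mb_db
        Tissue clutter power above microbubble power, dB (≥ 20 in vivo).
    clutter_max_freq_hz
        Fastest tissue-motion temporal frequency (slow, < 20 Hz).
    noise_sigma
        Complex noise standard deviation at zero depth (0 disables noise).
    noise_depth_tau_mm
        Depth constant τ of the noise law  variance ∝ exp(depth / τ),
        emulating depth-dependent electronic/thermal noise gain.
    seed
        RNG seed; every generator is deterministic given the seed.
    """

    field_depth_mm: float = 2.93
    field_width_mm: float = 8.82
    pitch_axial_um: float = 38.5
    pitch_lateral_um: float = 38.5
    frame_rate_hz: float = 1000.0
    n_frames: int = 1600
    center_freq_mhz: float = 20.0

    morphology: str = "chaotic"
    branching_depth: int = 3
    children_per_node: int = 2
    root_radius_um: float = 60.0
    radius_decay: float = 0.7
    root_speed_mm_s: float = 4.0
    speed_decay: float = 0.8

    n_bubbles: int = 50
    mb_amplitude_sigma_ln: float = 0.5
    psf_sigma_axial_um: float = 40.0
    psf_sigma_lateral_um: float = 50.0

    clutter_rank: int = 15
    clutter_to_mb_db: float = 30.0
    clutter_max_freq_hz: float = 15.0

    noise_sigma: float = 0.0
    noise_depth_tau_mm: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_depth_mm <= 0 or self.field_width_mm <= 0:
            raise ValueError("field size must be positive")
        if self.pitch_axial_um <= 0 or self.pitch_lateral_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.branching_depth < 0:
            raise ValueError("branching depth must be >= 0")
        if self.morphology not in ("chaotic", "columnar", "pruned"):
            raise ValueError(f"unknown morphology preset {self.morphology!r}")

    @property
    def n_axial(self) -> int:
        return int(round(self.field_depth_mm * 1000.0 / self.pitch_axial_um)) + 1

    @property
    def n_lateral(self) -> int:
        return int(round(self.field_width_mm * 1000.0 / self.pitch_lateral_um)) + 1

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent generator for a named sub-stream of the scene seed."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)
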