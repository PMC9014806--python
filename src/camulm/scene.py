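"""Synthetic tumor-microvasculature scenes: vessel trees, microbubble
trajectories, and realistic complex IQ ensembles.

The generator emulates a CAM (chorioallantoic membrane) tumor acquisition:
a branching vessel network rooted at the membrane edge of the field,
microbubbles advected through it, each rendered as a complex Gaussian
point-spread function on the native beamforming grid, summed with low-rank
slowly-moving tissue clutter and depth-dependent complex Gaussian noise.
Every stage keeps its ground truth, so downstream filtering, localization,
tracking and metric code can be tested against known answers without any
acquisition hardware.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import SceneConfig
from .iq import IQEnsemble

__all__ = [
    "VesselNetwork",
    "MBTrajectorySet",
    "IQScene",
    "generate_vessel_network",
    "simulate_mb_trajectories",
    "synthesize_iq",
]

_UM_PER_MM = 1000.0


# ---------------------------------------------------------------------------
# vessel network
# ---------------------------------------------------------------------------

@dataclass
class VesselNetwork:
    """Ground-truth vessel tree.

    ``segments[i]`` is an ``(n_pts, 2)`` polyline of ``(z_mm, x_mm)``
    centerline points; ``parent[i]`` is the index of the parent segment
    (−1 for the root).  Each child's first point coincides with its
    parent's last point.
    """

    segments: list  # list of (n_pts, 2) float arrays, (z_mm, x_mm)
    radius_um: np.ndarray
    speed_mm_s: np.ndarray
    parent: np.ndarray

    def __post_init__(self) -> None:
        self.radius_um = np.asarray(self.radius_um, dtype=float)
        self.speed_mm_s = np.asarray(self.speed_mm_s, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        if len(self.segments) == 0:
            raise ValueError("vessel network must contain at least one segment")
        if np.any(self.radius_um <= 0) or np.any(self.speed_mm_s <= 0):
            raise ValueError("radii and speeds must be strictly positive")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def children_of(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.parent == i)

    def leaves(self) -> np.ndarray:
        has_child = np.zeros(self.n_segments, dtype=bool)
        has_child[self.parent[self.parent >= 0]] = True
        return np.flatnonzero(~has_child)

    def segment_length_mm(self, i: int) -> float:
        pts = self.segments[i]
        return float(np.sum(np.hypot(*(np.diff(pts, axis=0).T))))

    def root_to_leaf_path(self, leaf: int) -> list[int]:
        """Segment indices from the root down to ``leaf``."""
        chain = [int(leaf)]
        while self.parent[chain[-1]] >= 0:
            chain.append(int(self.parent[chain[-1]]))
        return chain[::-1]

    def to_json(self, path) -> None:
        obj = {
            "segments": [s.tolist() for s in self.segments],
            "radius_um": self.radius_um.tolist(),
            "speed_mm_s": self.speed_mm_s.tolist(),
            "parent": self.parent.tolist(),
        }
        with open(path, "w") as f:
            json.dump(obj, f)

    @classmethod
    def from_json(cls, path) -> "VesselNetwork":
        with open(path) as f:
            obj = json.load(f)
        return cls(
            segments=[np.asarray(s, dtype=float) for s in obj["segments"]],
            radius_um=np.asarray(obj["radius_um"]),
            speed_mm_s=np.asarray(obj["speed_mm_s"]),
            parent=np.asarray(obj["parent"]),
        )


def _steer_inside(p: np.ndarray, heading: float, step: float,
                  z_lim: tuple[float, float], x_lim: tuple[float, float]) -> tuple[np.ndarray, float]:
    """One polyline step; reflect the heading off the field margins.

    Heading convention: direction = (cos h, sin h) in (z, x).  Reflecting
    the axial component maps h -> pi - h; the lateral component h -> -h.
    """
    q = p + step * np.array([np.cos(heading), np.sin(heading)])
    if q[0] < z_lim[0] or q[0] > z_lim[1]:
        heading = np.pi - heading
        q = p + step * np.array([np.cos(heading), np.sin(heading)])
    if q[1] < x_lim[0] or q[1] > x_lim[1]:
        heading = -heading
        q = p + step * np.array([np.cos(heading), np.sin(heading)])
    q[0] = np.clip(q[0], z_lim[0], z_lim[1])
    q[1] = np.clip(q[1], x_lim[0], x_lim[1])
    return q, heading


def generate_vessel_network(config: SceneConfig) -> VesselNetwork:
    """Grow a branching vessel tree rooted at the membrane (bottom) edge.

    Presets: ``chaotic`` adds heading jitter at every polyline step
    (tortuous tumor vasculature), ``columnar`` grows near-straight columns
    rising from the membrane, and ``pruned`` carves an avascular region out
    of a chaotic tree by dropping the subtrees that enter it, emulating
    treatment-induced vascular disruption.

    Deterministic given ``config.seed``.  Raises ``ValueError`` when the
    requested tree cannot fit the field.
    """
    rng = config.rng(stream=1)
    depth_mm, width_mm = config.field_depth_mm, config.field_width_mm

    n_leaves = config.children_per_node ** config.branching_depth if config.children_per_node > 0 else 1
    if n_leaves * 4.0 * config.root_radius_um / _UM_PER_MM > width_mm:
        raise ValueError("infeasible geometry: requested vessels cannot fit the field")

    margin = 0.03 * min(depth_mm, width_mm)
    z_lim = (margin, depth_mm - margin)
    x_lim = (margin, width_mm - margin)

    if config.morphology == "columnar":
        jitter, spread = 0.02, 0.25
    else:
        jitter, spread = 0.25, 0.9

    root_len = 0.30 * depth_mm
    n_pts_per_seg = 12

    segments: list[np.ndarray] = []
    radius: list[float] = []
    speed: list[float] = []
    parent: list[int] = []

    def grow(start: np.ndarray, heading: float, gen: int, parent_idx: int) -> None:
        length = root_len * (0.75 ** gen)
        step = length / (n_pts_per_seg - 1)
        pts = [start.copy()]
        h = heading
        for _ in range(n_pts_per_seg - 1):
            h += rng.normal(0.0, jitter)
            q, h = _steer_inside(pts[-1], h, step, z_lim, x_lim)
            pts.append(q)
        idx = len(segments)
        segments.append(np.asarray(pts))
        radius.append(config.root_radius_um * config.radius_decay ** gen)
        speed.append(config.root_speed_mm_s * config.speed_decay ** gen)
        parent.append(parent_idx)
        if gen < config.branching_depth:
            offsets = np.linspace(-spread, spread, config.children_per_node) if config.children_per_node > 1 else [0.0]
            for off in offsets:
                grow(segments[idx][-1], h + off + rng.normal(0.0, jitter), gen + 1, idx)

    # membrane edge = maximum depth; the tree grows upward (heading pi -> -z)
    root_start = np.array([z_lim[1], width_mm / 2.0])
    grow(root_start, np.pi, 0, -1)

    net = VesselNetwork(
        segments=segments,
        radius_um=np.array(radius),
        speed_mm_s=np.array(speed),
        parent=np.array(parent),
    )

    if config.morphology == "pruned":
        net = _carve_avascular_region(net, config)
    return net


def _carve_avascular_region(net: VesselNetwork, config: SceneConfig) -> VesselNetwork:
    """Drop subtrees whose segment midpoint enters an avascular disc."""
    center = np.array([0.35 * config.field_depth_mm, 0.35 * config.field_width_mm])
    r_av = 0.22 * min(config.field_depth_mm, config.field_width_mm)

    doomed = np.zeros(net.n_segments, dtype=bool)
    for i in range(1, net.n_segments):  # never prune the root
        mid = net.segments[i][len(net.segments[i]) // 2]
        if np.hypot(*(mid - center)) < r_av:
            doomed[i] = True
    # propagate to descendants
    changed = True
    while changed:
        changed = False
        for i in range(net.n_segments):
            p = net.parent[i]
            if p >= 0 and doomed[p] and not doomed[i]:
                doomed[i] = True
                changed = True
    keep = np.flatnonzero(~doomed)
    remap = {int(old): new for new, old in enumerate(keep)}
    return VesselNetwork(
        segments=[net.segments[i] for i in keep],
        radius_um=net.radius_um[keep],
        speed_mm_s=net.speed_mm_s[keep],
        parent=np.array([remap.get(int(net.parent[i]), -1) for i in keep]),
    )


# ---------------------------------------------------------------------------
# microbubble trajectories
# ---------------------------------------------------------------------------

@dataclass
class MBTrajectorySet:
    """Per-bubble ground-truth positions.

    ``positions[b, t]`` is ``(z_mm, x_mm)`` of bubble ``b`` at frame ``t``.
    All bubbles recirculate, so every bubble is alive on every frame
    (``birth[b] == 0``, ``death[b] == n_frames``); the fields are kept for
    generality.
    """

    positions: np.ndarray       # (n_bubbles, n_frames, 2)
    amplitude: np.ndarray       # (n_bubbles,)
    birth: np.ndarray           # (n_bubbles,)
    death: np.ndarray           # (n_bubbles,)

    @property
    def n_bubbles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def alive_mask(self) -> np.ndarray:
        t = np.arange(self.n_frames)[None, :]
        return (t >= self.birth[:, None]) & (t < self.death[:, None])

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = []
        for b in range(self.n_bubbles):
            for t in range(self.n_frames):
                rows.append((b, t, self.positions[b, t, 0], self.positions[b, t, 1]))
        pd.DataFrame(rows, columns=["bubble_id", "frame", "z_mm", "x_mm"]).to_csv(path, index=False)


def _path_geometry(net: VesselNetwork, chain: list[int]):
    """Concatenate a root-to-leaf chain into arc-length parametrized arrays."""
    pts, seg_of = [], []
    for si in chain:
        seg = net.segments[si]
        start = 1 if pts else 0  # child start duplicates parent end
        for p in seg[start:]:
            pts.append(p)
            seg_of.append(si)
    pts = np.asarray(pts)
    d = np.hypot(*(np.diff(pts, axis=0).T))
    s = np.concatenate([[0.0], np.cumsum(d)])
    return pts, np.asarray(seg_of), s


def simulate_mb_trajectories(net: VesselNetwork, config: SceneConfig) -> MBTrajectorySet:
    """Advect microbubbles along root-to-leaf centerlines.

    Each bubble follows a randomly chosen root-to-leaf path at the local
    segment speed, offset from the centerline by a fixed perpendicular
    fraction of the local radius (so every position stays inside the vessel
    tube), and re-enters at the root on exit — recirculation keeps the
    circulating count constant, as in a CAM bolus that stays in circulation
    far longer than one acquisition.
    """
    if config.frame_rate_hz <= 0:
        raise ValueError("frame rate must be strictly positive")
    rng = config.rng(stream=2)
    leaves = net.leaves()
    dt = 1.0 / config.frame_rate_hz

    n_b, n_f = config.n_bubbles, config.n_frames
    positions = np.zeros((n_b, n_f, 2))
    amplitude = np.exp(rng.normal(0.0, config.mb_amplitude_sigma_ln, size=n_b))

    for b in range(n_b):
        u = rng.uniform(-0.9, 0.9)  # fixed radial offset fraction
        pts, seg_of, s = _path_geometry(net, net.root_to_leaf_path(int(rng.choice(leaves))))
        total = s[-1]
        pos = rng.uniform(0.0, total)  # steady-state: random initial arc position
        for t in range(n_f):
            k = min(int(np.searchsorted(s, pos, side="right")) - 1, len(s) - 2)
            k = max(k, 0)
            frac = (pos - s[k]) / max(s[k + 1] - s[k], 1e-12)
            p = pts[k] + frac * (pts[k + 1] - pts[k])
            tang = pts[k + 1] - pts[k]
            tang = tang / max(np.hypot(*tang), 1e-12)
            normal = np.array([-tang[1], tang[0]])
            r_mm = net.radius_um[seg_of[k]] / _UM_PER_MM
            positions[b, t] = p + u * r_mm * normal
            pos += net.speed_mm_s[seg_of[k]] * dt
            if pos >= total:  # recirculate through a fresh leaf path
                overshoot = pos - total
                pts, seg_of, s = _path_geometry(net, net.root_to_leaf_path(int(rng.choice(leaves))))
                total = s[-1]
                pos = overshoot % total

    return MBTrajectorySet(
        positions=positions,
        amplitude=amplitude,
        birth=np.zeros(n_b, dtype=int),
        death=np.full(n_b, n_f, dtype=int),
    )


# ---------------------------------------------------------------------------
# IQ synthesis
# ---------------------------------------------------------------------------

@dataclass
class IQScene:
    """A rendered acquisition plus its ground-truth components."""

    iq: IQEnsemble
    bubbles_only: IQEnsemble
    clutter_only: IQEnsemble
    noise_only: IQEnsemble
    trajectories: MBTrajectorySet
    network: VesselNetwork | None = None


def _render_bubbles(traj: MBTrajectorySet, config: SceneConfig, rng) -> np.ndarray:
    n_ax, n_lat = config.n_axial, config.n_lateral
    stack = np.zeros((config.n_frames, n_ax, n_lat), dtype=np.complex128)
    sz = config.psf_sigma_axial_um / _UM_PER_MM
    sx = config.psf_sigma_lateral_um / _UM_PER_MM
    pz = config.pitch_axial_um / _UM_PER_MM
    px = config.pitch_lateral_um / _UM_PER_MM
    phase = np.exp(1j * rng.uniform(0.0, 2 * np.pi, size=traj.n_bubbles))
    alive = traj.alive_mask()
    hw_z = int(np.ceil(4 * sz / pz))
    hw_x = int(np.ceil(4 * sx / px))
    for b in range(traj.n_bubbles):
        amp = traj.amplitude[b] * phase[b]
        for t in range(traj.n_frames):
            if not alive[b, t]:
                continue
            z, x = traj.positions[b, t]
            iz, ix = int(round(z / pz)), int(round(x / px))
            z0, z1 = max(iz - hw_z, 0), min(iz + hw_z + 1, n_ax)
            x0, x1 = max(ix - hw_x, 0), min(ix + hw_x + 1, n_lat)
            if z0 >= z1 or x0 >= x1:
                continue
            gz = np.exp(-0.5 * ((np.arange(z0, z1) * pz - z) / sz) ** 2)
            gx = np.exp(-0.5 * ((np.arange(x0, x1) * px - x) / sx) ** 2)
            stack[t, z0:z1, x0:x1] += amp * gz[:, None] * gx[None, :]
    return stack


def _render_clutter(config: SceneConfig, rng, target_power: float) -> np.ndarray:
    """Exact rank-``clutter_rank`` spatiotemporal tissue process.

    Smooth random spatial fields (Gaussian-filtered noise) are
    orthonormalized across pixels, slow complex sinusoids (0.5 Hz up to
    ``clutter_max_freq_hz``) are orthonormalized across frames, and the
    two are combined with geometrically decaying weights — so the Casorati
    matrix of the clutter has exactly those weights as its singular values
    and a clean knee at the configured rank.
    """
    n_f, n_ax, n_lat = config.n_frames, config.n_axial, config.n_lateral
    rank = config.clutter_rank
    t = np.arange(n_f) / config.frame_rate_hz

    fields = np.stack([
        gaussian_filter(rng.standard_normal((n_ax, n_lat)),
                        sigma=(max(n_ax / 16, 1), max(n_lat / 16, 1))).ravel()
        for _ in range(rank)
    ], axis=1)                                            # (n_pix, rank)
    U, _ = np.linalg.qr(fields)                           # orthonormal smooth modes

    freqs = np.linspace(0.5, config.clutter_max_freq_hz, rank)
    V = np.stack([np.exp(2j * np.pi * f * t) for f in freqs], axis=1)  # (n_f, rank)
    V, _ = np.linalg.qr(V)

    weights = 0.8 ** np.arange(rank)
    casorati = (U * weights) @ V.conj().T                 # (n_pix, n_f)
    stack = casorati.T.reshape(n_f, n_ax, n_lat)
    power = np.mean(np.abs(stack) ** 2)
    if power > 0:
        stack *= np.sqrt(target_power / power)
    return stack


def synthesize_iq(traj: MBTrajectorySet, network: VesselNetwork | None,
                  config: SceneConfig) -> IQScene:
    """Render trajectories into a complex IQ ensemble.

    Each bubble becomes a separable complex Gaussian PSF at its sub-pixel
    position (constant random phase per bubble); tissue clutter is an exact
    rank-``clutter_rank`` spatiotemporal process ``clutter_to_mb_db`` above
    the bubble power; complex Gaussian noise follows the depth law
    ``var ∝ exp(depth / noise_depth_tau_mm)``.  Ground-truth component
    stacks are retained on the returned :class:`IQScene`.
    """
    if (config.psf_sigma_axial_um < config.pitch_axial_um
            or config.psf_sigma_lateral_um < config.pitch_lateral_um):
        raise ValueError("PSF width below one pixel pitch: unresolvable rendering")
    rng = config.rng(stream=3)

    bubbles = _render_bubbles(traj, config, rng)
    mb_power = float(np.mean(np.abs(bubbles) ** 2))

    if config.clutter_rank > 0:
        ref = mb_power if mb_power > 0 else 1.0
        clutter = _render_clutter(config, rng, ref * 10 ** (config.clutter_to_mb_db / 10.0))
    else:
        clutter = np.zeros_like(bubbles)

    if config.noise_sigma > 0:
        depth = np.arange(config.n_axial) * config.pitch_axial_um / _UM_PER_MM
        sigma_z = config.noise_sigma * np.exp(depth / (2.0 * config.noise_depth_tau_mm))
        noise = (rng.standard_normal(bubbles.shape) + 1j * rng.standard_normal(bubbles.shape))
        noise *= sigma_z[None, :, None] / np.sqrt(2.0)
    else:
        noise = np.zeros_like(bubbles)

    meta = dict(
        pitch_axial_um=config.pitch_axial_um,
        pitch_lateral_um=config.pitch_lateral_um,
        frame_rate_hz=config.frame_rate_hz,
        center_freq_mhz=config.center_freq_mhz,
    )
    return IQScene(
        iq=IQEnsemble(bubbles + clutter + noise, **meta),
        bubbles_only=IQEnsemble(bubbles, **meta),
        clutter_only=IQEnsemble(clutter, **meta),
        noise_only=IQEnsemble(noise, **meta),
        trajectories=traj,
        network=network,
    )


def two_vessel_demo_scene(config: SceneConfig, separation_um: float = 50.0,
                          speed_mm_s: float = 2.0, n_per_vessel: int = 2) -> IQScene:
    """Deterministic two-parallel-vessel scene for the resolution benchmark.

    Two straight vertical vessels ``separation_um`` apart carry bubbles
    flowing axially at ``speed_mm_s``, staggered along the vessel so no
    two bubbles are ever within a PSF width of each other — each frame
    then contains only isolated bubbles, and the vessels are resolvable
    by localization over time even though their separation is below the
    diffraction limit (their echoes merge in any single frame and in the
    accumulated power image).
    """
    x_c = config.field_width_mm / 2.0
    x_pos = [x_c - separation_um / 2000.0, x_c + separation_um / 2000.0]
    z0, z1 = 0.15 * config.field_depth_mm, 0.85 * config.field_depth_mm
    span = z1 - z0
    dt = 1.0 / config.frame_rate_hz
    t = np.arange(config.n_frames)

    n_b = 2 * n_per_vessel
    positions = np.zeros((n_b, config.n_frames, 2))
    b = 0
    for v in range(2):
        for j in range(n_per_vessel):
            # stagger phases so simultaneous bubbles stay far apart axially
            phase = (j / n_per_vessel + v / (2 * n_per_vessel)) * span
            z = z0 + (phase + speed_mm_s * dt * t) % span
            positions[b, :, 0] = z
            positions[b, :, 1] = x_pos[v]
            b += 1
    traj = MBTrajectorySet(
        positions=positions,
        amplitude=np.ones(n_b),
        birth=np.zeros(n_b, dtype=int),
        death=np.full(n_b, config.n_frames, dtype=int),
    )
    return synthesize_iq(traj, None, config)


def synthesize_noise_reference(config: SceneConfig) -> IQEnsemble:
    """Bubble- and clutter-free acquisition of the same geometry: pure
    depth-law noise, as recorded for noise-equalization references."""
    cfg = SceneConfig.from_dict({**config.to_dict(), "clutter_rank": 0, "n_bubbles": 0})
    if cfg.noise_sigma <= 0:
        raise ValueError("noise reference requires noise_sigma > 0")
    empty = MBTrajectorySet(
        positions=np.zeros((0, cfg.n_frames, 2)),
        amplitude=np.zeros(0),
        birth=np.zeros(0, dtype=int),
        death=np.zeros(0, dtype=int),
    )
    return synthesize_iq(empty, None, cfg).iq
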