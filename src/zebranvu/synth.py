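"""Synthetic swim trajectories, calcium traces and tectum-like image stacks.

Every generator is a pure function of its parameter object (which carries the
seed), and returns the ground truth alongside the data so downstream stages
can be tested by parameter recovery rather than against unavailable
recordings.

The trajectory model is a correlated random walk in a half-darkened circular
well: a three-state continuous-time Markov chain (inactive / low / high
locomotor regimes, speeds inside the tracker's class bands) drives step
length, heading evolves by wrapped-normal turns with a thigmotactic pull
toward the wall, and divider crossings are accepted with side-dependent
probabilities tuned so the long-run light occupancy approximates ``p_light``.
Treatment presets encode only effect *directions*; their magnitudes are
package defaults and deliberately arbitrary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .io import ImageStack, Trajectory, TreatmentGroup, WellGeometry

__all__ = [
    "BehaviourParams",
    "CalciumParams",
    "StackParams",
    "TrajectoryTruth",
    "StackTruth",
    "simulate_trajectory",
    "simulate_cohort",
    "group_presets",
    "simulate_calcium_trace",
    "simulate_tectum_stack",
    "default_polylines",
]

SPEED_BANDS = (3.3, 6.4)  # mm/s class edges: inactive < 3.3 <= low < 6.4 <= high


def _default_rates() -> np.ndarray:
    # generator matrix (rows sum to zero): mostly-inactive beat-and-glide style
    # occupancy with sub-second bursts of low/high speed swimming
    return np.array(
        [
            [-0.15, 0.105, 0.045],
            [0.30, -0.50, 0.20],
            [0.40, 0.40, -0.80],
        ]
    )


@dataclass
class BehaviourParams:
    """Parameters of the synthetic free-swimming larva.

    ``p_light`` is the target long-run fraction of time on the light side;
    ``state_rates`` the 3x3 transition-rate matrix over (inactive, low, high);
    ``speed_means`` per-state speeds in mm/s, each inside its class band;
    ``heading_persistence`` κ (turn variance 1/κ rad²); ``wall_attraction``
    the thigmotactic heading drift (rad/s at the wall); ``crossing_bias``
    scales the divider-crossing asymmetry (+inf pins the larva to its side).
    """

    p_light: float = 0.8
    state_rates: np.ndarray = field(default_factory=_default_rates)
    speed_means: tuple[float, float, float] = (1.0, 4.8, 9.0)
    heading_persistence: float = 4.0
    wall_attraction: float = 1.0
    crossing_bias: float = 1.0
    duration: float = 3600.0
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.state_rates = np.asarray(self.state_rates, dtype=float)
        if not 0.0 <= self.p_light <= 1.0:
            raise ValueError("p_light must lie in [0, 1]")
        if self.state_rates.shape != (3, 3):
            raise ValueError("state_rates must be 3x3")
        if not np.allclose(self.state_rates.sum(axis=1), 0.0, atol=1e-9):
            raise ValueError("state_rates rows must sum to zero")
        if np.any(self.state_rates - np.diag(np.diag(self.state_rates)) < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        lo, hi = SPEED_BANDS
        s = self.speed_means
        if not (s[0] < s[1] < s[2]):
            raise ValueError("speed_means must be sorted ascending")
        if not (s[0] < lo and lo <= s[1] < hi and s[2] >= hi):
            raise ValueError(f"speed_means must lie inside the class bands (<{lo}, [{lo},{hi}), >={hi})")
        if self.heading_persistence < 0 or self.wall_attraction < 0:
            raise ValueError("heading_persistence and wall_attraction must be >= 0")
        if self.dt <= 0 or self.dt > 1.0:
            raise ValueError("dt must lie in (0, 1] s")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BehaviourParams):
            return NotImplemented
        self_d, other_d = vars(self).copy(), vars(other).copy()
        return np.array_equal(self_d.pop("state_rates"), other_d.pop("state_rates")) and (
            self_d == other_d
        )

    def stationary_states(self) -> np.ndarray:
        """Stationary distribution of the locomotor chain (left null vector of Q)."""
        w, v = np.linalg.eig(self.state_rates.T)
        k = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, k])
        return pi / pi.sum()


@dataclass
class TrajectoryTruth:
    """Latent variables of one simulated larva."""

    states: np.ndarray  # per-interval locomotor state index (0/1/2)
    zones: np.ndarray  # per-point zone label ('light'/'dark')
    transitions: int


def simulate_trajectory(
    params: BehaviourParams, well: WellGeometry = WellGeometry()
) -> tuple[Trajectory, TrajectoryTruth]:
    """Simulate one larva; returns the trajectory and every latent variable.

    The larva starts on the light side (as in the assay, where larvae are
    placed on the light half).  Wall contacts reflect specularly; rejected
    divider crossings reflect off the divider.
    """
    rng = np.random.default_rng(params.seed)
    n_steps = int(round(params.duration / params.dt))
    if n_steps < 1:
        raise ValueError("duration shorter than one step")
    P = expm(params.state_rates * params.dt)
    cumP = np.cumsum(P, axis=1)

    # pre-drawn randomness; the stepping loop itself is deterministic
    u_state = rng.random(n_steps)
    turn_sd = math.sqrt(1.0 / params.heading_persistence) if params.heading_persistence > 0 else math.pi
    turns = rng.normal(0.0, turn_sd, n_steps)
    u_cross = rng.random(n_steps)

    if params.crossing_bias == math.inf:
        acc_dark, acc_light = 0.0, 1.0
    else:
        acc_dark = min(1.0, (1.0 - params.p_light) / max(params.crossing_bias, 1e-12))
        acc_light = min(1.0, params.p_light * params.crossing_bias)

    cx, cy = well.centre
    nx_, ny_ = well.divider_normal
    R = well.radius
    margin = 0.5  # mm standoff so read-back tolerance is never an issue

    # start on the light side, uniformly in the half-disc
    while True:
        px, py = rng.uniform(-R, R, 2)
        if px * px + py * py <= (R - margin) ** 2 and px * nx_ + py * ny_ <= 0:
            break
    px, py = px + cx, py + cy
    heading = rng.uniform(-math.pi, math.pi)

    x = np.empty(n_steps + 1)
    y = np.empty(n_steps + 1)
    states = np.empty(n_steps, dtype=np.int8)
    x[0], y[0] = px, py
    state = int(np.searchsorted(np.cumsum(params.stationary_states()), rng.random()))
    speeds = params.speed_means
    wall = params.wall_attraction * params.dt
    Rm = R - margin

    for i in range(n_steps):
        state = int(np.searchsorted(cumP[state], u_state[i]))
        states[i] = state
        # thigmotactic drift: pull heading toward the outward radial direction
        rx, ry = px - cx, py - cy
        r = math.hypot(rx, ry)
        if wall > 0 and r > 1e-9:
            out_angle = math.atan2(ry, rx)
            heading += wall * (r / R) ** 2 * math.sin(out_angle - heading)
        heading += turns[i]
        step = speeds[state] * params.dt
        qx = px + step * math.cos(heading)
        qy = py + step * math.sin(heading)
        # divider crossing: side-dependent acceptance
        s_old = (px - cx) * nx_ + (py - cy) * ny_
        s_new = (qx - cx) * nx_ + (qy - cy) * ny_
        if s_old <= 0 < s_new:  # light -> dark attempt
            if u_cross[i] >= acc_dark:
                qx -= 2.0 * s_new * nx_
                qy -= 2.0 * s_new * ny_
        elif s_new <= 0 < s_old:  # dark -> light attempt
            if u_cross[i] >= acc_light:
                qx -= 2.0 * s_new * nx_
                qy -= 2.0 * s_new * ny_
        # wall: radial specular reflection
        rx, ry = qx - cx, qy - cy
        r = math.hypot(rx, ry)
        if r > Rm:
            scale = (2.0 * Rm - r) / r
            qx = cx + rx * scale
            qy = cy + ry * scale
        heading = math.atan2(qy - py, qx - px) if (qx != px or qy != py) else heading
        px, py = qx, qy
        x[i + 1], y[i + 1] = px, py

    t = np.arange(n_steps + 1) * params.dt
    traj = Trajectory(larva_id=f"sim-{params.seed}", t=t, x=x, y=y)
    s = (x - cx) * nx_ + (y - cy) * ny_
    zones = np.where(s > 0, "dark", "light")
    transitions = int(np.sum(zones[1:] != zones[:-1]))
    return traj, TrajectoryTruth(states=states, zones=zones, transitions=transitions)


def group_presets(effect: str) -> BehaviourParams:
    """Behaviour parameters for one treatment arm.

    ``control`` (mannitol), ``mannitol_snp`` and ``glucose_snp`` share the
    baseline (SNP fully rescues the glucose phenotype); ``glucose`` lowers
    light preference, doubles activation out of inactivity and strengthens
    thigmotaxis.  Directions mirror the reported phenotype; magnitudes are
    arbitrary package defaults.
    """
    base = BehaviourParams()
    if effect in ("control", "mannitol", "mannitol_snp", "glucose_snp"):
        return base
    if effect == "glucose":
        rates = _default_rates()
        rates[0] *= 2.0  # leave the inactive state twice as readily
        return replace(base, p_light=0.6, state_rates=rates, wall_attraction=3.0)
    raise ValueError(f"unknown treatment preset {effect!r}")


_PRESET_GROUPS = {
    "control": TreatmentGroup("mannitol", False),
    "mannitol": TreatmentGroup("mannitol", False),
    "mannitol_snp": TreatmentGroup("mannitol", True),
    "glucose": TreatmentGroup("glucose", False),
    "glucose_snp": TreatmentGroup("glucose", True),
}


def simulate_cohort(
    effect: str,
    n: int,
    base_seed: int = 0,
    well: WellGeometry = WellGeometry(),
    duration: float | None = None,
    dt: float | None = None,
) -> list[tuple[Trajectory, TrajectoryTruth]]:
    """Simulate ``n`` larvae of one arm with per-larva seeds ``base_seed + i``."""
    params = group_presets(effect)
    if duration is not None:
        params = replace(params, duration=duration)
    if dt is not None:
        params = replace(params, dt=dt)
    group = _PRESET_GROUPS[effect]
    out = []
    for i in range(n):
        traj, truth = simulate_trajectory(replace(params, seed=base_seed + i), well)
        traj.larva_id = f"{effect}-{i:03d}"
        traj.group = group
        out.append((traj, truth))
    return out


# --- calcium traces ---------------------------------------------------------


@dataclass
class CalciumParams:
    """Poisson-timed exponential-decay transients over a drifting baseline.

    ``amplitude`` is in ΔF/F₀ units (the transient adds amplitude·baseline to
    F); ``noise_sd`` and ``drift_amplitude`` are in raw fluorescence units.
    """

    rate: float = 0.05  # events/s (3 events/min)
    tau_decay: float = 2.0  # s
    amplitude: float = 0.3  # ΔF/F₀
    baseline: float = 100.0  # a.u.
    drift_amplitude: float = 2.0  # a.u.
    noise_sd: float = 1.0  # a.u.
    duration: float = 300.0  # s
    dt: float = 0.2  # s (5 Hz single-plane acquisition)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau_decay", "amplitude", "baseline", "duration", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rate < 0 or self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("rate, noise_sd, drift_amplitude must be >= 0")


def simulate_calcium_trace(
    params: CalciumParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return ``(t, F, event_times)`` for one synthetic fluorescence trace.

    F(t) = baseline + slow sinusoidal drift + Σ_k amplitude·baseline·
    exp(-(t - t_k)/τ)·1[t >= t_k] + Gaussian noise; event times are a
    homogeneous Poisson process of the given rate.  The drift period is fixed
    to duration/3 so it is slow relative to the transients.
    """
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, params.duration, params.dt)
    n_events = rng.poisson(params.rate * params.duration)
    event_times = np.sort(rng.uniform(0.0, params.duration, n_events))
    F = params.baseline + params.drift_amplitude * np.sin(
        2.0 * math.pi * t / (params.duration / 3.0)
    )
    for tk in event_times:
        mask = t >= tk
        F[mask] += params.amplitude * params.baseline * np.exp(-(t[mask] - tk) / params.tau_decay)
    if params.noise_sd > 0:
        F = F + rng.normal(0.0, params.noise_sd, t.shape)
    return t, F, event_times


# --- tectum-like image stacks ----------------------------------------------


def default_polylines(shape: tuple[int, int, int], voxel_size: tuple[float, float, float],
                      radius: float = 3.0) -> list[tuple[np.ndarray, float]]:
    """Two gently curved vessels spanning the volume in x (points in µm, z/y/x)."""
    nz, ny, nx = shape
    ext = np.array(voxel_size) * (np.array(shape) - 1)
    xs = np.linspace(0.1 * ext[2], 0.9 * ext[2], 25)
    lines = []
    for frac, amp in ((0.35, 0.06), (0.65, -0.06)):
        ys = frac * ext[1] + amp * ext[1] * np.sin(2 * math.pi * xs / ext[2])
        zs = np.full_like(xs, 0.5 * ext[0])
        lines.append((np.column_stack([zs, ys, xs]), radius))
    return lines


@dataclass
class StackParams:
    """Geometry and photometry of a synthetic two-channel tectum stack.

    The red channel holds vessel tubes (Gaussian cross-section, level
    ``red_vessel_level``) plus mural-nuclei blobs; the green channel holds
    vessel-localised signal at ``green_level``.  Set ``red_vessel_level=0`` to
    emulate a nuclear-only red reporter line.  All distances in µm.
    """

    shape: tuple[int, int, int] = (40, 120, 160)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (1.0, 0.6, 0.6)  # µm
    vessel_polylines: list[tuple[np.ndarray, float]] | None = None  # ((N,3) µm, radius µm)
    green_level: float = 120.0
    red_vessel_level: float = 100.0
    n_nuclei: int = 12
    nucleus_sigma: float = 1.5  # µm
    nucleus_level: float = 300.0
    background: float = 5.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.vessel_polylines is None:
            self.vessel_polylines = default_polylines(self.shape, self.voxel_size)
        ext = np.array(self.voxel_size) * (np.array(self.shape) - 1)
        for pts, radius in self.vessel_polylines:
            pts = np.asarray(pts, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3:
                raise ValueError("polylines must be (N, 3) arrays in µm (z, y, x)")
            if np.any(pts < 0) or np.any(pts > ext):
                raise ValueError("polyline outside the volume")
            if radius <= 0:
                raise ValueError("tube radius must be positive")


@dataclass
class StackTruth:
    """Ground truth of a synthetic stack."""

    centreline_length_um: float
    green_level: float
    n_nuclei: int
    nucleus_centres_um: np.ndarray  # (n, 3) in µm (z, y, x)
    vessel_mip_mask: np.ndarray  # noiseless FWHM vessel mask on the (y, x) MIP


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sqrt(((np.diff(pts, axis=0)) ** 2).sum(axis=1)).sum())


def simulate_tectum_stack(params: StackParams) -> tuple[ImageStack, StackTruth]:
    """Render the synthetic stack and return it with its ground truth.

    Tubes have a Gaussian radial profile with σ = radius/2 (the ground-truth
    mask is the FWHM isocontour of the noiseless profile, projected).  Nuclei
    are isotropic Gaussian blobs placed at least 5σ apart, on the vessels when
    present.
    """
    from scipy.ndimage import distance_transform_edt

    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.shape
    vz, vy, vx = params.voxel_size

    # rasterise centrelines, then a Euclidean distance map in physical units
    marker = np.ones(params.shape, dtype=bool)
    total_len = 0.0
    step = min(params.voxel_size) / 2.0
    radius = params.vessel_polylines[0][1] if params.vessel_polylines else 1.0
    for pts, radius in params.vessel_polylines:
        pts = np.asarray(pts, dtype=float)
        total_len += _polyline_length(pts)
        for a, b in zip(pts[:-1], pts[1:]):
            seg_len = float(np.linalg.norm(b - a))
            n = max(2, int(seg_len / step) + 1)
            line = a[None, :] + np.linspace(0, 1, n)[:, None] * (b - a)[None, :]
            idx = np.round(line / np.array([vz, vy, vx])).astype(int)
            idx = np.clip(idx, 0, np.array([nz - 1, ny - 1, nx - 1]))
            marker[idx[:, 0], idx[:, 1], idx[:, 2]] = False
    if params.vessel_polylines:
        d = distance_transform_edt(marker, sampling=params.voxel_size)
        sigma = radius / 2.0
        tube = np.exp(-(d ** 2) / (2.0 * sigma ** 2)).astype(np.float32)
    else:
        tube = np.zeros(params.shape, dtype=np.float32)

    red = params.background + params.red_vessel_level * tube
    green = params.background + params.green_level * tube

    # nuclei: Gaussian blobs >= 4σ apart, centred on vessels when present
    centres: list[np.ndarray] = []
    ext = np.array(params.voxel_size) * (np.array(params.shape) - 1)
    # 5 sigma apart: the inter-blob saddle then stays below any sane
    # threshold, so separated blobs cannot merge into one component
    min_sep = 5.0 * params.nucleus_sigma
    attempts = 0
    while len(centres) < params.n_nuclei and attempts < 10_000:
        attempts += 1
        if params.vessel_polylines:
            pts, rad = params.vessel_polylines[rng.integers(len(params.vessel_polylines))]
            base = pts[rng.integers(len(pts))]
            offset = rng.normal(0.0, rad / 2.0, 3)
            c = base + offset
        else:
            c = rng.uniform(0.15 * ext, 0.85 * ext)
        c = np.clip(c, 0.1 * ext, 0.9 * ext)
        if all(np.linalg.norm(c - p) >= min_sep for p in centres):
            centres.append(c)
    if len(centres) < params.n_nuclei:
        raise RuntimeError("could not place the requested number of nuclei")
    zc = np.arange(nz) * vz
    yc = np.arange(ny) * vy
    xc = np.arange(nx) * vx
    for c in centres:
        # local window of ±4σ to keep rendering cheap
        sl = tuple(
            slice(
                max(0, int((c[i] - 4 * params.nucleus_sigma) / params.voxel_size[i])),
                min(params.shape[i], int((c[i] + 4 * params.nucleus_sigma) / params.voxel_size[i]) + 2),
            )
            for i in range(3)
        )
        zz = zc[sl[0]][:, None, None] - c[0]
        yy = yc[sl[1]][None, :, None] - c[1]
        xx = xc[sl[2]][None, None, :] - c[2]
        r2 = zz ** 2 + yy ** 2 + xx ** 2
        red[sl] += params.nucleus_level * np.exp(-r2 / (2.0 * params.nucleus_sigma ** 2))

    if params.noise_sd > 0:
        red = red + rng.normal(0.0, params.noise_sd, params.shape)
        green = green + rng.normal(0.0, params.noise_sd, params.shape)

    stack = ImageStack(
        channels={"red": red.astype(np.float32), "green": green.astype(np.float32)},
        voxel_size=params.voxel_size,
    )
    truth = StackTruth(
        centreline_length_um=total_len,
        green_level=params.green_level,
        n_nuclei=params.n_nuclei,
        nucleus_centres_um=np.array(centres) if centres else np.empty((0, 3)),
        vessel_mip_mask=(tube.max(axis=0) >= 0.5),
    )
    return stack, truth
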