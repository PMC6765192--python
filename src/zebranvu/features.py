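"""Geometric and positional locomotion features of larval swim paths.

For each zone-delimited path segment the package fits the minimum-area
enclosing ellipse (Khachiyan's dual iteration) and derives

* eccentricity  ε = sqrt(1 - (b/a)^2)           — elongation / exploration,
* MPDE  = mean point distance to the ellipse centre (mm)  — exploration,
* MPDC  = mean point distance to the well centre (mm)     — thigmotaxis,

alongside the light-preference and speed-class time budgets (1-min bins
averaged over the recording; class percentages normalised to zone time).
Speed classes follow the tracker bands: inactive < 3.3 mm/s, low 3.3-6.4 mm/s,
high >= 6.4 mm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import (
    FeatureSet,
    LarvaFeatureRecord,
    Trajectory,
    WellGeometry,
    ZoneFeatures,
)
from .segmentation import (
    DARK,
    LIGHT,
    PathSegment,
    assign_zone,
    count_transitions,
    filter_short_segments,
    segment_by_zone,
)

__all__ = [
    "SpeedThresholds",
    "EllipseFit",
    "FeatureConfig",
    "instantaneous_speeds",
    "classify_speed",
    "time_budgets",
    "min_enclosing_ellipse",
    "eccentricity",
    "mpde",
    "mpdc",
    "larva_features",
]

SPEED_CLASSES = ("inactive", "low", "high")


@dataclass(frozen=True)
class SpeedThresholds:
    """Speed-class band edges in mm/s: [0, inactive_below) / [inactive_below,
    high_at_or_above) / [high_at_or_above, inf)."""

    inactive_below: float = 3.3
    high_at_or_above: float = 6.4

    def __post_init__(self) -> None:
        if not 0 < self.inactive_below < self.high_at_or_above:
            raise ValueError("need 0 < inactive_below < high_at_or_above")


@dataclass(frozen=True)
class EllipseFit:
    """Minimum enclosing ellipse: centre, semi-axes a >= b, orientation of a."""

    centre: tuple[float, float]
    a: float
    b: float
    orientation: float
    degenerate: bool = False

    def form(self, points: np.ndarray) -> np.ndarray:
        """Ellipse quadratic form evaluated at points; <= 1 means inside."""
        p = np.atleast_2d(points) - np.asarray(self.centre)
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        u = p @ np.array([c, s])
        v = p @ np.array([-s, c])
        a = self.a if self.a > 0 else np.inf
        b = self.b if self.b > 0 else np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (u / a) ** 2 + (v / b) ** 2
        # along a zero axis any non-zero offset is outside
        out = np.where((self.b == 0) & (np.abs(v) > 1e-9), np.inf, out)
        return out


@dataclass
class FeatureConfig:
    """Tunables of the behavioural pipeline (defaults follow the assay protocol)."""

    thresholds: SpeedThresholds = field(default_factory=SpeedThresholds)
    bin_s: float = 60.0
    block_s: float | None = None  # e.g. 900.0 for 15-min blocks
    artefact_percentile: float = 1.0
    ellipse_tol: float = 1e-7


def instantaneous_speeds(traj: Trajectory) -> np.ndarray:
    """Per-interval speed (mm/s): Euclidean displacement over Δt; length n-1."""
    dt = np.diff(traj.t)
    if np.any(dt <= 0):
        raise ValueError("zero or negative inter-frame interval")
    return np.hypot(np.diff(traj.x), np.diff(traj.y)) / dt


def classify_speed(speeds: np.ndarray, th: SpeedThresholds = SpeedThresholds()) -> np.ndarray:
    """Assign each interval to ``inactive`` / ``low`` / ``high``.

    Bands are half-open: inactive [0, 3.3), low [3.3, 6.4), high [6.4, inf).
    """
    speeds = np.asarray(speeds, dtype=float)
    if np.any(speeds < 0):
        raise ValueError("negative speed")
    out = np.full(speeds.shape, "inactive", dtype="<U8")
    out[speeds >= th.inactive_below] = "low"
    out[speeds >= th.high_at_or_above] = "high"
    return out


def time_budgets(
    traj: Trajectory,
    labels: np.ndarray,
    classes: np.ndarray,
    bin_s: float = 60.0,
    block_s: float | None = None,
) -> dict:
    """Light-preference and speed-class budgets from 1-min bins.

    Each inter-frame interval carries its duration, the zone of its starting
    point and its speed class.  Per bin: % of time in light, and within each
    zone % of zone time per class.  Bins are then averaged with equal weight
    (bins without time in a zone are excluded from that zone's average).

    Returns a dict with ``pct_time_light``, ``zones`` (zone -> class pcts) and,
    when ``block_s`` is given, ``blocks`` mapping block labels to the same
    structure computed from the bins inside each block.
    """
    if traj.duration < bin_s:
        raise ValueError("recording shorter than one bin")
    dt = np.diff(traj.t)
    zone = np.asarray(labels)[:-1]
    cls = np.asarray(classes)
    if len(cls) != len(dt) or len(zone) != len(dt):
        raise ValueError("labels/classes must align with trajectory intervals")
    bin_idx = np.floor((traj.t[:-1] - traj.t[0]) / bin_s).astype(int)
    n_bins = bin_idx.max() + 1

    # per-bin accumulators: time per (bin, zone, class) and per (bin, zone)
    zcode = (zone == DARK).astype(int)
    ccode = np.select([cls == c for c in SPEED_CLASSES], [0, 1, 2])
    tzc = np.zeros((n_bins, 2, 3))
    np.add.at(tzc, (bin_idx, zcode, ccode), dt)
    tz = tzc.sum(axis=2)  # (bin, zone)
    tot = tz.sum(axis=1)

    def summarise(bins: np.ndarray) -> dict:
        sel_tot = tot[bins]
        valid = sel_tot > 0
        pct_light = 100.0 * tz[bins, 0] / np.where(valid, sel_tot, 1.0)
        res: dict = {"pct_time_light": float(pct_light[valid].mean())}
        zones = {}
        for zi, zname in enumerate((LIGHT, DARK)):
            ztime = tz[bins, zi]
            ok = ztime > 0
            if not ok.any():
                zones[zname] = None
                continue
            pct = 100.0 * tzc[bins][:, zi, :] / np.where(ok, ztime, 1.0)[:, None]
            zones[zname] = {
                f"pct_{c}": float(pct[ok, ci].mean()) for ci, c in enumerate(SPEED_CLASSES)
            }
        res["zones"] = zones
        return res

    all_bins = np.arange(n_bins)
    out = summarise(all_bins)
    if block_s is not None:
        bins_per_block = int(round(block_s / bin_s))
        out["blocks"] = {}
        for b0 in range(0, n_bins, bins_per_block):
            bins = all_bins[b0 : b0 + bins_per_block]
            lo, hi = b0 * bin_s, min((b0 + bins_per_block) * bin_s, traj.duration)
            label = f"{lo / 60:g}-{hi / 60:g}min"
            out["blocks"][label] = summarise(bins)
    return out


# --- minimum enclosing ellipse ---------------------------------------------


def _degenerate_fit(pts: np.ndarray) -> EllipseFit:
    """Collinear / too-few-points fallback: segment of half the largest extent."""
    uniq = np.unique(pts, axis=0)
    if len(uniq) == 1:
        return EllipseFit(centre=(float(uniq[0, 0]), float(uniq[0, 1])), a=0.0, b=0.0,
                          orientation=0.0, degenerate=True)
    centred = uniq - uniq.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    d = vt[0]
    proj = centred @ d
    lo, hi = proj.min(), proj.max()
    mid = uniq.mean(axis=0) + d * (lo + hi) / 2.0
    return EllipseFit(
        centre=(float(mid[0]), float(mid[1])),
        a=float((hi - lo) / 2.0),
        b=0.0,
        orientation=float(math.atan2(d[1], d[0])),
        degenerate=True,
    )


def _newton_polish(
    Q: np.ndarray, u: np.ndarray, d: int, tol: float, max_newton: int = 30
) -> tuple[np.ndarray, float]:
    """Solve the dual KKT conditions (M_i = d+1 on the support) by damped
    Newton, using dM_i/du_j = -(q_i^T X^{-1} q_j)^2.  Returns the refined
    weights and the residual dual gap."""

    def gap(u: np.ndarray) -> float:
        X = Q.T @ (Q * u[:, None])
        Xinv = np.linalg.inv(X)
        M = np.einsum("ij,jk,ik->i", Q, Xinv, Q)
        ep = M.max() / (d + 1.0) - 1.0
        Ms = M[u > 0]
        em = 1.0 - Ms.min() / (d + 1.0) if len(Ms) else np.inf
        return max(ep, em)

    u = u.copy()
    S = np.flatnonzero(u > 1e-9)
    try:
        for _ in range(max_newton):
            X = Q.T @ (Q * u[:, None])
            Xinv = np.linalg.inv(X)
            QS = Q[S]
            B = QS @ Xinv @ QS.T
            r = np.diag(B) - (d + 1.0)
            if np.abs(r).max() < 0.1 * tol:
                break
            k = len(S)
            kkt = np.zeros((k + 1, k + 1))
            kkt[:k, :k] = -(B**2)
            kkt[:k, k] = 1.0
            kkt[k, :k] = 1.0
            sol = np.linalg.solve(kkt, np.concatenate([-r, [0.0]]))
            du = sol[:k]
            step = 1.0
            neg = du < 0
            if neg.any():
                step = min(1.0, 0.9 * float(np.min(u[S][neg] / (-du[neg]))))
            u[S] = np.clip(u[S] + step * du, 0.0, None)
            u /= u.sum()
        return u, gap(u)
    except np.linalg.LinAlgError:
        return u, np.inf


def min_enclosing_ellipse(
    points: np.ndarray, tol: float = 1e-7, max_iter: int = 100_000
) -> EllipseFit:
    """Minimum-area ellipse enclosing a 2-D point set.

    Khachiyan's iterative reweighting on the convex-hull vertices, run to
    relative tolerance ``tol``; the shape matrix is then rescaled so the
    farthest point sits exactly on the boundary, guaranteeing containment.
    Degenerate inputs (fewer than 3 distinct points, or all collinear) return
    ``degenerate=True`` with ``a`` = half the largest pairwise distance and
    ``b = 0``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("empty point set")
    if pts.shape[1] != 2:
        raise ValueError("points must be Nx2")
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 3:
        return _degenerate_fit(pts)
    centred = uniq - uniq.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[1] <= 1e-12 * max(sv[0], 1.0):
        return _degenerate_fit(pts)

    # hull reduction: the enclosing ellipse depends only on hull vertices
    work = uniq
    if len(uniq) > 8:
        from scipy.spatial import ConvexHull, QhullError

        try:
            work = uniq[ConvexHull(uniq).vertices]
        except QhullError:
            return _degenerate_fit(pts)

    # precondition: centre and scale to unit extent so the lifted system stays
    # well conditioned for segments far from the origin
    shift = work.mean(axis=0)
    scale = float(np.abs(work - shift).max())
    work = (work - shift) / scale

    # Khachiyan dual ascent with away steps (Todd-Yildirim), which converges
    # linearly; the 3x3 inverse is maintained by rank-1 Sherman-Morrison
    # updates so each iteration costs one small matmul
    n, d = len(work), 2
    Q = np.column_stack([work, np.ones(n)])  # n x 3
    u = np.full(n, 1.0 / n)
    X = Q.T @ (Q * u[:, None])
    Xinv = np.linalg.inv(X)
    err = np.inf
    coarse_tol = max(tol, 1e-5)
    for it in range(max_iter):
        M = np.einsum("ij,jk,ik->i", Q, Xinv, Q)
        j_plus = int(np.argmax(M))
        Mmin = np.where(u > 0, M, np.inf)
        j_minus = int(np.argmin(Mmin))
        eps_plus = M[j_plus] / (d + 1.0) - 1.0
        eps_minus = 1.0 - M[j_minus] / (d + 1.0)
        err = max(eps_plus, eps_minus)
        if err < tol:
            break
        if err < coarse_tol and (it & 1023) == 0:
            # the active support is identified; a Newton solve of the KKT
            # conditions (M_i = d+1 on the support) finishes in a few steps
            # where the first-order iteration would zigzag for ~1e5 more
            u_new, err_new = _newton_polish(Q, u, d, tol)
            if err_new < err:
                u, err = u_new, err_new
                if err < tol:
                    break
                Xinv = np.linalg.inv(Q.T @ (Q * u[:, None]))
                M = np.einsum("ij,jk,ik->i", Q, Xinv, Q)
                j_plus = int(np.argmax(M))
                Mmin = np.where(u > 0, M, np.inf)
                j_minus = int(np.argmin(Mmin))
        if eps_plus >= eps_minus:
            j, m = j_plus, M[j_plus]
            lam = (m - d - 1.0) / ((d + 1.0) * (m - 1.0))
        else:
            j, m = j_minus, M[j_minus]
            lam = max(
                (m - d - 1.0) / ((d + 1.0) * (m - 1.0)), -u[j] / (1.0 - u[j])
            )
        u *= 1.0 - lam
        u[j] += lam
        if u[j] < 0.0:
            u[j] = 0.0
        # X' = (1-lam) X + lam q q^T
        q = Q[j]
        Xq = Xinv @ q
        denom = (1.0 - lam) + lam * (q @ Xq)
        Xinv = (Xinv - (lam / denom) * np.outer(Xq, Xq)) / (1.0 - lam)
        if (it + 1) % 256 == 0:  # refresh to curb rank-1 round-off drift
            Xinv = np.linalg.inv(Q.T @ (Q * u[:, None]))
    else:
        raise RuntimeError(
            f"enclosing-ellipse iteration did not converge in {max_iter} steps "
            f"(residual {err:.3g})"
        )

    c = work.T @ u
    cov = (work * u[:, None]).T @ work - np.outer(c, c)
    A = np.linalg.inv(cov) / d
    # rescale so the farthest point touches the boundary exactly
    delta = work - c
    forms = np.einsum("ij,jk,ik->i", delta, A, delta)
    A = A / forms.max()

    evals, evecs = np.linalg.eigh(A)
    a = scale / math.sqrt(evals[0])
    b = scale / math.sqrt(evals[1])
    major = evecs[:, 0]
    centre = shift + scale * c
    return EllipseFit(
        centre=(float(centre[0]), float(centre[1])),
        a=float(a),
        b=float(b),
        orientation=float(math.atan2(major[1], major[0])),
        degenerate=False,
    )


def eccentricity(fit: EllipseFit) -> float:
    """ε = sqrt(1 - (b/a)^2); 0 for a circle, 1 for a degenerate (line) fit."""
    if fit.degenerate:
        return 1.0
    if fit.a == 0:
        raise ValueError("eccentricity undefined for a zero-extent ellipse")
    return math.sqrt(max(0.0, 1.0 - (fit.b / fit.a) ** 2))


def mpde(points: np.ndarray, fit: EllipseFit) -> float:
    """Mean Euclidean distance from the path's points to the ellipse centre (mm)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return float(np.hypot(pts[:, 0] - fit.centre[0], pts[:, 1] - fit.centre[1]).mean())


def mpdc(points: np.ndarray, well: WellGeometry) -> float:
    """Mean Euclidean distance from the path's points to the well centre (mm)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("empty point set")
    return float(np.hypot(pts[:, 0] - well.centre[0], pts[:, 1] - well.centre[1]).mean())


# --- full per-larva pipeline -----------------------------------------------


def _segment_features(
    traj: Trajectory,
    well: WellGeometry,
    kept: list[PathSegment],
    removed: list[PathSegment],
    tol: float,
) -> dict[str, dict | None]:
    out: dict[str, dict | None] = {}
    for zone in (LIGHT, DARK):
        segs = [s for s in kept if s.zone == zone]
        n_removed = sum(1 for s in removed if s.zone == zone)
        if not segs:
            out[zone] = None if n_removed == 0 else {
                "mean_eccentricity": None,
                "mean_mpde": None,
                "mean_mpdc": None,
                "n_segments_kept": 0,
                "n_segments_removed": n_removed,
            }
            continue
        eccs, mpdes, mpdcs = [], [], []
        for seg in segs:
            pts = traj.points[seg.start : seg.end + 1]
            fit = min_enclosing_ellipse(pts, tol=tol)
            eccs.append(eccentricity(fit))
            mpdes.append(mpde(pts, fit))
            mpdcs.append(mpdc(pts, well))
        out[zone] = {
            "mean_eccentricity": float(np.mean(eccs)),
            "mean_mpde": float(np.mean(mpdes)),
            "mean_mpdc": float(np.mean(mpdcs)),
            "n_segments_kept": len(segs),
            "n_segments_removed": n_removed,
        }
    return out


def _feature_set(budget: dict, transitions: int, geo: dict[str, dict | None]) -> FeatureSet:
    zones: dict[str, ZoneFeatures | None] = {}
    for zone in (LIGHT, DARK):
        b = budget["zones"].get(zone)
        g = geo.get(zone)
        if b is None and g is None:
            zones[zone] = None
            continue
        zones[zone] = ZoneFeatures(
            pct_inactive=b["pct_inactive"] if b else float("nan"),
            pct_low=b["pct_low"] if b else float("nan"),
            pct_high=b["pct_high"] if b else float("nan"),
            mean_eccentricity=g["mean_eccentricity"] if g else None,
            mean_mpde=g["mean_mpde"] if g else None,
            mean_mpdc=g["mean_mpdc"] if g else None,
            n_segments_kept=g["n_segments_kept"] if g else 0,
            n_segments_removed=g["n_segments_removed"] if g else 0,
        )
    return FeatureSet(
        pct_time_light=budget["pct_time_light"], transitions=transitions, zones=zones
    )


def larva_features(
    traj: Trajectory,
    well: WellGeometry,
    config: FeatureConfig = FeatureConfig(),
) -> LarvaFeatureRecord:
    """Run the full behavioural chain on one larva.

    Zones -> unfiltered transitions and time budgets -> zone segmentation ->
    1st-percentile artefact filter -> per-segment ε / MPDE / MPDC on the kept
    segments -> per-zone means.  Zones the larva never visited carry ``None``
    features (absent, not zero).  With ``config.block_s`` set, the same
    endpoints are also produced per time block.
    """
    if traj.group is None:
        raise ValueError("trajectory must carry a treatment group")
    labels = assign_zone(traj, well)
    speeds = instantaneous_speeds(traj)
    classes = classify_speed(speeds, config.thresholds)
    budget = time_budgets(traj, labels, classes, bin_s=config.bin_s, block_s=config.block_s)
    transitions = count_transitions(labels)
    segments = segment_by_zone(traj, labels)
    kept, removed = filter_short_segments(
        segments, percentile=config.artefact_percentile, larva_id=traj.larva_id
    )
    geo = _segment_features(traj, well, kept, removed, config.ellipse_tol)
    overall = _feature_set(budget, transitions, geo)

    blocks: dict[str, FeatureSet] = {}
    if config.block_s is not None:
        for label, bud in budget["blocks"].items():
            lo_min, hi_min = label.replace("min", "").split("-")
            lo, hi = float(lo_min) * 60 + traj.t[0], float(hi_min) * 60 + traj.t[0]
            sel = (traj.t >= lo) & (traj.t <= hi)
            idx = np.nonzero(sel)[0]
            if len(idx) < 2:
                continue
            sub = Trajectory(
                larva_id=traj.larva_id,
                t=traj.t[idx],
                x=traj.x[idx],
                y=traj.y[idx],
                group=traj.group,
            )
            sub_labels = labels[idx]
            sub_transitions = count_transitions(sub_labels)
            sub_segments = segment_by_zone(sub, sub_labels)
            sub_kept, sub_removed = filter_short_segments(
                sub_segments, percentile=config.artefact_percentile, larva_id=traj.larva_id
            )
            sub_geo = _segment_features(sub, well, sub_kept, sub_removed, config.ellipse_tol)
            blocks[label] = _feature_set(bud, sub_transitions, sub_geo)

    return LarvaFeatureRecord(
        larva_id=traj.larva_id, group=traj.group, overall=overall, blocks=blocks
    )
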