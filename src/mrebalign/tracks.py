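"""Trajectory statistics for membrane-bound filament motion.

A :class:`Track` is an ordered list of per-frame 2-D positions.  The
module fits each track with an orthogonal-regression line (principal
axis of the position cloud) and with mean-squared-displacement models
that classify motion as directed or diffusive; filters tracks by the
standard directionality cutoffs; measures track angles relative to the
cell midline with the axial fold transforms; and computes the pairwise
angle-difference / dot-product statistics used to quantify local
alignment of motion.

Angles are axial quantities: a line at theta and theta + 180 deg is the
same line, so all line angles live in [0, 180) and angle differences are
folded into [0, 90].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial import cKDTree

__all__ = [
    "Track",
    "TrackSummary",
    "FilterPolicy",
    "PairStatistic",
    "MIN_FIT_FRAMES",
    "fit_track_line",
    "fit_msd",
    "summarize_track",
    "apply_filters",
    "fold_angle",
    "angle_to_midline",
    "sigma90",
    "pairwise_statistics",
    "angle_width_binning",
]

#: minimum number of successive frames for a track to be fit-eligible
MIN_FIT_FRAMES = 5

#: cap on the number of MSD lags entering any fit; only bites on tracks
#: far longer than typical filament runs (see :func:`fit_msd`)
MAX_MSD_LAGS = 100


@dataclass(frozen=True)
class Track:
    """One particle trajectory: per-frame positions in um."""

    track_id: int | str
    frames: np.ndarray
    positions: np.ndarray
    frame_interval: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=int)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or len(pos) != len(frames):
            raise ValueError("positions must be (n, 2) matching frames")
        if len(frames) >= 2 and not np.all(np.diff(frames) > 0):
            raise ValueError(f"track {self.track_id}: frames must be strictly increasing")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "positions", pos)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def fit_eligible(self) -> bool:
        return self.n_frames >= MIN_FIT_FRAMES


@dataclass
class TrackSummary:
    """Per-track fitted quantities; the substrate of the filter step."""

    track_id: int | str
    n_frames: int
    mean_position: tuple[float, float]
    line_angle: float          # degrees, axial, [0, 180)
    r2_orth: float             # orthogonal-regression explained variance
    displacement: float        # um, end-to-end along the fitted line
    velocity_msd: float = math.nan   # um/s, from the MSD drift term
    diffusion_D: float = math.nan    # um^2/s
    alpha: float = math.nan          # log-log MSD slope
    r2_loglog: float = math.nan
    localization_sigma: float = math.nan  # um, from *_locnoise models
    msd_fit_ok: bool = True

    def as_dict(self) -> dict:
        d = {
            "track_id": self.track_id,
            "n_frames": self.n_frames,
            "mean_x_um": self.mean_position[0],
            "mean_y_um": self.mean_position[1],
            "line_angle_deg": self.line_angle,
            "r2_orth": self.r2_orth,
            "displacement_um": self.displacement,
            "velocity_um_s": self.velocity_msd,
            "diffusion_um2_s": self.diffusion_D,
            "alpha": self.alpha,
            "r2_loglog": self.r2_loglog,
            "localization_sigma_um": self.localization_sigma,
            "msd_fit_ok": self.msd_fit_ok,
        }
        return d


def fit_track_line(track: Track) -> TrackSummary:
    """Orthogonal least-squares line through a track.

    The first principal axis of the position cloud minimizes the
    perpendicular distances, giving the (axial) line angle; ``r2_orth``
    is the fraction of total position variance explained along the axis.
    Displacement is end-to-end along the fitted line (first to last
    projection).
    """
    pos = track.positions
    center = pos.mean(axis=0)
    centered = pos - center
    if np.allclose(centered, 0.0):
        raise ValueError(f"track {track.track_id}: zero-variance track")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    lam = s**2
    r2 = float(lam[0] / lam.sum()) if len(lam) > 1 else 1.0
    angle = math.degrees(math.atan2(axis[1], axis[0])) % 180.0
    proj = centered @ axis
    return TrackSummary(
        track_id=track.track_id,
        n_frames=track.n_frames,
        mean_position=(float(center[0]), float(center[1])),
        line_angle=angle,
        r2_orth=r2,
        displacement=float(abs(proj[-1] - proj[0])),
    )


def time_averaged_msd(track: Track, max_lag: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD per lag: (lag times s, MSD um^2)."""
    pos = track.positions
    n = len(pos)
    top = n - 1 if max_lag is None else min(max_lag, n - 1)
    lags = np.arange(1, top + 1)
    msd = np.array(
        [np.mean(np.sum((pos[k:] - pos[:-k]) ** 2, axis=1)) for k in lags]
    )
    return lags * track.frame_interval, msd


def _loglog_alpha(t: np.ndarray, msd: np.ndarray) -> tuple[float, float]:
    ok = msd > 0
    if ok.sum() < 2:
        return math.nan, 0.0
    res = stats.linregress(np.log(t[ok]), np.log(msd[ok]))
    return float(res.slope), float(res.rvalue**2)


def fit_msd(track: Track, model: str = "drift_diffusion") -> TrackSummary:
    """MSD-based motion classification of one track.

    Models
    ------
    ``drift_diffusion``
        MSD(t) = 4 D t + (V t)^2, nonlinear least squares on the first
        80% of the lags (later lags average fewer displacements and are
        noisier).
    ``drift_diffusion_locnoise``
        MSD(t) = 4 D t + (V t)^2 + 4 sigma^2, single-molecule variant,
        fitted on lags up to half the track length.
    ``powerlaw_locnoise``
        MSD(t) = C t^alpha + 4 sigma^2, same lag range.

    All parameters are constrained non-negative.  The scaling exponent
    ``alpha`` and its ``r2_loglog`` always come from a straight-line fit
    of log MSD vs log t over the same lag range.  Lags are additionally
    capped at ``MAX_MSD_LAGS``: the time average at lag k pools only
    n - k displacements, so on very long tracks the largest lags carry
    almost no information and would otherwise dominate the regression.
    """
    if track.n_frames < MIN_FIT_FRAMES + 1:
        raise ValueError(f"track {track.track_id}: too short for an MSD fit")
    summary = fit_track_line(track)
    if model == "drift_diffusion":
        n_keep = max(2, int(math.floor(0.8 * (track.n_frames - 1))))
    elif model in ("drift_diffusion_locnoise", "powerlaw_locnoise"):
        n_keep = max(2, track.n_frames // 2)
    else:
        raise ValueError(f"unknown MSD model: {model!r}")
    n_keep = min(n_keep, MAX_MSD_LAGS)
    t_fit, msd_fit = time_averaged_msd(track, max_lag=n_keep)

    alpha, r2ll = _loglog_alpha(t_fit, msd_fit)
    summary.alpha = alpha
    summary.r2_loglog = r2ll

    scale = max(msd_fit.max(), 1e-12)
    try:
        if model == "drift_diffusion":
            # linear in (D, V^2): exact non-negative least squares
            design = np.column_stack([4 * t_fit, t_fit**2])
            (d_coef, v2), _ = optimize.nnls(design, msd_fit)
            summary.diffusion_D, summary.velocity_msd = float(d_coef), float(math.sqrt(v2))
        elif model == "drift_diffusion_locnoise":
            design = np.column_stack([4 * t_fit, t_fit**2, np.full_like(t_fit, 4.0)])
            (d_coef, v2, s2), _ = optimize.nnls(design, msd_fit)
            summary.diffusion_D, summary.velocity_msd = float(d_coef), float(math.sqrt(v2))
            summary.localization_sigma = float(math.sqrt(s2))
        else:  # powerlaw_locnoise
            popt, _ = optimize.curve_fit(
                lambda t, C, a, sig: C * t**a + 4 * sig**2,
                t_fit, msd_fit, p0=[scale, 1.0, 0.01],
                bounds=(0, [np.inf, 4.0, np.inf]), maxfev=10000,
            )
            summary.alpha = float(popt[1])
            summary.localization_sigma = float(popt[2])
    except (RuntimeError, ValueError):
        summary.msd_fit_ok = False
    return summary


def summarize_track(track: Track, model: str = "drift_diffusion") -> TrackSummary:
    """Line fit plus MSD fit; honors generator-attached fit metadata.

    Synthetic null-model tracks carry a recorded orthogonal-regression
    R^2 in ``track.meta['r2_orth']``; when present it overrides the
    fitted value so downstream filters see the stated quality.
    """
    summary = fit_msd(track, model=model)
    if "r2_orth" in track.meta:
        summary.r2_orth = float(track.meta["r2_orth"])
    return summary


@dataclass(frozen=True)
class FilterPolicy:
    """Directionality/linearity cutoffs applied to track summaries.

    Thresholds are strict lower bounds, matching the convention
    "R^2 > 0.9, displacement > 0.2 um, velocity > 1e-9 um/s, log-log
    R^2 > 0.6".  A ``None`` threshold disables that predicate.
    """

    r2_orth_min: float | None = 0.9
    displacement_min_um: float | None = 0.2
    velocity_min_um_s: float | None = 1e-9
    r2_loglog_min: float | None = 0.6
    min_frames: int | None = MIN_FIT_FRAMES
    max_frames: int | None = None

    @classmethod
    def filament(cls) -> "FilterPolicy":
        return cls()

    @classmethod
    def single_molecule(cls) -> "FilterPolicy":
        # 5e-5 nm/s = 5e-8 um/s, honored verbatim despite the odd magnitude
        return cls(
            r2_orth_min=None,
            displacement_min_um=None,
            velocity_min_um_s=5e-8,
            r2_loglog_min=0.95,
            min_frames=10,
            max_frames=120,
        )

    def predicates(self, s: TrackSummary) -> dict[str, bool]:
        checks: dict[str, bool] = {}
        if self.min_frames is not None:
            checks["min_frames"] = s.n_frames >= self.min_frames
        if self.max_frames is not None:
            checks["max_frames"] = s.n_frames <= self.max_frames
        if self.r2_orth_min is not None:
            checks["r2_orth"] = s.r2_orth > self.r2_orth_min
        if self.displacement_min_um is not None:
            checks["displacement"] = s.displacement > self.displacement_min_um
        if self.velocity_min_um_s is not None:
            checks["velocity"] = s.velocity_msd > self.velocity_min_um_s
        if self.r2_loglog_min is not None:
            checks["r2_loglog"] = s.r2_loglog > self.r2_loglog_min
        checks["msd_fit_ok"] = s.msd_fit_ok
        return checks


def apply_filters(
    summaries: list[TrackSummary], policy: FilterPolicy
) -> tuple[list[TrackSummary], dict[str, int]]:
    """Retain summaries passing every policy predicate.

    Returns the retained subset and per-predicate attrition counts (how
    many tracks each predicate rejected; a track can count against
    several predicates).
    """
    retained: list[TrackSummary] = []
    attrition: dict[str, int] = {}
    for s in summaries:
        checks = policy.predicates(s)
        for name, ok in checks.items():
            if not ok:
                attrition[name] = attrition.get(name, 0) + 1
        if all(checks.values()):
            retained.append(s)
    return retained, attrition


def fold_angle(delta: float | np.ndarray) -> float | np.ndarray:
    """Fold a raw angle difference into [0, 90] degrees.

    Applies the axial two-step transform: shift negative differences by
    +180, then reflect values above 90 to 180 - value.  Idempotent.
    """
    d = np.asarray(delta, dtype=float)
    d = np.mod(d, 360.0)
    d = np.where(d > 180.0, d - 180.0, d)   # now in [0, 180]
    d = np.where(d < 0.0, d + 180.0, d)
    d = np.where(d > 90.0, 180.0 - d, d)
    return float(d) if np.isscalar(delta) or d.ndim == 0 else d


def angle_to_midline(summary: TrackSummary, width_profile) -> float | None:
    """Track angle relative to the cell midline, folded to [0, 90] deg.

    The midline angle is taken at the station nearest the track's mean
    position.  Returns ``None`` for round cells (no midline).
    """
    if width_profile.midline is None:
        return None
    i = width_profile.nearest_station(np.asarray(summary.mean_position))
    return float(fold_angle(summary.line_angle - width_profile.midline_angles_deg[i]))


def sigma90(angles) -> float:
    """Root-mean-square deviation of an angle sample from 90 degrees."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("sigma90 of an empty sample is undefined")
    return float(np.sqrt(np.mean((a - 90.0) ** 2)))


@dataclass(frozen=True)
class PairStatistic:
    """Pairwise alignment statistics of track summaries."""

    distances: np.ndarray       # um, between mean positions
    delta_theta: np.ndarray     # degrees, folded to [0, 90]
    dot_products: np.ndarray    # cos(theta_i - theta_j)
    bin_edges: np.ndarray
    binned: pd.DataFrame        # d_bin_center, mean_dp, median_dtheta, n_pairs
    median_dtheta_1um: float    # median for pairs <= 1 um apart
    median_dtheta: float        # median over all retained pairs


def pairwise_statistics(
    summaries: list[TrackSummary],
    neighborhood_min: int = 3,
    neighborhood_radius: float = 5.0,
    max_distance: float = 3.0,
    bin_width: float = 0.5,
) -> PairStatistic:
    """Angle differences and dot products between nearby track pairs.

    For tracks i, j the dot product is DP = cos(theta_i - theta_j) of the
    raw line angles (no absolute value) and the distance is between mean
    positions.  Only tracks with at least ``neighborhood_min`` other
    tracks within ``neighborhood_radius`` are considered (this removes
    out-of-cell tracks), and pairs are kept up to ``max_distance``
    (about one cell length) where they are binned by distance.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 track summaries")
    pos = np.array([s.mean_position for s in summaries])
    ang = np.array([s.line_angle for s in summaries])
    tree = cKDTree(pos)
    n_neighbors = np.array([len(tree.query_ball_point(p, neighborhood_radius)) - 1 for p in pos])
    eligible = n_neighbors >= neighborhood_min

    pairs = np.array(sorted(tree.query_pairs(max_distance)), dtype=int)
    if pairs.size:
        keep = eligible[pairs[:, 0]] & eligible[pairs[:, 1]]
        pairs = pairs[keep]
    edges = np.arange(0.0, max_distance + bin_width / 2, bin_width)
    if pairs.size == 0:
        empty = pd.DataFrame(
            {"d_bin_center": (edges[:-1] + edges[1:]) / 2,
             "mean_dp": np.nan, "median_dtheta_deg": np.nan, "n_pairs": 0}
        )
        z = np.empty(0)
        return PairStatistic(z, z, z, edges, empty, math.nan, math.nan)

    i, j = pairs[:, 0], pairs[:, 1]
    d = np.hypot(*(pos[i] - pos[j]).T)
    raw = ang[i] - ang[j]
    dtheta = fold_angle(raw)
    dp = np.cos(np.radians(raw))

    which = np.digitize(d, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        m = which == b
        rows.append(
            {
                "d_bin_center": (edges[b] + edges[b + 1]) / 2,
                "mean_dp": float(np.mean(dp[m])) if m.any() else math.nan,
                "median_dtheta_deg": float(np.median(dtheta[m])) if m.any() else math.nan,
                "n_pairs": int(m.sum()),
            }
        )
    near = d <= 1.0
    return PairStatistic(
        distances=d,
        delta_theta=dtheta,
        dot_products=dp,
        bin_edges=edges,
        binned=pd.DataFrame(rows),
        median_dtheta_1um=float(np.median(dtheta[near])) if near.any() else math.nan,
        median_dtheta=float(np.median(dtheta)),
    )


def angle_width_binning(
    angles_deg,
    local_widths_um,
    bin_width: float = 0.25,
    min_count: int = 3,
) -> pd.DataFrame:
    """Median midline angle binned by local cell width.

    Bins with fewer than ``min_count`` tracks are suppressed.  Returns a
    table with ``width_bin_center_um``, ``median_angle_deg``, ``n``.
    """
    a = np.asarray(angles_deg, float)
    w = np.asarray(local_widths_um, float)
    if a.shape != w.shape:
        raise ValueError("angles and widths must align")
    lo = math.floor(w.min() / bin_width) * bin_width
    hi = math.ceil(w.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    which = np.clip(np.digitize(w, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        m = which == b
        if m.sum() < min_count:
            continue
        rows.append(
            {
                "width_bin_center_um": (edges[b] + edges[b + 1]) / 2,
                "median_angle_deg": float(np.median(a[m])),
                "n": int(m.sum()),
            }
        )
    return pd.DataFrame(rows, columns=["width_bin_center_um", "median_angle_deg", "n"])
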