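"""Synthetic trajectories and cell contours for pipeline validation.

Microscopy-free stand-ins with the statistical structure the analysis
assumes: spherocylinder ("rod"), circular ("sphere") and bulged-sphere
contours; circumferentially biased vs isotropic directional tracks;
the random-angle null field (straight 1-um segments at 25 nm/s with a
recorded orthogonal-regression R^2 of 0.95, placed uniformly on a
100 x 100 um area, angles uniform on [0, 180) degrees); and ballistic /
diffusive tracks with localization noise for validating MSD fits.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contours import CellContour
from .tracks import Track

__all__ = [
    "TrajectoryScenario",
    "ContourScenario",
    "generate_tracks",
    "generate_contour",
    "generate_msd_fixture",
    "RANDOM_FIELD_SIZE_UM",
]

TRAJECTORY_KINDS = ("circumferential", "isotropic", "random_field", "ballistic", "diffusive")
CONTOUR_KINDS = ("rod", "sphere", "bulged_sphere")

#: side of the square field on which null-model tracks are scattered (um)
RANDOM_FIELD_SIZE_UM = 100.0
#: null-model track displacement (um) and nominal velocity (um/s)
RANDOM_FIELD_DISPLACEMENT_UM = 1.0
RANDOM_FIELD_VELOCITY_UM_S = 0.025
#: orthogonal-regression R^2 recorded on each null-model track
RANDOM_FIELD_R2 = 0.95


@dataclass(frozen=True)
class TrajectoryScenario:
    """Recipe for one batch of synthetic tracks."""

    kind: str
    n_tracks: int = 100
    frame_interval: float = 1.0        # s
    n_frames_range: tuple[int, int] = (20, 60)
    speed: float = 0.025               # um/s, directional kinds
    angular_noise: float = 10.0        # von Mises concentration, circumferential
    diffusion_coeff: float = 0.01      # um^2/s, diffusive kind
    localization_sigma: float = 0.0    # um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in TRAJECTORY_KINDS:
            raise ValueError(f"unknown trajectory kind: {self.kind!r}")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.speed < 0 or self.localization_sigma < 0:
            raise ValueError("speed and localization_sigma must be non-negative")
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be non-negative")
        lo, hi = self.n_frames_range
        if lo < 2 or hi < lo:
            raise ValueError("n_frames_range must satisfy 2 <= min <= max")


@dataclass(frozen=True)
class ContourScenario:
    """Recipe for one synthetic cell contour."""

    kind: str
    width: float = 0.9            # um, rod
    length: float = 3.0           # um, rod (total, caps included)
    radius: float = 1.0           # um, sphere / bulged body
    bulge_width: float = 0.8      # um, bulged_sphere
    neck_depth: float = 0.3       # um, fillet radius of the neck
    n_vertices: int = 128
    vertex_jitter: float = 0.0    # um, radial noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CONTOUR_KINDS:
            raise ValueError(f"unknown contour kind: {self.kind!r}")
        if self.n_vertices < 16:
            raise ValueError("n_vertices must be >= 16")
        if min(self.width, self.length, self.radius, self.bulge_width, self.neck_depth) <= 0:
            raise ValueError("geometry parameters must be positive")
        if self.vertex_jitter < 0:
            raise ValueError("vertex_jitter must be non-negative")
        if self.kind == "rod" and self.length <= self.width:
            raise ValueError("rod length must exceed its width")
        if self.kind == "bulged_sphere" and self.bulge_width >= 2 * self.radius:
            raise ValueError("bulge_width must be below the sphere diameter")


# ---------------------------------------------------------------------------
# contours

def _arc(center, radius, a0, a1, n, ccw=True):
    """Sample an arc from angle a0 to a1 (radians); direction chosen explicitly."""
    if ccw and a1 < a0:
        a1 += 2 * math.pi
    if not ccw and a1 > a0:
        a1 -= 2 * math.pi
    t = np.linspace(a0, a1, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)])


def _rod_outline(width: float, length: float, n: int) -> np.ndarray:
    """CCW spherocylinder: two straight flanks capped by semicircles."""
    r = width / 2.0
    c = (length - width) / 2.0  # cap centers at (+-c, 0)
    flank = length - width
    per_flank = max(2, int(round(n * flank / (2 * flank + 2 * math.pi * r))))
    per_cap = max(4, (n - 2 * per_flank) // 2)
    bottom = np.column_stack([np.linspace(-c, c, per_flank, endpoint=False), np.full(per_flank, -r)])
    right = _arc((c, 0.0), r, -math.pi / 2, math.pi / 2, per_cap)
    top = np.column_stack([np.linspace(c, -c, per_flank, endpoint=False), np.full(per_flank, r)])
    left = _arc((-c, 0.0), r, math.pi / 2, 3 * math.pi / 2, per_cap)
    return np.vstack([bottom, right, top, left])


def _bulged_outline(radius: float, bulge_width: float, neck_depth: float, n: int) -> np.ndarray:
    """Body circle joined to a tangent smaller circle by concave neck fillets.

    The fillet circles of radius ``neck_depth`` are tangent to both the
    body (radius R) and the bulge (radius rb), so the neck region curves
    inward: its vertices carry sidewall curvature of opposite sign to
    the convex body and bulge.
    """
    R, rb, f = radius, bulge_width / 2.0, neck_depth
    d = R + rb  # bulge center on +x, externally tangent
    # fillet center: distance R+f from the body center, rb+f from the bulge center
    xf = (d * d + (R + f) ** 2 - (rb + f) ** 2) / (2 * d)
    yf2 = (R + f) ** 2 - xf * xf
    if yf2 <= 0:
        raise ValueError("neck fillet does not fit this body/bulge combination")
    yf = math.sqrt(yf2)

    beta = math.atan2(yf, xf)                 # body tangency angle (upper)
    gamma = math.atan2(yf, xf - d)            # direction bulge -> upper fillet center
    # tangency angles of the fillet arc, measured from the fillet center
    up = np.array([xf, yf])
    phi_body = math.atan2(*((up * (R / (R + f)) - up))[::-1])      # toward body tangent point
    phi_bulge = math.atan2(*((np.array([d, 0]) + (rb) * (up - [d, 0]) / (rb + f) - up))[::-1])

    arc_body = 2 * (math.pi - beta) * R
    gamma_half = abs(gamma)  # bulge tangency angle about the bulge center
    arc_bulge = 2 * gamma_half * rb
    arc_fillet = abs(phi_bulge - phi_body)
    if arc_fillet > math.pi:
        arc_fillet = 2 * math.pi - arc_fillet
    arc_fillet *= f
    total = arc_body + arc_bulge + 2 * arc_fillet

    def n_of(s):
        return max(4, int(round(n * s / total)))

    # CCW walk: body far side (upper tangency -> lower), lower fillet (CW),
    # bulge far side (CCW through 0), upper fillet (CW).
    body = _arc((0, 0), R, beta, 2 * math.pi - beta, n_of(arc_body))
    lower_f = _arc((xf, -yf), f, -phi_body, -phi_bulge, n_of(arc_fillet), ccw=False)
    bulge = _arc((d, 0), rb, -gamma_half, gamma_half, n_of(arc_bulge))
    upper_f = _arc((xf, yf), f, phi_bulge, phi_body, n_of(arc_fillet), ccw=False)
    return np.vstack([body, lower_f, bulge, upper_f])


def generate_contour(scenario: ContourScenario) -> CellContour:
    """Build one closed, counter-clockwise synthetic cell contour."""
    rng = np.random.default_rng(scenario.seed)
    if scenario.kind == "sphere":
        t = np.linspace(0, 2 * math.pi, scenario.n_vertices, endpoint=False)
        v = scenario.radius * np.column_stack([np.cos(t), np.sin(t)])
    elif scenario.kind == "rod":
        v = _rod_outline(scenario.width, scenario.length, scenario.n_vertices)
    else:
        v = _bulged_outline(scenario.radius, scenario.bulge_width,
                            scenario.neck_depth, scenario.n_vertices)
    if scenario.vertex_jitter > 0:
        center = v.mean(axis=0)
        radial = v - center
        norms = np.hypot(*radial.T)[:, None]
        v = v + radial / norms * rng.normal(0.0, scenario.vertex_jitter, (len(v), 1))
    return CellContour(v)


# ---------------------------------------------------------------------------
# trajectories

def _straight_track(track_id, start, angle_deg, length_um, speed, frame_interval,
                    loc_sigma, rng, meta=None) -> Track:
    if speed <= 0:
        raise ValueError("directional tracks need a positive speed")
    n_frames = max(2, int(round(length_um / (speed * frame_interval))) + 1)
    t = np.arange(n_frames) * frame_interval
    direction = np.array([math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))])
    pos = np.asarray(start, float) + np.outer(t * speed, direction)
    if loc_sigma > 0:
        pos = pos + rng.normal(0.0, loc_sigma, pos.shape)
    return Track(track_id, np.arange(n_frames), pos, frame_interval, meta or {})


def _axial_von_mises(rng, kappa: float) -> float:
    """Axial angular noise in degrees: half a von Mises draw on the doubled circle."""
    if not math.isfinite(kappa) or kappa > 1e8:
        return 0.0
    return math.degrees(rng.vonmises(0.0, kappa)) / 2.0


def generate_tracks(scenario: TrajectoryScenario, domain=None) -> list[Track]:
    """Generate one batch of synthetic tracks.

    ``domain`` is a rod :class:`ContourScenario` for the circumferential
    kind (tracks run at ~90 deg to its midline, which lies along x), an
    optional ``(width, height)`` field for the planar kinds, or None for
    the default 100 x 100 um field.
    """
    rng = np.random.default_rng(scenario.seed)
    fi = scenario.frame_interval
    lo, hi = scenario.n_frames_range
    if isinstance(domain, tuple):
        field_w, field_h = map(float, domain)
    else:
        field_w = field_h = RANDOM_FIELD_SIZE_UM

    tracks: list[Track] = []
    if scenario.kind == "random_field":
        for i in range(scenario.n_tracks):
            angle = rng.uniform(0.0, 180.0)
            center = rng.uniform(0.0, [field_w, field_h])
            direction = np.array([math.cos(math.radians(angle)), math.sin(math.radians(angle))])
            start = center - 0.5 * RANDOM_FIELD_DISPLACEMENT_UM * direction
            tracks.append(
                _straight_track(
                    i, start, angle, RANDOM_FIELD_DISPLACEMENT_UM,
                    RANDOM_FIELD_VELOCITY_UM_S, fi, 0.0, rng,
                    meta={"r2_orth": RANDOM_FIELD_R2},
                )
            )
    elif scenario.kind in ("ballistic", "isotropic"):
        for i in range(scenario.n_tracks):
            angle = rng.uniform(0.0, 180.0)
            n_frames = int(rng.integers(lo, hi + 1))
            start = rng.uniform(0.0, [field_w, field_h])
            length = scenario.speed * (n_frames - 1) * fi
            tracks.append(
                _straight_track(i, start, angle, length, scenario.speed, fi,
                                scenario.localization_sigma, rng)
            )
    elif scenario.kind == "diffusive":
        for i in range(scenario.n_tracks):
            n_frames = int(rng.integers(lo, hi + 1))
            start = rng.uniform(0.0, [field_w, field_h])
            steps = rng.normal(0.0, math.sqrt(2 * scenario.diffusion_coeff * fi), (n_frames - 1, 2))
            pos = start + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
            if scenario.localization_sigma > 0:
                pos = pos + rng.normal(0.0, scenario.localization_sigma, pos.shape)
            tracks.append(Track(i, np.arange(n_frames), pos, fi))
    elif scenario.kind == "circumferential":
        if not (isinstance(domain, ContourScenario) and domain.kind == "rod"):
            raise ValueError("circumferential tracks need a rod contour domain")
        half_flank = (domain.length - domain.width) / 2.0
        for i in range(scenario.n_tracks):
            angle = 90.0 + _axial_von_mises(rng, scenario.angular_noise)
            n_frames = int(rng.integers(lo, hi + 1))
            start = np.array([
                rng.uniform(-half_flank, half_flank),
                rng.uniform(-0.4 * domain.width, 0.4 * domain.width),
            ])
            length = scenario.speed * (n_frames - 1) * fi
            tracks.append(
                _straight_track(i, start, angle, length, scenario.speed, fi,
                                scenario.localization_sigma, rng)
            )
    else:  # pragma: no cover - kinds validated at construction
        raise ValueError(f"unknown trajectory kind: {scenario.kind!r}")
    return tracks


def generate_msd_fixture(kind: str, *, speed: float = 0.025,
                         diffusion_coeff: float = 0.01, n_frames: int = 100,
                         frame_interval: float = 1.0, localization_sigma: float = 0.0,
                         angle_deg: float = 30.0, seed: int = 0) -> Track:
    """Single-track oracle input for MSD fits.

    Ballistic: exact straight drift at ``speed`` (MSD = (V t)^2 at zero
    noise).  Diffusive: a 2-D random walk with diffusion coefficient D
    (ensemble MSD -> 4 D t).  Zero speed and D give a stationary track.
    """
    rng = np.random.default_rng(seed)
    if kind == "ballistic":
        if speed < 0:
            raise ValueError("speed must be non-negative")
        t = np.arange(n_frames) * frame_interval
        direction = np.array([math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))])
        pos = np.outer(t * speed, direction)
    elif kind == "diffusive":
        if diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be non-negative")
        steps = rng.normal(0.0, math.sqrt(2 * diffusion_coeff * frame_interval), (n_frames - 1, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    else:
        raise ValueError(f"unknown MSD fixture kind: {kind!r}")
    if localization_sigma > 0:
        pos = pos + rng.normal(0.0, localization_sigma, pos.shape)
    elif localization_sigma < 0:
        raise ValueError("localization_sigma must be non-negative")
    return Track(0, np.arange(n_frames), pos, frame_interval)
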