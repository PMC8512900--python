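"""Parametric back-surface scenes with known ground truth.

The generator emulates the acquisition the detection pipeline was built
for: a standing subject seen from behind by a ToF camera (144 x 176
organized grid) at ~1.4-2 m, inside a device frame with vertical side
posts, performing anterior-posterior pelvic tilt at ~1 cycle/s.

The body is a stylized parametric relief, not an anthropometric mesh:

* horizontal cross-sections are shallow quartic reliefs whose half-width
  interpolates hip -> waist -> shoulder -> neck (PCHIP, so the waist
  knot is the exact minimum of the width profile);
* the sagittal midline z(y) is a C2 cubic spline through sacrum, sacral
  base, lumbar lordosis apex (deepest from the camera), thoracic
  kyphosis apex (nearest the camera) and neck;
* pelvic tilt shears the sub-lumbar midline about the lordosis knot by
  ``tilt_amplitude_deg * sin(phase)`` degrees;
* arms are capsules pivoted at the shoulders and abducted outward; the
  posterior axillary fold is an explicit groove whose top end is the
  ground-truth axilla;
* the device frame contributes two vertical posts.

Every ground-truth landmark is defined on the continuous surface
(extrema and inflections located by dense scan of the constructed
midline; widths by dense scan of the width interpolant), so rendered
frames come with exact per-frame truth and per-pixel labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.stats import truncnorm

from .io_formats import LandmarkSet, OrganizedFrame

LABEL_NONE, LABEL_SUBJECT, LABEL_DEVICE, LABEL_SPECKLE = 0, 1, 2, 3


@dataclass(frozen=True)
class Camera:
    """Pinhole camera of an SR4000-class sensor: organized grid plus
    horizontal/vertical field of view (degrees)."""

    shape: tuple[int, int] = (144, 176)
    fov_h_deg: float = 43.6
    fov_v_deg: float = 34.6
    height: float = 1.5  # mounting height above the floor, meters

    def ray_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel ray slopes (u, v): a point at depth z projects to
        (u*z, v*z, z) in camera coordinates."""
        h, w = self.shape
        tan_u = math.tan(math.radians(self.fov_h_deg) / 2)
        tan_v = math.tan(math.radians(self.fov_v_deg) / 2)
        u = tan_u * np.linspace(-1.0, 1.0, w)
        v = tan_v * np.linspace(1.0, -1.0, h)
        uu, vv = np.meshgrid(u, v)
        return uu, vv


@dataclass(frozen=True)
class BackModelParams:
    """Anthropometric and pose parameters of one synthetic subject.

    Widths are half-widths in meters; vertical stations are fractions
    of body height measured from the floor.  Defaults are the means of
    the sampling priors (young-adult cohort).
    """

    body_height: float = 1.742
    shoulder_half_width: float = 0.192
    waist_half_width: float = 0.125
    hip_half_width: float = 0.178
    waist_y_fraction: float = 0.65
    kyphosis_apex_y_fraction: float = 0.76
    kyphosis_depth: float = 0.025
    lordosis_apex_y_fraction: float = 0.66
    lordosis_depth: float = 0.030
    arm_abduction_deg: float = 22.0
    subject_depth: float = 1.78
    tilt_amplitude_deg: float = 6.0
    clothing_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("body_height", "shoulder_half_width", "waist_half_width",
                     "hip_half_width", "kyphosis_depth", "lordosis_depth",
                     "subject_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.waist_half_width >= self.shoulder_half_width:
            raise ValueError("waist_half_width must be below shoulder_half_width")
        for name in ("waist_y_fraction", "kyphosis_apex_y_fraction",
                     "lordosis_apex_y_fraction"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.kyphosis_apex_y_fraction <= self.lordosis_apex_y_fraction:
            raise ValueError("kyphosis apex must lie above the lordosis apex")


#: Sampling priors: (mean, sd, half-range in sd units) per field.  The
#: shoulder width and body height follow the reported cohort
#: anthropometry (38.4 +/- 2.7 cm shoulder width, 174.2 +/- 10.0 cm
#: stature).  The hip prior is the reported 28.5 +/- 1.9 cm bi-cristal
#: breadth inflated by ~25%: the rendered quantity is the soft-tissue
#: silhouette width at the trochanter, which exceeds the skeletal
#: breadth.  The remaining spreads are plausible young-adult variation.
_PRIORS: dict[str, tuple[float, float, float]] = {
    "body_height": (1.742, 0.080, 1.75),
    "shoulder_half_width": (0.192, 0.0135, 2.5),
    "waist_half_width": (0.125, 0.008, 2.5),
    "hip_half_width": (0.178, 0.012, 2.5),
    "waist_y_fraction": (0.65, 0.012, 2.0),
    "kyphosis_apex_y_fraction": (0.76, 0.012, 2.0),
    "kyphosis_depth": (0.025, 0.004, 2.0),
    "lordosis_apex_y_fraction": (0.66, 0.012, 2.0),
    "lordosis_depth": (0.030, 0.005, 2.0),
    "arm_abduction_deg": (22.0, 3.0, 2.0),
    "subject_depth": (1.78, 0.05, 2.0),
    "tilt_amplitude_deg": (6.0, 1.5, 2.0),
}


def sample_params(seed: int, overrides: dict | None = None) -> BackModelParams:
    """Draw subject parameters from truncated-normal priors.

    Deterministic in ``seed``; ``overrides`` pin individual fields and
    are validated against the model invariants.
    """
    rng = np.random.default_rng(seed)
    values: dict[str, float] = {"seed": seed}
    for name, (mean, sd, halfwidth) in _PRIORS.items():
        draw = truncnorm.rvs(-halfwidth, halfwidth, loc=mean, scale=sd,
                             random_state=rng)
        values[name] = float(draw)
    # keep the waist indentation anatomically present: strictly inside
    # both the shoulder and the hip widths
    values["waist_half_width"] = min(values["waist_half_width"],
                                     values["shoulder_half_width"] - 0.02,
                                     values["hip_half_width"] - 0.008)
    if overrides:
        values.update(overrides)
    return BackModelParams(**values)


@dataclass
class GroundTruth:
    """Exact landmark positions on the continuous surface plus per-pixel
    provenance labels of a rendered frame."""

    landmarks: LandmarkSet
    labels: np.ndarray | None = None


class BackSurface:
    """Continuous scene for one subject at one pelvic-tilt phase."""

    # vertical stations, fractions of body height from the floor
    STATION_BOTTOM = 0.40       # lower-limb region, below the camera's view
    STATION_HIP = 0.56
    STATION_S1 = 0.62
    STATION_CHEST = 0.81
    STATION_NECKBASE = 0.845
    STATION_TOP = 0.88

    NECK_HALF_WIDTH = 0.055
    FLANK_DEPTH = 0.02          # silhouette-edge relief depth
    FLANK_EXPONENT = 4
    SACRAL_DROP = 0.07          # sacrum recedes toward the camera below LL
    NECK_SETBACK = 0.02
    TOP_SETBACK = 0.035

    ARM_RADIUS = 0.045
    ARM_LENGTH = 0.30
    ARM_PIVOT_OUT = 0.012
    ARM_PIVOT_UP = 0.005
    ARM_Z_OFFSET = 0.01
    AXILLA_DROP = 0.045         # axilla below the widest chest station

    GROOVE_DEPTH = 0.08         # posterior axillary fold depth
    GROOVE_RAMP = 0.01
    GROOVE_LENGTH = 0.12
    GROOVE_SIGMA = 0.012
    GROOVE_X_FRACTION = 0.88

    POST_X = 0.45               # device frame side posts
    POST_RADIUS = 0.02

    def __init__(self, params: BackModelParams, tilt_phase: float = 0.0,
                 camera_height: float = 1.5, include_arms: bool = True,
                 include_posts: bool = True) -> None:
        self.params = params
        self.tilt_phase = float(tilt_phase)
        self.include_arms = include_arms
        self.include_posts = include_posts
        p = params
        self.y_floor = -camera_height
        st = lambda f: self.y_floor + f * p.body_height
        self.y_bottom = st(self.STATION_BOTTOM)
        self.y_hip = st(self.STATION_HIP)
        self.y_s1_knot = st(self.STATION_S1)
        self.y_waist = st(p.waist_y_fraction)
        self.y_ll = st(p.lordosis_apex_y_fraction)
        self.y_tk = st(p.kyphosis_apex_y_fraction)
        self.y_chest = st(self.STATION_CHEST)
        self.y_neckbase = st(self.STATION_NECKBASE)
        self.y_top = st(self.STATION_TOP)

        self._width = PchipInterpolator(
            [self.y_bottom, self.y_hip, self.y_waist, self.y_chest,
             self.y_neckbase, self.y_top],
            [p.hip_half_width, p.hip_half_width, p.waist_half_width,
             p.shoulder_half_width, self.NECK_HALF_WIDTH, self.NECK_HALF_WIDTH],
        )
        z0 = p.subject_depth
        self._midline = CubicSpline(
            [self.y_hip, self.y_s1_knot, self.y_ll, self.y_tk,
             self.y_neckbase, self.y_top],
            [z0 + p.lordosis_depth - self.SACRAL_DROP,
             z0 + p.lordosis_depth - 0.35 * self.SACRAL_DROP,
             z0 + p.lordosis_depth,
             z0 - p.kyphosis_depth,
             z0 - p.kyphosis_depth + self.NECK_SETBACK,
             z0 - p.kyphosis_depth + self.TOP_SETBACK],
            bc_type=((1, 0.05), (1, 0.25)),
        )
        self.tilt_angle = math.radians(p.tilt_amplitude_deg) * math.sin(self.tilt_phase)

        # arm geometry: pivot just outside the torso at the axilla level
        self.y_axilla = self.y_chest - self.AXILLA_DROP
        w_ax = float(self._width(self.y_axilla))
        self.x_axilla = self.GROOVE_X_FRACTION * w_ax
        theta = math.radians(p.arm_abduction_deg)
        self._arm_dir = np.array([math.sin(theta), -math.cos(theta)])
        self._arm_pivot_abs = np.array([w_ax + self.ARM_PIVOT_OUT,
                                        self.y_axilla + self.ARM_PIVOT_UP])
        self._arm_z = float(self._midline(self.y_axilla)) + self.ARM_Z_OFFSET
        self._groove_dir = self._arm_dir.copy()

        # dense lookup tables: ray-marching evaluates the surface millions
        # of times, where np.interp beats repeated spline evaluation
        self._ygrid = np.arange(self.y_bottom, self.y_top + 1e-3, 1e-3)
        self._wtab = np.asarray(self._width(self._ygrid), dtype=float)
        self._ztab = np.asarray(self.midline_z(self._ygrid), dtype=float)

    # -- continuous geometry -------------------------------------------------

    def width(self, y):
        """Half-width of the body silhouette at height ``y``."""
        y = np.asarray(y, dtype=float)
        w = self._width(y)
        return np.where((y >= self.y_bottom) & (y <= self.y_top), w, np.nan)

    def midline_z(self, y):
        """Sagittal midline depth z(y) including the pelvic-tilt shear.

        Below the sacral end of the spline the midline continues
        linearly (C1, zero curvature), so the lowest inflection of the
        profile remains the sacral one.
        """
        y = np.asarray(y, dtype=float)
        z = self._midline(y)
        z_hip = float(self._midline(self.y_hip))
        s_hip = float(self._midline(self.y_hip, 1))
        z = np.where(y < self.y_hip, z_hip + s_hip * (y - self.y_hip), z)
        shear = math.tan(self.tilt_angle) * (self.y_ll - y)
        return np.where(y < self.y_ll, z + shear, z)

    def torso_z(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        w = np.interp(y, self._ygrid, self._wtab)
        with np.errstate(invalid="ignore", divide="ignore"):
            q = np.abs(x) / w
        inside = (y >= self.y_bottom) & (y <= self.y_top) & (q <= 1.0)
        z = np.interp(y, self._ygrid, self._ztab) + \
            self.FLANK_DEPTH * q ** self.FLANK_EXPONENT
        if self.params.clothing_amplitude:
            lowband = y < self.y_waist + 0.03
            ripple = self.params.clothing_amplitude * np.sin(
                2 * np.pi * (y - self.y_s1_knot) / 0.10)
            z = np.where(lowband, z + ripple, z)
        return np.where(inside, z, np.nan)

    def arm_z(self, x, y, side: int):
        """Front surface of one arm capsule; ``side`` is -1 (left) or +1."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        pivot = self._arm_pivot_abs * np.array([side, 1.0])
        direction = self._arm_dir * np.array([side, 1.0])
        relx = x - pivot[0]
        rely = y - pivot[1]
        t = np.clip(relx * direction[0] + rely * direction[1], 0.0, self.ARM_LENGTH)
        dx = relx - t * direction[0]
        dy = rely - t * direction[1]
        rho2 = dx * dx + dy * dy
        inside = rho2 <= self.ARM_RADIUS ** 2
        with np.errstate(invalid="ignore"):
            z = self._arm_z - np.sqrt(np.maximum(self.ARM_RADIUS ** 2 - rho2, 0.0))
        return np.where(inside, z, np.nan)

    def groove_displacement(self, x, y):
        """Depth added by the posterior axillary folds (both sides)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        total = np.zeros(np.broadcast(x, y).shape)
        for side in (-1, 1):
            direction = self._groove_dir * np.array([side, 1.0])
            # the fold ramps in above the axilla and attains full depth
            # exactly at the ground-truth point
            top = np.array([side * self.x_axilla, self.y_axilla]) \
                - self.GROOVE_RAMP * direction
            relx = x - top[0]
            rely = y - top[1]
            t = np.clip(relx * direction[0] + rely * direction[1],
                        0.0, self.GROOVE_LENGTH)
            dx = relx - t * direction[0]
            dy = rely - t * direction[1]
            d2 = dx * dx + dy * dy
            u = np.clip(t / self.GROOVE_RAMP, 0.0, 1.0)
            amp = self.GROOVE_DEPTH * u * u * (3 - 2 * u)
            total = total + amp * np.exp(-d2 / (2 * self.GROOVE_SIGMA ** 2))
        return total

    def subject_z(self, x, y):
        """Depth of the subject surface (torso plus arms plus fold grooves)."""
        z = self.torso_z(x, y)
        if self.include_arms:
            for side in (-1, 1):
                za = self.arm_z(x, y, side)
                z = np.where(np.isnan(z) | (za < z), za, z)
        return z + self.groove_displacement(x, y)

    def device_z(self, x, y):
        x = np.asarray(x, dtype=float)
        z = np.full(np.broadcast(x, np.asarray(y)).shape, np.nan)
        for side in (-1, 1):
            dx = x - side * self.POST_X
            inside = np.abs(dx) <= self.POST_RADIUS
            with np.errstate(invalid="ignore"):
                zp = self.params.subject_depth - np.sqrt(
                    np.maximum(self.POST_RADIUS ** 2 - dx * dx, 0.0))
            z = np.where(inside & (~(zp >= z)), zp, z)
        return z

    # -- ground truth --------------------------------------------------------

    def _profile_landmarks(self) -> dict[str, float]:
        """Dense-scan the constructed midline for its extrema/inflection."""
        y = np.arange(self.y_hip + 0.005, self.y_top - 0.005, 1e-4)
        z = np.asarray(self.midline_z(y))
        dz = np.diff(z)
        sign = np.sign(dz)
        turning = np.nonzero(sign[:-1] * sign[1:] < 0)[0] + 1
        minima = [i for i in turning if z[i] <= z[i - 1] and z[i] <= z[i + 1]]
        maxima = [i for i in turning if z[i] >= z[i - 1] and z[i] >= z[i + 1]]
        if not minima or not maxima:
            raise RuntimeError("constructed midline lacks the expected extrema")
        y_tk = max(y[i] for i in minima)
        below = [y[i] for i in maxima if y[i] < y_tk]
        if not below:
            raise RuntimeError("no lordosis apex below the kyphosis apex")
        y_ll = max(below)
        d2 = np.diff(z, 2)
        s2 = np.sign(d2)
        infl = np.nonzero(s2[:-1] * s2[1:] < 0)[0] + 1
        if len(infl) == 0:
            raise RuntimeError("constructed midline has no inflection")
        y_s1 = float(y[infl[0] + 1])
        return {"y_TK": float(y_tk), "y_LL": float(y_ll), "y_S1": y_s1}

    def _waist_truth(self) -> tuple[float, float]:
        y = np.arange(self.y_hip + 0.02, self.y_chest - 0.02, 1e-4)
        w = np.asarray(self._width(y))
        i = int(np.argmin(w))
        return float(y[i]), float(w[i])

    def _shoulder_truth_y(self) -> float:
        """Topmost surface height at the axilla's x coordinate."""
        from scipy.optimize import brentq

        x_a = self.x_axilla
        w_chest = float(self._width(self.y_chest))
        if x_a < self.NECK_HALF_WIDTH:
            y_torso = self.y_top
        elif x_a >= w_chest:
            y_torso = self.y_chest
        else:
            y_torso = brentq(lambda y: float(self._width(y)) - x_a,
                             self.y_chest, self.y_neckbase)
        y_best = float(y_torso)
        if self.include_arms:
            dx = abs(x_a - self._arm_pivot_abs[0])
            if dx < self.ARM_RADIUS:
                y_arm = self._arm_pivot_abs[1] + math.sqrt(
                    self.ARM_RADIUS ** 2 - dx * dx)
                y_best = max(y_best, float(y_arm))
        return y_best

    def ground_truth(self) -> LandmarkSet:
        """Exact landmark positions on the continuous surface."""
        ls = LandmarkSet()
        prof = self._profile_landmarks()
        for name, y in (("TK", prof["y_TK"]), ("LL", prof["y_LL"]),
                        ("S1", prof["y_S1"])):
            ls[name] = [0.0, y, float(self.midline_z(y))]
        y_w, w_w = self._waist_truth()
        z_w = float(self.midline_z(y_w)) + self.FLANK_DEPTH
        ls["WL"] = [-w_w, y_w, z_w]
        ls["WR"] = [w_w, y_w, z_w]
        if self.include_arms:
            z_ax = float(self.subject_z(self.x_axilla, self.y_axilla))
            ls["AL"] = [-self.x_axilla, self.y_axilla, z_ax]
            ls["AR"] = [self.x_axilla, self.y_axilla, z_ax]
            y_s = self._shoulder_truth_y()
            z_s = float(self.midline_z(y_s)) + self.FLANK_DEPTH
            ls["SL"] = [-self.x_axilla, y_s, z_s]
            ls["SR"] = [self.x_axilla, y_s, z_s]
            ls["C7T1"] = [0.0, y_s, float(self.midline_z(y_s))]
        return ls


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _march_field(field, u: np.ndarray, v: np.ndarray, z_lo: float, z_hi: float,
                 step: float = 0.004, iters: int = 30) -> np.ndarray:
    """First intersection depth of each pixel ray with a depth field.

    ``field(x, y)`` returns the surface depth at a lateral position (NaN
    where no surface exists).  Along a ray the residual
    ``g(z) = field(u z, v z) - z`` starts positive in front of the
    surface; the first sign change brackets the hit, refined by
    bisection.  Returns NaN for rays that miss.
    """
    zs = np.arange(z_lo, z_hi + step, step)
    uf = u.ravel()[:, None]
    vf = v.ravel()[:, None]
    g = field(uf * zs[None, :], vf * zs[None, :]) - zs[None, :]
    crossing = (g[:, :-1] > 0) & (g[:, 1:] <= 0)
    has = crossing.any(axis=1)
    first = np.argmax(crossing, axis=1)
    lo = zs[first].astype(float)
    hi = zs[first + 1].astype(float)
    idx = np.nonzero(has)[0]
    lo, hi = lo[idx], hi[idx]
    uu, vv = u.ravel()[idx], v.ravel()[idx]
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        gm = field(uu * mid, vv * mid) - mid
        gm = np.where(np.isnan(gm), 1.0, gm)
        take_hi = gm <= 0
        hi = np.where(take_hi, mid, hi)
        lo = np.where(take_hi, lo, mid)
    z_hit = 0.5 * (lo + hi)
    # rays straddling a depth discontinuity (occlusion seams) bracket a
    # jump, not a root; a real ToF sensor returns unreliable "flying
    # pixels" there, which we drop
    resid = np.abs(field(uu * z_hit, vv * z_hit) - z_hit)
    ok = np.isfinite(resid) & (resid <= 1e-7)
    out = np.full(u.size, np.nan)
    out[idx[ok]] = z_hit[ok]
    return out.reshape(u.shape)


def render_frame(surface: BackSurface, camera: Camera | None = None,
                 noise_sigma: float = 0.004, speckle_rate: float = 0.01,
                 seed: int | np.random.Generator = 0,
                 timestamp: float | None = None
                 ) -> tuple[OrganizedFrame, GroundTruth]:
    """Ray-cast the scene onto the organized grid and add sensor noise.

    Gaussian depth noise of ``noise_sigma`` (meters) and a
    ``speckle_rate`` fraction of speckle outliers displaced along their
    ray by 0.1-0.5 m are applied per pixel; noise moves points along
    the ray, as depth errors of a ToF sensor do.  Returns the frame and
    the ground truth (landmarks plus per-pixel labels).
    """
    camera = camera or Camera()
    if surface.params.subject_depth <= 0:
        raise ValueError("surface must lie in front of the camera")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u, v = camera.ray_grids()
    z0 = surface.params.subject_depth
    z_lo, z_hi = z0 - 0.16, z0 + 0.19
    depth = _march_field(surface.subject_z, u, v, z_lo, z_hi)
    labels = np.where(np.isfinite(depth), LABEL_SUBJECT, LABEL_NONE).astype(np.int8)
    if surface.include_posts:
        dev = _march_field(surface.device_z, u, v, z_lo, z_hi)
        closer = np.isfinite(dev) & (~np.isfinite(depth) | (dev < depth))
        depth = np.where(closer, dev, depth)
        labels[closer] = LABEL_DEVICE
    valid = np.isfinite(depth)

    z = depth.copy()
    if noise_sigma > 0:
        z = z + np.where(valid, rng.normal(0.0, noise_sigma, z.shape), 0.0)
    if speckle_rate > 0:
        hit = np.nonzero(valid.ravel())[0]
        n_speckle = int(round(speckle_rate * hit.size))
        if n_speckle:
            pick = rng.choice(hit, size=n_speckle, replace=False)
            shift = rng.uniform(0.1, 0.5, n_speckle) * rng.choice([-1.0, 1.0], n_speckle)
            zf = z.ravel()
            zf[pick] = zf[pick] + shift
            z = zf.reshape(z.shape)
            lab = labels.ravel()
            lab[pick] = LABEL_SPECKLE
            labels = lab.reshape(labels.shape)
    z = np.where(valid, np.maximum(z, 0.0), np.nan)
    frame = OrganizedFrame(x=u * z, y=v * z, z=z, valid=valid, timestamp=timestamp)
    return frame, GroundTruth(landmarks=surface.ground_truth(), labels=labels)


def render_frames(surface: BackSurface, n: int, camera: Camera | None = None,
                  noise_sigma: float = 0.004, speckle_rate: float = 0.01,
                  seed: int = 0) -> tuple[list[OrganizedFrame], GroundTruth]:
    """``n`` noise realizations of one frozen pose (single ray-cast).

    Models the frame-averaging window of a static instant: the scene is
    cast once and each frame draws independent sensor noise.
    """
    camera = camera or Camera()
    rng = np.random.default_rng(seed)
    u, v = camera.ray_grids()
    z0 = surface.params.subject_depth
    depth = _march_field(surface.subject_z, u, v, z0 - 0.16, z0 + 0.19)
    labels = np.where(np.isfinite(depth), LABEL_SUBJECT, LABEL_NONE).astype(np.int8)
    if surface.include_posts:
        dev = _march_field(surface.device_z, u, v, z0 - 0.16, z0 + 0.19)
        closer = np.isfinite(dev) & (~np.isfinite(depth) | (dev < depth))
        depth = np.where(closer, dev, depth)
        labels[closer] = LABEL_DEVICE
    valid = np.isfinite(depth)
    frames = []
    for k in range(n):
        z = depth + np.where(valid, rng.normal(0.0, noise_sigma, depth.shape), 0.0)
        if speckle_rate > 0:
            hit = np.nonzero(valid.ravel())[0]
            n_speckle = int(round(speckle_rate * hit.size))
            if n_speckle:
                pick = rng.choice(hit, size=n_speckle, replace=False)
                shift = rng.uniform(0.1, 0.5, n_speckle) * rng.choice(
                    [-1.0, 1.0], n_speckle)
                zf = z.ravel()
                zf[pick] = zf[pick] + shift
                z = zf.reshape(z.shape)
        z = np.where(valid, np.maximum(z, 0.0), np.nan)
        frames.append(OrganizedFrame(x=u * z, y=v * z, z=z, valid=valid,
                                     timestamp=float(k)))
    return frames, GroundTruth(landmarks=surface.ground_truth(), labels=labels)


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------


def select_evaluation_frames(duration_s: float, fps: float) -> list[int]:
    """Frame indices sampled every 10 s (first at 5 s), mirroring the
    evaluation protocol of an 80 s recording: 10 s preparation, 60 s of
    exercise, 10 s rest, eight frames at 10 s intervals."""
    times = np.arange(5.0, duration_s, 10.0)
    return [int(round(t * fps)) for t in times]


def validation_dataset_size(n_subjects: int = 53, duration_s: float = 80.0,
                            fps: float = 30.0) -> int:
    """Number of evaluation clouds the sampling scheme yields."""
    return n_subjects * len(select_evaluation_frames(duration_s, fps))


@dataclass
class Session:
    """A recorded pelvic-tilt session: frame times with tilt phases and
    lazily computed per-frame ground truth / renders."""

    params: BackModelParams
    duration_s: float
    fps: float
    seed: int
    camera: Camera = field(default_factory=Camera)
    noise_sigma: float = 0.004
    speckle_rate: float = 0.01
    tilt_frequency_hz: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration and fps must be positive")
        self.times = np.arange(int(round(self.duration_s * self.fps))) / self.fps
        self.evaluation_indices = select_evaluation_frames(self.duration_s, self.fps)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def tilt_phase(self, index: int) -> float:
        return 2 * math.pi * self.tilt_frequency_hz * float(self.times[index])

    def surface(self, index: int) -> BackSurface:
        return BackSurface(self.params, tilt_phase=self.tilt_phase(index),
                           camera_height=self.camera.height)

    def ground_truth(self, index: int) -> LandmarkSet:
        return self.surface(index).ground_truth()

    def render(self, index: int) -> tuple[OrganizedFrame, GroundTruth]:
        return render_frame(self.surface(index), self.camera,
                            noise_sigma=self.noise_sigma,
                            speckle_rate=self.speckle_rate,
                            seed=np.random.default_rng((self.seed, index)),
                            timestamp=float(self.times[index]))

    def iter_frames(self) -> Iterator[tuple[OrganizedFrame, GroundTruth]]:
        for i in range(self.n_frames):
            yield self.render(i)


def simulate_session(params: BackModelParams, duration_s: float = 80.0,
                     fps: float = 30.0, seed: int = 0,
                     camera: Camera | None = None, **kwargs) -> Session:
    """Create a pelvic-tilt session (1 cycle/s) for one subject."""
    return Session(params=params, duration_s=duration_s, fps=fps, seed=seed,
                   camera=camera or Camera(), **kwargs)
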