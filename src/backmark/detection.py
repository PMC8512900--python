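"""Landmark detection on a segmented subject cloud.

The ten landmarks are found by local surface analysis, in dependency
order: a horizontal band at the cloud centroid separates torso from
arms; lateral plane fits locate the axillae (AL/AR) as the top of the
deep fold behind the fitted arm/flank plane; the shoulders (SL/SR) are
the highest points in narrow belts at the axilla x positions; the
cervicothoracic junction (C7-T1) is the cloud point nearest the
shoulder-line midpoint in the frontal plane; a polynomial fit to the
sagittal spine band yields the thoracic-kyphosis and lumbar-lordosis
apices (TK, LL: extrema of z(y)) and the sacral base (S1: the lowest
inflection), each mapped back to the surface; the waist points (WL/WR)
are the minimal-half-width silhouette edges between S1 and the axillae.

Failures are data, not exceptions: :func:`detect_landmarks` always
returns a total :class:`~backmark.io_formats.LandmarkSet`, recording a
reason for each landmark it could not place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from sklearn.base import BaseEstimator

from .config import DetectionConfig
from .io_formats import LANDMARK_NAMES, LandmarkFailure, LandmarkSet, PointCloud
from .preprocessing import _as_points, dbscan

logger = logging.getLogger(__name__)


class DetectionFailure(RuntimeError):
    """A detection step could not produce its landmark; carries the
    machine-readable reason recorded in the landmark set."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class SpineProfile:
    """Polynomial approximation z(y) of the sagittal spine band."""

    poly: np.polynomial.Polynomial
    fit_domain: tuple[float, float]
    rss: float

    def __post_init__(self) -> None:
        if self.poly.degree() < 4:
            raise ValueError("spine profile requires degree >= 4")
        if not self.fit_domain[0] < self.fit_domain[1]:
            raise ValueError("degenerate fit domain")

    @property
    def poly_coeffs(self) -> np.ndarray:
        """Coefficients in the plain power basis, ascending order."""
        return self.poly.convert().coef

    def __call__(self, y):
        y = np.asarray(y, dtype=float)
        lo, hi = self.fit_domain
        if np.any((y < lo - 1e-12) | (y > hi + 1e-12)):
            raise ValueError("profile evaluated outside its fit domain")
        return self.poly(y)


@dataclass
class DetectionContext:
    """Intermediate state shared between detection steps."""

    aux_left: np.ndarray
    aux_right: np.ndarray
    torso_x_range: tuple[float, float]
    diagnostics: dict = dataclass_field(default_factory=dict)


def find_arm_boundaries(cloud, config: DetectionConfig | None = None) -> DetectionContext:
    """Locate the trunk/arm boundary from a band at the centroid height.

    The band is clustered with DBSCAN; the largest cluster is the
    torso, whose lateral extreme points become the auxiliary boundary
    points, and whose x extent is the torso range.
    """
    cfg = config or DetectionConfig()
    pts = _as_points(cloud)
    if len(pts) < cfg.min_cloud_points:
        raise DetectionFailure("cloud_too_small")
    yc = pts[:, 1].mean()
    band = pts[np.abs(pts[:, 1] - yc) <= cfg.centroid_band_halfwidth]
    if len(band) < cfg.min_cluster_size:
        raise DetectionFailure("arms_inseparable")
    labels = dbscan(band, cfg.dbscan_epsilon, cfg.dbscan_min_points)
    ids, counts = np.unique(labels[labels >= 0], return_counts=True)
    if len(ids) == 0 or counts.max() < cfg.min_cluster_size:
        raise DetectionFailure("arms_inseparable")
    torso = band[labels == ids[np.argmax(counts)]]
    aux_left = torso[np.argmin(torso[:, 0])]
    aux_right = torso[np.argmax(torso[:, 0])]
    return DetectionContext(
        aux_left=aux_left.copy(), aux_right=aux_right.copy(),
        torso_x_range=(float(torso[:, 0].min()), float(torso[:, 0].max())),
        diagnostics={"centroid_y": float(yc), "band_size": len(band),
                     "torso_size": len(torso)},
    )


def _fit_plane(pts: np.ndarray) -> np.ndarray:
    """Least-squares plane z = a x + b y + c; returns (a, b, c)."""
    design = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    coeffs, *_ = np.linalg.lstsq(design, pts[:, 2], rcond=None)
    return coeffs


def detect_axilla(cloud, context: DetectionContext, side: str,
                  config: DetectionConfig | None = None) -> np.ndarray:
    """Top of the deep axillary fold on one side.

    A plane is fitted to the lateral fragment beyond the side's
    auxiliary point; points lying behind it (larger z, away from the
    camera) by at least the distance threshold form the fold object,
    whose highest point is the axilla.
    """
    cfg = config or DetectionConfig()
    pts = _as_points(cloud)
    if side == "left":
        fragment = pts[pts[:, 0] < context.aux_left[0]]
    elif side == "right":
        fragment = pts[pts[:, 0] > context.aux_right[0]]
    else:
        raise ValueError("side must be 'left' or 'right'")
    if len(fragment) < cfg.dbscan_min_points:
        raise DetectionFailure("axilla_not_found")
    a, b, c = _fit_plane(fragment)
    residual = fragment[:, 2] - (a * fragment[:, 0] + b * fragment[:, 1] + c)
    deep = fragment[residual >= cfg.under_plane_threshold]
    if len(deep) == 0:
        raise DetectionFailure("axilla_not_found")
    labels = dbscan(deep, cfg.dbscan_epsilon, cfg.dbscan_min_points)
    ids, counts = np.unique(labels[labels >= 0], return_counts=True)
    if len(ids) == 0:
        raise DetectionFailure("axilla_not_found")
    obj = deep[labels == ids[np.argmax(counts)]]
    top = obj[np.argmax(obj[:, 1])]
    context.diagnostics[f"axilla_{side}_object_size"] = len(obj)
    return top.copy()


def detect_shoulder(cloud, axilla: np.ndarray, side: str,
                    config: DetectionConfig | None = None) -> np.ndarray:
    """Highest point in the belt centered on the axilla's x coordinate.

    Ties are resolved toward the axilla x, then toward the camera.
    """
    cfg = config or DetectionConfig()
    pts = _as_points(cloud)
    belt = pts[np.abs(pts[:, 0] - axilla[0]) <= cfg.shoulder_belt_halfwidth]
    if len(belt) == 0:
        raise DetectionFailure("shoulder_not_found")
    order = np.lexsort((belt[:, 2], np.abs(belt[:, 0] - axilla[0]), -belt[:, 1]))
    return belt[order[0]].copy()


def detect_c7t1(cloud, shoulder_left: np.ndarray, shoulder_right: np.ndarray
                ) -> np.ndarray:
    """Cloud point closest, in the frontal (xy) plane, to the midpoint
    of the shoulder line; ties resolved by lowest point index."""
    pts = _as_points(cloud)
    if len(pts) == 0:
        raise DetectionFailure("c7t1_not_found")
    target = 0.5 * (shoulder_left[:2] + shoulder_right[:2])
    d2 = (pts[:, 0] - target[0]) ** 2 + (pts[:, 1] - target[1]) ** 2
    return pts[np.argmin(d2)].copy()


def extract_spine_band(cloud, c7t1: np.ndarray,
                       config: DetectionConfig | None = None) -> PointCloud:
    """Narrow vertical band below C7-T1 containing the spine-line points."""
    cfg = config or DetectionConfig()
    pts = _as_points(cloud)
    mask = (np.abs(pts[:, 0] - c7t1[0]) <= cfg.spine_band_halfwidth) & \
           (pts[:, 1] <= c7t1[1])
    band = pts[mask]
    if len(band) < 4 * (cfg.polynomial_degree + 1):
        raise DetectionFailure("spine_band_sparse")
    return PointCloud(band)


def fit_sagittal_profile(band, degree: int = 5) -> SpineProfile:
    """Least-squares polynomial z(y) over the spine band."""
    if degree < 4:
        raise ValueError("degree must be at least 4")
    pts = _as_points(band)
    y, z = pts[:, 1], pts[:, 2]
    if np.ptp(y) < 1e-9:
        raise ValueError("all band points at the same height; fit is rank-deficient")
    poly = np.polynomial.Polynomial.fit(y, z, degree)
    rss = float(np.sum((poly(y) - z) ** 2))
    return SpineProfile(poly=poly, fit_domain=(float(y.min()), float(y.max())),
                        rss=rss)


def locate_profile_landmarks(profile: SpineProfile) -> dict[str, float]:
    """Heights of TK, LL and S1 on the fitted sagittal profile.

    TK is the local minimum of z(y) (apex nearest the camera) with the
    greatest y; LL the local maximum below it; S1 the inflection with
    the smallest y.  Roots of the derivative polynomials are taken from
    companion-matrix eigenvalues; roots closer than 1e-9 coincide.
    """
    lo, hi = profile.fit_domain
    dp = profile.poly.deriv()
    d2p = dp.deriv()

    def real_roots(p) -> np.ndarray:
        roots = p.roots()
        roots = roots[np.abs(roots.imag) < 1e-9].real
        roots = roots[(roots >= lo) & (roots <= hi)]
        roots = np.sort(roots)
        if len(roots) > 1:
            keep = np.concatenate([[True], np.diff(roots) > 1e-9])
            roots = roots[keep]
        return roots

    crit = real_roots(dp)
    curvature = d2p(crit)
    minima = crit[curvature > 0]
    maxima = crit[curvature < 0]
    if len(minima) == 0:
        raise DetectionFailure("TK_not_found")
    y_tk = float(minima.max())
    below = maxima[maxima < y_tk]
    if len(below) == 0:
        raise DetectionFailure("LL_not_found")
    y_ll = float(below.max())
    inflections = real_roots(d2p)
    if len(inflections) == 0:
        raise DetectionFailure("S1_not_found")
    y_s1 = float(inflections.min())
    return {"y_TK": y_tk, "y_LL": y_ll, "y_S1": y_s1}


def map_to_surface(cloud, y_target: float, x_center: float | None = None,
                   config: DetectionConfig | None = None) -> np.ndarray:
    """Nearest cloud point, in xy, to (x_center, y_target) within a
    horizontal slab around the target height.

    When ``x_center`` is not given it defaults to the midpoint of the
    slab's x extent.  Ties resolved by lowest index.
    """
    cfg = config or DetectionConfig()
    pts = _as_points(cloud)
    slab = pts[np.abs(pts[:, 1] - y_target) <= cfg.surface_slab_halfwidth]
    if len(slab) == 0:
        raise DetectionFailure("surface_slab_empty")
    if x_center is None:
        x_center = 0.5 * (slab[:, 0].min() + slab[:, 0].max())
    d2 = (slab[:, 0] - x_center) ** 2 + (slab[:, 1] - y_target) ** 2
    return slab[np.argmin(d2)].copy()


def detect_waist(cloud, context: DetectionContext, y_s1: float,
                 y_axilla_min: float, config: DetectionConfig | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Waist indentation points: the minimal-half-width silhouette
    edges between the sacral base and the axillae.

    The search band is the lower 60% of the S1-to-axilla interval,
    restricted laterally to the torso range (excluding the arms); the
    per-side width profile over 1 cm bins is smoothed with a 3-bin
    moving average before taking its minimum.
    """
    cfg = config or DetectionConfig()
    pts = _as_points(cloud)
    y_hi = y_s1 + 0.6 * (y_axilla_min - y_s1)
    x_lo = context.torso_x_range[0] - 0.01
    x_hi = context.torso_x_range[1] + 0.01
    sel = (pts[:, 1] >= y_s1) & (pts[:, 1] <= y_hi) & \
          (pts[:, 0] >= x_lo) & (pts[:, 0] <= x_hi)
    region = pts[sel]
    if len(region) == 0:
        raise DetectionFailure("waist_not_found")
    bins = np.floor((region[:, 1] - y_s1) / cfg.waist_bin_height).astype(int)

    results = []
    for side_sign in (-1, 1):
        extremes: dict[int, int] = {}
        counts: dict[int, int] = {}
        for i, b in enumerate(bins):
            counts[b] = counts.get(b, 0) + 1
            x = region[i, 0] * side_sign
            if b not in extremes or x > region[extremes[b], 0] * side_sign:
                extremes[b] = i
        # a bin is usable when enough points support its edge estimate
        order = sorted(b for b in extremes if counts[b] >= 5)
        if len(order) < 5:
            raise DetectionFailure("waist_not_found")
        widths = np.array([abs(region[extremes[b], 0]) for b in order])
        k = cfg.waist_smooth_bins
        kernel = np.ones(k) / k
        smooth = np.convolve(widths, kernel, mode="same")
        # guard the convolution edges, where fewer bins contribute
        half = k // 2
        smooth[:half] = smooth[half]
        smooth[len(smooth) - half:] = smooth[len(smooth) - half - 1]
        if np.ptp(smooth) < 0.002:
            raise DetectionFailure("waist_indistinct")
        # the sensor's lateral quantization flattens the trough into a
        # plateau; take the central bin of the near-minimal plateau
        plateau = np.nonzero(smooth <= smooth.min() + 0.002)[0]
        best = int(plateau[len(plateau) // 2])
        results.append(region[extremes[order[best]]].copy())
    wl, wr = (results[0], results[1])
    return wl, wr


def detect_landmarks(cloud, config: DetectionConfig | None = None) -> LandmarkSet:
    """Run the full detection chain; failures propagate as recorded
    reasons, never exceptions, so anatomically odd input yields a
    partial landmark set."""
    cfg = config or DetectionConfig()
    ls = LandmarkSet()

    def fail(names: list[str], reason: str) -> None:
        for n in names:
            ls[n] = LandmarkFailure(reason)

    try:
        context = find_arm_boundaries(cloud, cfg)
    except DetectionFailure as exc:
        fail(list(LANDMARK_NAMES), exc.reason)
        return ls

    axillae = {}
    for side, name in (("left", "AL"), ("right", "AR")):
        try:
            axillae[name] = detect_axilla(cloud, context, side, cfg)
            ls[name] = axillae[name]
        except DetectionFailure as exc:
            ls[name] = LandmarkFailure(exc.reason)

    shoulders = {}
    for axn, shn in (("AL", "SL"), ("AR", "SR")):
        if axn not in axillae:
            ls[shn] = LandmarkFailure(f"prerequisite_failed:{axn}")
            continue
        try:
            shoulders[shn] = detect_shoulder(cloud, axillae[axn], shn, cfg)
            ls[shn] = shoulders[shn]
        except DetectionFailure as exc:
            ls[shn] = LandmarkFailure(exc.reason)

    if {"SL", "SR"} <= shoulders.keys():
        try:
            c7t1 = detect_c7t1(cloud, shoulders["SL"], shoulders["SR"])
            ls["C7T1"] = c7t1
        except DetectionFailure as exc:
            c7t1 = None
            ls["C7T1"] = LandmarkFailure(exc.reason)
    else:
        c7t1 = None
        ls["C7T1"] = LandmarkFailure("prerequisite_failed:shoulders")

    heights = None
    if c7t1 is not None:
        try:
            band = extract_spine_band(cloud, c7t1, cfg)
            profile = fit_sagittal_profile(band, cfg.polynomial_degree)
            heights = locate_profile_landmarks(profile)
            for key, name in (("y_TK", "TK"), ("y_LL", "LL"), ("y_S1", "S1")):
                try:
                    ls[name] = map_to_surface(cloud, heights[key], None, cfg)
                except DetectionFailure as exc:
                    ls[name] = LandmarkFailure(exc.reason)
        except (DetectionFailure, ValueError) as exc:
            reason = exc.reason if isinstance(exc, DetectionFailure) else "spine_fit_failed"
            fail(["TK", "LL", "S1"], reason)
    else:
        fail(["TK", "LL", "S1"], "prerequisite_failed:C7T1")

    if heights is not None and ls.is_present("S1") and axillae:
        y_ax_min = min(p[1] for p in axillae.values())
        try:
            wl, wr = detect_waist(cloud, context, float(ls.position("S1")[1]),
                                  float(y_ax_min), cfg)
            ls["WL"], ls["WR"] = wl, wr
        except DetectionFailure as exc:
            fail(["WL", "WR"], exc.reason)
    else:
        fail(["WL", "WR"], "prerequisite_failed:S1_or_axilla")

    logger.info("detected %d/10 landmarks", len(ls.present()))
    return ls


class LandmarkDetector(BaseEstimator):
    """Estimator wrapper around the detection chain.

    ``fit`` validates parameters (detection is training-free);
    ``predict`` maps one segmented subject cloud, or a sequence of
    clouds, to landmark sets.
    """

    def __init__(self, centroid_band_halfwidth: float = 0.02,
                 dbscan_epsilon: float = 0.03, dbscan_min_points: int = 10,
                 under_plane_threshold: float = 0.01,
                 shoulder_belt_halfwidth: float = 0.01,
                 spine_band_halfwidth: float = 0.025,
                 polynomial_degree: int = 5,
                 surface_slab_halfwidth: float = 0.02):
        self.centroid_band_halfwidth = centroid_band_halfwidth
        self.dbscan_epsilon = dbscan_epsilon
        self.dbscan_min_points = dbscan_min_points
        self.under_plane_threshold = under_plane_threshold
        self.shoulder_belt_halfwidth = shoulder_belt_halfwidth
        self.spine_band_halfwidth = spine_band_halfwidth
        self.polynomial_degree = polynomial_degree
        self.surface_slab_halfwidth = surface_slab_halfwidth

    def _config(self) -> DetectionConfig:
        return DetectionConfig(
            centroid_band_halfwidth=self.centroid_band_halfwidth,
            dbscan_epsilon=self.dbscan_epsilon,
            dbscan_min_points=self.dbscan_min_points,
            under_plane_threshold=self.under_plane_threshold,
            shoulder_belt_halfwidth=self.shoulder_belt_halfwidth,
            spine_band_halfwidth=self.spine_band_halfwidth,
            polynomial_degree=self.polynomial_degree,
            surface_slab_halfwidth=self.surface_slab_halfwidth,
        )

    def fit(self, X=None, y=None):
        if self.polynomial_degree < 4:
            raise ValueError("polynomial_degree must be at least 4")
        self.config_ = self._config()
        return self

    def predict(self, X):
        if not hasattr(self, "config_"):
            self.fit()
        if isinstance(X, (PointCloud, np.ndarray)):
            return detect_landmarks(X, self.config_)
        return [detect_landmarks(cloud, self.config_) for cloud in X]
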