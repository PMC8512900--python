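"""Preprocessing of raw ToF frame streams into a denoised subject silhouette.

Stages, in pipeline order:

1. temporal averaging of ``n`` successive organized frames (noise
   variance drops roughly as 1/n at the cost of time resolution);
2. depth limiting (scene cutoff at 2 m);
3. spherical-neighborhood outlier removal;
4. one-time ROI calibration — DBSCAN separates the subject's lower
   limbs from the device frame's side posts in a 10 cm bottom band, and
   the inner faces of the posts define the x interval of the device
   interior;
5. silhouette segmentation — x-crop to the ROI followed by a second,
   tighter neighborhood filter.

All filters are extractive: they only select subsets of the input
points, never move them.  Each stage exists both as a plain function
and as a scikit-learn style transformer operating on ``(n, 3)`` arrays
or :class:`~backmark.io_formats.PointCloud` objects, so stages compose
with :class:`sklearn.pipeline.Pipeline`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import DBSCAN as _SkDBSCAN

from .config import FilterParams, PreprocessingConfig
from .io_formats import OrganizedFrame, PointCloud

logger = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """ROI calibration could not separate limb and device clusters."""


class SegmentationError(RuntimeError):
    """Silhouette segmentation produced an empty cloud (subject absent)."""


@dataclass(frozen=True)
class RoiCalibration:
    """Frontal-axis interval delimiting the inside of the device frame."""

    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if not self.x_min < self.x_max:
            raise ValueError("x_min must be below x_max")


def _as_points(cloud) -> np.ndarray:
    if isinstance(cloud, PointCloud):
        return cloud.points
    return np.asarray(cloud, dtype=float)


def _wrap_like(points: np.ndarray, template) -> "PointCloud | np.ndarray":
    if isinstance(template, PointCloud):
        return PointCloud(points, source_id=template.source_id)
    return points


# ---------------------------------------------------------------------------
# Temporal averaging
# ---------------------------------------------------------------------------


def average_frames(frames: Sequence[OrganizedFrame], n: int | None = None) -> OrganizedFrame:
    """Per-pixel arithmetic mean of the first ``n`` frames.

    A pixel is valid in the output only when valid in every constituent
    frame (strict mask intersection); partial averages over subsets
    would mix noise levels across the grid.
    """
    if n is None:
        n = len(frames)
    if n < 1:
        raise ValueError("n must be at least 1")
    if len(frames) < n:
        raise ValueError(f"need at least {n} frames, got {len(frames)}")
    use = frames[:n]
    shape = use[0].shape
    for f in use:
        if f.shape != shape:
            raise ValueError(f"frame shape {f.shape} != {shape}")
    valid = np.logical_and.reduce([f.valid for f in use])
    def mean_of(attr: str) -> np.ndarray:
        stack = np.stack([getattr(f, attr) for f in use])
        with np.errstate(invalid="ignore"):
            out = stack.mean(axis=0)
        return np.where(valid, out, np.nan)
    ts = use[-1].timestamp
    return OrganizedFrame(x=mean_of("x"), y=mean_of("y"), z=mean_of("z"),
                          valid=valid, timestamp=ts)


def mean_shift_curve(frames: Sequence[OrganizedFrame], n_max: int) -> list[tuple[int, float]]:
    """Mean per-pixel displacement between the n- and (n-1)-frame averages.

    Returns ``[(n, mean Euclidean shift in meters)]`` for n = 2..n_max;
    the curve flattens as averaging converges, which is how the
    averaging depth is chosen against the real-time budget.
    """
    if n_max < 2:
        raise ValueError("n_max must be at least 2")
    if len(frames) < n_max:
        raise ValueError(f"need at least {n_max} frames, got {len(frames)}")
    curve = []
    for n in range(2, n_max + 1):
        prev = average_frames(frames, n - 1)
        curr = average_frames(frames, n)
        both = prev.valid & curr.valid
        if not both.any():
            curve.append((n, float("nan")))
            continue
        d = np.sqrt(
            (curr.x[both] - prev.x[both]) ** 2
            + (curr.y[both] - prev.y[both]) ** 2
            + (curr.z[both] - prev.z[both]) ** 2
        )
        curve.append((n, float(d.mean())))
    return curve


# ---------------------------------------------------------------------------
# Point filters
# ---------------------------------------------------------------------------


def limit_depth(cloud, z_max: float):
    """Retain points with z <= z_max (boundary inclusive)."""
    if z_max <= 0:
        raise ValueError("z_max must be positive")
    pts = _as_points(cloud)
    return _wrap_like(pts[pts[:, 2] <= z_max], cloud)


def radius_outlier_filter(cloud, params: FilterParams):
    """Remove points with fewer than ``min_neighbors`` other points
    within ``params.radius``.

    Returns ``(kept, removed_indices)``; the query point itself is not
    counted as its own neighbor.
    """
    pts = _as_points(cloud)
    if len(pts) == 0:
        return _wrap_like(pts, cloud), np.empty(0, dtype=int)
    if params.min_neighbors == 0:
        return _wrap_like(pts, cloud), np.empty(0, dtype=int)
    tree = cKDTree(pts)
    # counts include the query point itself -> subtract 1
    counts = tree.query_ball_point(pts, r=params.radius, return_length=True) - 1
    keep = counts >= params.min_neighbors
    removed = np.nonzero(~keep)[0]
    return _wrap_like(pts[keep], cloud), removed


def dbscan(cloud, epsilon: float, min_points: int) -> np.ndarray:
    """Density-based clustering; returns per-point labels, -1 for noise.

    Standard DBSCAN semantics: a core point has at least ``min_points``
    points (itself included) within ``epsilon``; border points join the
    first core cluster found in scan order.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    pts = _as_points(cloud)
    if len(pts) == 0:
        return np.empty(0, dtype=int)
    model = _SkDBSCAN(eps=epsilon, min_samples=min_points)
    return model.fit_predict(pts)


# ---------------------------------------------------------------------------
# ROI calibration and silhouette segmentation
# ---------------------------------------------------------------------------


def calibrate_roi(cloud, config: PreprocessingConfig | None = None) -> RoiCalibration:
    """Determine the device-interior x interval from a calibration cloud.

    The cloud is split left/right of the centroid; in each side's bottom
    band (``roi_bottom_band`` above the side's lowest point) DBSCAN
    separates the subject's lower limb from the device post.  The
    cluster whose x centroid is closer to the whole-cloud centroid is
    the limb; the other cluster's inner x face, moved inward by
    ``roi_margin``, is the ROI bound for that side.
    """
    config = config or PreprocessingConfig()
    pts = _as_points(cloud)
    if len(pts) == 0:
        raise CalibrationError("empty calibration cloud")
    cx = pts[:, 0].mean()
    bounds = {}
    for side, mask in (("left", pts[:, 0] <= cx), ("right", pts[:, 0] > cx)):
        side_pts = pts[mask]
        if len(side_pts) == 0:
            raise CalibrationError(f"no points on {side} side")
        y_min = side_pts[:, 1].min()
        band = side_pts[side_pts[:, 1] <= y_min + config.roi_bottom_band]
        labels = dbscan(band, config.dbscan_epsilon, config.dbscan_min_points)
        cluster_ids = [c for c in np.unique(labels) if c >= 0]
        if len(cluster_ids) < 2:
            raise CalibrationError(
                f"{side} side: found {len(cluster_ids)} cluster(s), need limb and device"
            )
        centroids = {c: band[labels == c, 0].mean() for c in cluster_ids}
        limb = min(centroids, key=lambda c: abs(centroids[c] - cx))
        # the device frame surrounds the subject, so its element is the
        # outermost cluster; anything between (e.g. a hanging arm) is
        # part of the subject and must stay inside the ROI
        device = max(cluster_ids, key=lambda c: abs(centroids[c] - cx))
        if device == limb:
            raise CalibrationError(f"{side} side: limb and device clusters coincide")
        device_x = band[labels == device, 0]
        if side == "left":
            bounds["x_min"] = device_x.max() + config.roi_margin
        else:
            bounds["x_max"] = device_x.min() - config.roi_margin
    roi = RoiCalibration(**bounds)
    logger.info("ROI calibrated: x in [%.3f, %.3f]", roi.x_min, roi.x_max)
    return roi


def segment_subject(cloud, roi: RoiCalibration, denoise: FilterParams | None = None):
    """Crop to the ROI x interval, then apply the subject-stage
    neighborhood filter.  Raises when nothing remains (subject absent)."""
    denoise = denoise or PreprocessingConfig().subject_filter
    pts = _as_points(cloud)
    inside = (pts[:, 0] >= roi.x_min) & (pts[:, 0] <= roi.x_max)
    cropped = pts[inside]
    kept, _ = radius_outlier_filter(cropped, denoise)
    kept_pts = _as_points(kept)
    if len(kept_pts) == 0:
        raise SegmentationError("no subject points inside ROI after denoising")
    return _wrap_like(kept_pts, cloud)


def preprocess_frames(frames: Sequence[OrganizedFrame],
                      roi: RoiCalibration | None = None,
                      config: PreprocessingConfig | None = None):
    """Full chain on a frame window: average, flatten, depth-limit,
    acquisition-stage denoise, then (when a ROI is given) segment the
    subject.  Returns ``(cloud, roi)``; the ROI is calibrated from this
    window when not supplied."""
    config = config or PreprocessingConfig()
    avg = average_frames(frames, min(config.n_average, len(frames)))
    cloud = avg.to_cloud()
    cloud = limit_depth(cloud, config.depth_max)
    cloud, removed = radius_outlier_filter(cloud, config.acq_filter)
    logger.info("acquisition filter removed %d points", len(removed))
    if roi is None:
        roi = calibrate_roi(cloud, config)
    subject = segment_subject(cloud, roi, config.subject_filter)
    logger.info("silhouette: %d points", len(_as_points(subject)))
    return subject, roi


# ---------------------------------------------------------------------------
# scikit-learn style transformers
# ---------------------------------------------------------------------------


class DepthLimiter(TransformerMixin, BaseEstimator):
    """Stateless transformer keeping points with z <= ``z_max``."""

    def __init__(self, z_max: float = 2.0):
        self.z_max = z_max

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return limit_depth(X, self.z_max)


class RadiusOutlierFilter(TransformerMixin, BaseEstimator):
    """Stateless transformer applying the spherical-neighborhood
    outlier criterion; ``transform`` returns the kept points only."""

    def __init__(self, radius: float = 0.05, min_neighbors: int = 20):
        self.radius = radius
        self.min_neighbors = min_neighbors

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        kept, _ = radius_outlier_filter(X, FilterParams(self.radius, self.min_neighbors))
        return kept


class RoiCalibrator(TransformerMixin, BaseEstimator):
    """Fits the device-interior x interval on a calibration cloud;
    ``transform`` then crops any later cloud to that interval.

    Fitted attributes: ``x_min_``, ``x_max_``, ``roi_``.
    """

    def __init__(self, config: PreprocessingConfig | None = None):
        self.config = config

    def fit(self, X, y=None):
        self.roi_ = calibrate_roi(X, self.config or PreprocessingConfig())
        self.x_min_ = self.roi_.x_min
        self.x_max_ = self.roi_.x_max
        return self

    def transform(self, X):
        if not hasattr(self, "roi_"):
            raise RuntimeError("RoiCalibrator is not fitted")
        pts = _as_points(X)
        inside = (pts[:, 0] >= self.x_min_) & (pts[:, 0] <= self.x_max_)
        return _wrap_like(pts[inside], X)


class SubjectSegmenter(TransformerMixin, BaseEstimator):
    """ROI crop plus subject-stage denoising as a single transformer.

    When constructed without a ROI it calibrates one from the first
    cloud passed to :meth:`fit`.
    """

    def __init__(self, roi: RoiCalibration | None = None,
                 config: PreprocessingConfig | None = None):
        self.roi = roi
        self.config = config

    def fit(self, X, y=None):
        cfg = self.config or PreprocessingConfig()
        self.roi_ = self.roi if self.roi is not None else calibrate_roi(X, cfg)
        return self

    def transform(self, X):
        if not hasattr(self, "roi_"):
            raise RuntimeError("SubjectSegmenter is not fitted")
        cfg = self.config or PreprocessingConfig()
        return segment_subject(X, self.roi_, cfg.subject_filter)
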