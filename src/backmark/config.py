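"""Pipeline configuration.

Every tunable threshold of the preprocessing and detection stages lives
here with its default.  Distances are meters, angles degrees.  The
defaults are the operating values of the acquisition setup the pipeline
was designed around (SR4000-class sensor, subject standing 1.4–2 m from
the camera inside a device frame):

* ``depth_max`` — scene depth cutoff, 2.0 m.
* ``n_average`` — frames averaged per processed cloud, 10.
* acquisition-stage outlier criterion — a point is noise when fewer
  than 20 neighbors lie within 5 cm.
* subject-stage criterion — fewer than 10 neighbors within 3 cm.
* DBSCAN ``epsilon`` 0.03 m (``min_points`` is a free choice, 10).
* ``roi_bottom_band`` — 10 cm band above the lowest point used for
  ROI calibration.
"""

from __future__ import annotations

import configparser
import io
from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass(frozen=True)
class FilterParams:
    """Spherical-neighborhood outlier criterion: a point is kept when at
    least ``min_neighbors`` other points lie within ``radius`` meters."""

    radius: float
    min_neighbors: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.min_neighbors < 0:
            raise ValueError("min_neighbors must be non-negative")


@dataclass
class PreprocessingConfig:
    depth_max: float = 2.0
    n_average: int = 10
    acq_filter_radius: float = 0.05
    acq_filter_min_neighbors: int = 20
    subject_filter_radius: float = 0.03
    subject_filter_min_neighbors: int = 10
    dbscan_epsilon: float = 0.03
    dbscan_min_points: int = 10
    roi_bottom_band: float = 0.10
    roi_margin: float = 0.01

    @property
    def acq_filter(self) -> FilterParams:
        return FilterParams(self.acq_filter_radius, self.acq_filter_min_neighbors)

    @property
    def subject_filter(self) -> FilterParams:
        return FilterParams(self.subject_filter_radius,
                            self.subject_filter_min_neighbors)


@dataclass
class DetectionConfig:
    centroid_band_halfwidth: float = 0.02   # half of the 4 cm torso/arm band
    dbscan_epsilon: float = 0.03
    dbscan_min_points: int = 10
    min_cluster_size: int = 30
    under_plane_threshold: float = 0.01
    shoulder_belt_halfwidth: float = 0.01
    spine_band_halfwidth: float = 0.025
    polynomial_degree: int = 5
    surface_slab_halfwidth: float = 0.02
    waist_bin_height: float = 0.01
    waist_smooth_bins: int = 3
    min_cloud_points: int = 500


@dataclass
class SyntheticConfig:
    grid_shape: tuple[int, int] = (144, 176)
    camera_height: float = 1.5
    noise_sigma: float = 0.004
    speckle_rate: float = 0.01
    post_x: float = 0.45
    post_radius: float = 0.02


@dataclass
class RunConfig:
    """Full run configuration: one section per pipeline stage plus the
    run-level seed/output settings."""

    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0
    out_dir: str = "backmark-out"
    log_level: str = "INFO"

    _SECTIONS = ("preprocessing", "detection", "synthetic")

    def to_text(self) -> str:
        parser = configparser.ConfigParser()
        parser["run"] = {
            "seed": str(self.seed),
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }
        for section in self._SECTIONS:
            obj = getattr(self, section)
            parser[section] = {}
            for f in fields(obj):
                val = getattr(obj, f.name)
                if isinstance(val, tuple):
                    val = " ".join(str(v) for v in val)
                parser[section][f.name] = str(val)
        buf = io.StringIO()
        parser.write(buf)
        return buf.getvalue()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        parser = configparser.ConfigParser()
        with open(path) as fh:
            parser.read_file(fh)
        cfg = cls()
        known_sections = set(cls._SECTIONS) | {"run"}
        for section in parser.sections():
            if section not in known_sections:
                raise ValueError(f"unknown config section {section!r}")
            if section == "run":
                for key, val in parser["run"].items():
                    if key == "seed":
                        cfg.seed = int(val)
                    elif key == "out_dir":
                        cfg.out_dir = val
                    elif key == "log_level":
                        cfg.log_level = val
                    else:
                        raise ValueError(f"unknown config key run.{key}")
                continue
            obj = getattr(cfg, section)
            valid = {f.name: f for f in fields(obj)}
            for key, val in parser[section].items():
                if key not in valid:
                    raise ValueError(f"unknown config key {section}.{key}")
                current = getattr(obj, key)
                if isinstance(current, bool):
                    setattr(obj, key, parser[section].getboolean(key))
                elif isinstance(current, int):
                    setattr(obj, key, int(val))
                elif isinstance(current, float):
                    setattr(obj, key, float(val))
                elif isinstance(current, tuple):
                    setattr(obj, key, tuple(int(v) for v in val.split()))
                else:
                    setattr(obj, key, val)
        return cfg
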