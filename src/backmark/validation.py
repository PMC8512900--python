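"""Expert-validation statistics for landmark indications.

Implements the comparison protocol between an automatic method (rater
``M``) and several human experts (``E1``..``E3``): consensus positions
by expert averaging, signed per-axis errors in the frontal (xy) plane,
outlier removal by the interquartile rule in the principal-component
space of the error distribution, pairwise average distances, and a
Friedman test with Kendall's W effect size over the six rater-pair
distance groups.

All distances and errors are reported in millimeters; positions are
stored in meters.  Only x and y enter the statistics; depth is kept in
the stores but ignored, matching how landmark indications are assessed
on a frontal view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import LANDMARK_NAMES, AnnotationStore

logger = logging.getLogger(__name__)

EXPERTS = ("E1", "E2", "E3")
METHOD = "M"

#: Rater pairs of the distance table, in presentation order.
DISTANCE_PAIRS = (("E1", "E2"), ("E2", "E3"), ("E3", "E1"),
                  ("M", "E1"), ("M", "E2"), ("M", "E3"))

LANDMARK_GROUPS = {"axilla": ("AL", "AR"), "shoulders": ("SL", "SR"),
                   "waist": ("WL", "WR")}


class EmptyConsensusError(ValueError):
    """No (cloud, landmark) had indications from every requested rater."""


# ---------------------------------------------------------------------------
# Consensus and signed errors
# ---------------------------------------------------------------------------


def consensus(store: AnnotationStore, raters=EXPERTS) -> dict[tuple[str, str], np.ndarray]:
    """Expected landmark position L0 per (cloud, landmark): the
    component-wise xy mean over the requested raters.

    Records missing any rater's indication are skipped (and logged).
    """
    out: dict[tuple[str, str], np.ndarray] = {}
    skipped = 0
    for cloud_id in store.cloud_ids:
        sets = {r: store.get(cloud_id, r) for r in raters}
        for name in LANDMARK_NAMES:
            pts = []
            for r in raters:
                ls = sets[r]
                if ls is None or not ls.is_present(name):
                    break
                pts.append(ls.position(name)[:2])
            else:
                out[(cloud_id, name)] = np.mean(pts, axis=0)
                continue
            skipped += 1
    if skipped:
        logger.info("consensus: skipped %d incomplete (cloud, landmark) records",
                    skipped)
    if not out:
        raise EmptyConsensusError("no complete records for consensus")
    return out


def signed_errors(store: AnnotationStore,
                  consensus_map: dict[tuple[str, str], np.ndarray],
                  rater: str) -> pd.DataFrame:
    """Signed per-axis deviations dL = L - L0 in mm for one rater.

    Returns a frame with columns cloud_id, landmark, dx_mm, dy_mm.
    """
    rows = []
    for (cloud_id, name), l0 in consensus_map.items():
        ls = store.get(cloud_id, rater)
        if ls is None or not ls.is_present(name):
            continue
        delta = (ls.position(name)[:2] - l0) * 1000.0
        rows.append((cloud_id, name, float(delta[0]), float(delta[1])))
    return pd.DataFrame(rows, columns=["cloud_id", "landmark", "dx_mm", "dy_mm"])


def summarize_errors(table: pd.DataFrame) -> pd.DataFrame:
    """Per-landmark mean and sample SD (n-1) of the signed errors, mm."""
    out = {}
    for name in LANDMARK_NAMES:
        sub = table[table["landmark"] == name]
        if len(sub) == 0:
            continue
        row = {"mean_dx": sub["dx_mm"].mean(), "mean_dy": sub["dy_mm"].mean(),
               "n": len(sub)}
        if len(sub) >= 2:
            row["sd_dx"] = sub["dx_mm"].std(ddof=1)
            row["sd_dy"] = sub["dy_mm"].std(ddof=1)
        else:
            row["sd_dx"] = np.nan
            row["sd_dy"] = np.nan
        out[name] = row
    return pd.DataFrame(out).T


# ---------------------------------------------------------------------------
# Outlier removal in principal-component space
# ---------------------------------------------------------------------------


def pca_iqr_filter(deltas: np.ndarray) -> tuple[np.ndarray, int]:
    """Upper-tail interquartile outlier removal in PCA space.

    The 2-D error vectors are centered and projected onto the
    eigenvectors of their covariance (descending eigenvalue; sign fixed
    so each axis's largest-magnitude loading is positive).  On each
    component independently, values above Q3 + 1.5 IQR (linear-
    interpolation quartiles) are flagged; the union of flags is
    removed.  Kept points are returned in original coordinates.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.ndim != 2 or deltas.shape[1] != 2:
        raise ValueError("deltas must be (n, 2)")
    n = len(deltas)
    if n < 4:
        raise ValueError("need at least 4 points for quartiles")
    centered = deltas - deltas.mean(axis=0)
    cov = np.cov(centered, rowvar=False)
    if not np.all(np.isfinite(cov)) or np.allclose(cov, 0):
        return deltas.copy(), 0
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigvec = eigvec[:, order]
    for j in range(2):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    proj = centered @ eigvec
    flags = np.zeros(n, dtype=bool)
    for j in range(2):
        q1, q3 = np.percentile(proj[:, j], [25, 75])
        flags |= proj[:, j] > q3 + 1.5 * (q3 - q1)
    return deltas[~flags], int(flags.sum())


# ---------------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------------


def pairwise_average_distance(store: AnnotationStore, rater_a: str, rater_b: str,
                              landmark: str) -> float:
    """Mean xy Euclidean distance (mm) between two raters' indications
    of one landmark, over clouds where both are present; NaN if none."""
    dists = []
    for cloud_id in store.cloud_ids:
        la, lb = store.get(cloud_id, rater_a), store.get(cloud_id, rater_b)
        if la is None or lb is None:
            continue
        if not (la.is_present(landmark) and lb.is_present(landmark)):
            continue
        diff = (la.position(landmark)[:2] - lb.position(landmark)[:2]) * 1000.0
        dists.append(float(np.hypot(*diff)))
    return float(np.mean(dists)) if dists else float("nan")


@dataclass
class DistanceTable:
    """Per-landmark average distances for the six rater pairs plus the
    method-vs-all-experts mean, with group aggregates."""

    table: pd.DataFrame
    aggregates: dict[str, float] = field(default_factory=dict)


def aggregate_method_expert_distances(table: pd.DataFrame) -> DistanceTable:
    """Add the M-All column (mean of the three method-vs-expert
    distances) and the group/overall aggregates of M-All.

    ``table`` must be indexed by landmark with columns E1E2, E2E3,
    E3E1, ME1, ME2, ME3 (mm).
    """
    table = table.copy()
    table["MAll"] = table[["ME1", "ME2", "ME3"]].mean(axis=1)
    agg: dict[str, float] = {}
    for group, names in LANDMARK_GROUPS.items():
        present = [n for n in names if n in table.index]
        if present:
            agg[group] = float(table.loc[present, "MAll"].mean())
    agg["all_landmarks"] = float(table["MAll"].mean())
    return DistanceTable(table=table, aggregates=agg)


def build_distance_table(store: AnnotationStore) -> DistanceTable:
    """Average-distance table over all six rater pairs per landmark."""
    cols = {}
    for a, b in DISTANCE_PAIRS:
        key = f"{a}{b}".replace("M", "M")  # e.g. E1E2, ME1
        cols[f"{a}{b}"] = [pairwise_average_distance(store, a, b, name)
                           for name in LANDMARK_NAMES]
    df = pd.DataFrame(cols, index=list(LANDMARK_NAMES))
    df.columns = ["E1E2", "E2E3", "E3E1", "ME1", "ME2", "ME3"]
    missing = df.columns[df.isna().all()]
    if len(missing):
        logger.warning("distance table: no data for %s", list(missing))
    return aggregate_method_expert_distances(df)


# ---------------------------------------------------------------------------
# Friedman test with Kendall's W
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    p_value: float
    kendall_w: float
    effect: str
    n_blocks: int
    k_groups: int


def _effect_label(w: float) -> str:
    if w < 0.1:
        return "negligibly small"
    if w < 0.3:
        return "small"
    if w < 0.5:
        return "moderate"
    return "large"


def friedman_test(groups) -> FriedmanResult:
    """Friedman rank test for k related samples over n blocks.

    ``groups`` is an (n, k) array: one row per block (cloud), one
    column per group.  Within-block ties receive mid-ranks and the
    chi-square statistic carries the standard tie correction; Kendall's
    W is chi2 / (n (k - 1)).
    """
    data = np.asarray(groups, dtype=float)
    if data.ndim != 2:
        raise ValueError("groups must be a 2-D (blocks x groups) array")
    n, k = data.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 groups and 2 blocks")
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    rank_sums = ranks.sum(axis=0)
    ssbn = float(np.sum(rank_sums ** 2))
    # tie correction over blocks
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts ** 3 - counts))
    correction = 1.0 - ties / (n * (k ** 3 - k))
    if correction <= 0:  # every block fully tied
        chi2 = 0.0
    else:
        chi2 = (12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)) / correction
        chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    w = chi2 / (n * (k - 1))
    w = float(min(max(w, 0.0), 1.0))
    return FriedmanResult(chi2=float(chi2), p_value=p, kendall_w=w,
                          effect=_effect_label(w), n_blocks=n, k_groups=k)


def friedman_by_landmark(store: AnnotationStore) -> pd.DataFrame:
    """Friedman test per landmark over the six rater-pair distance
    groups, blocks being clouds where all four raters marked the
    landmark."""
    rows = {}
    for name in LANDMARK_NAMES:
        blocks = []
        for cloud_id in store.cloud_ids:
            sets = {r: store.get(cloud_id, r) for r in (*EXPERTS, METHOD)}
            if any(s is None or not s.is_present(name) for s in sets.values()):
                continue
            pos = {r: sets[r].position(name)[:2] for r in sets}
            row = [float(np.hypot(*(pos[a] - pos[b]))) * 1000.0
                   for a, b in DISTANCE_PAIRS]
            blocks.append(row)
        if len(blocks) < 2:
            continue
        res = friedman_test(np.array(blocks))
        rows[name] = {"W": res.kendall_w, "effect": res.effect,
                      "p": res.p_value, "chi2": res.chi2, "n": res.n_blocks}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Bundle of the validation tables, mirroring the standard layout:
    signed-error means and SDs per rater (with and without method
    outliers), outlier counts, pairwise distances, Friedman results."""

    mean_errors: pd.DataFrame
    sd_errors: pd.DataFrame
    outliers: pd.DataFrame
    distances: DistanceTable
    friedman: pd.DataFrame

    def to_csv_dir(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.mean_errors.to_csv(out / "table2_mean_errors.csv")
        self.sd_errors.to_csv(out / "table3_sd_errors.csv")
        self.outliers.to_csv(out / "table4_outliers.csv")
        self.distances.table.to_csv(out / "table5_distances.csv")
        self.friedman.to_csv(out / "table6_friedman.csv")
        (out / "summary.md").write_text(self.to_markdown())

    def to_markdown(self) -> str:
        parts = ["# Validation report\n"]
        for title, df in (("Mean signed errors (mm)", self.mean_errors),
                          ("SD of signed errors (mm)", self.sd_errors),
                          ("Removed outliers", self.outliers),
                          ("Average pairwise distances (mm)", self.distances.table),
                          ("Friedman / Kendall W", self.friedman)):
            parts.append(f"## {title}\n")
            parts.append(df.round(2).to_markdown())
            parts.append("")
        agg = ", ".join(f"{k}: {v:.2f} mm" for k, v in
                        sorted(self.distances.aggregates.items()))
        parts.append(f"Group means of method-vs-expert distance - {agg}\n")
        return "\n".join(parts)


def build_report(store: AnnotationStore, raters=EXPERTS, method: str = METHOD,
                 remove_outliers: bool = True) -> ValidationReport:
    """Assemble the full validation report from an annotation store."""
    if len(store) == 0:
        raise ValueError("empty annotation store")
    cons = consensus(store, raters)

    mean_cols, sd_cols = {}, {}
    method_table = None
    for rater in (*raters, method):
        table = signed_errors(store, cons, rater)
        if rater == method:
            method_table = table
        summary = summarize_errors(table)
        if summary.empty:
            continue
        mean_cols[f"{rater}x"] = summary["mean_dx"]
        mean_cols[f"{rater}y"] = summary["mean_dy"]
        sd_cols[f"{rater}x"] = summary["sd_dx"]
        sd_cols[f"{rater}y"] = summary["sd_dy"]

    outlier_rows = {}
    if method_table is not None and len(method_table) and remove_outliers:
        kept_rows = []
        for name in LANDMARK_NAMES:
            sub = method_table[method_table["landmark"] == name]
            if len(sub) < 4:
                outlier_rows[name] = {"removed": 0, "total": len(sub),
                                      "percent": 0.0}
                kept_rows.append(sub)
                continue
            deltas = sub[["dx_mm", "dy_mm"]].to_numpy()
            kept, n_removed = pca_iqr_filter(deltas)
            outlier_rows[name] = {
                "removed": n_removed, "total": len(sub),
                "percent": round(100.0 * n_removed / len(sub)),
            }
            mask = np.ones(len(sub), dtype=bool)
            if n_removed:
                # recompute flags to know which rows were kept
                kept_set = {tuple(row) for row in np.round(kept, 9)}
                mask = np.array([tuple(row) in kept_set
                                 for row in np.round(deltas, 9)])
            kept_rows.append(sub[mask])
        filtered = pd.concat(kept_rows, ignore_index=True)
        summary = summarize_errors(filtered)
        mean_cols[f"{method}out_x"] = summary["mean_dx"]
        mean_cols[f"{method}out_y"] = summary["mean_dy"]
        sd_cols[f"{method}out_x"] = summary["sd_dx"]
        sd_cols[f"{method}out_y"] = summary["sd_dy"]

    mean_errors = pd.DataFrame(mean_cols).reindex(list(LANDMARK_NAMES))
    sd_errors = pd.DataFrame(sd_cols).reindex(list(LANDMARK_NAMES))
    outliers = pd.DataFrame(outlier_rows).T if outlier_rows else pd.DataFrame(
        columns=["removed", "total", "percent"])
    distances = build_distance_table(store)
    friedman = friedman_by_landmark(store)
    return ValidationReport(mean_errors=mean_errors, sd_errors=sd_errors,
                            outliers=outliers, distances=distances,
                            friedman=friedman)
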