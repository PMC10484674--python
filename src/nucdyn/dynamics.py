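"""Depletion-induced change estimation.

The central statistic: for a set of genomic features, each repeat's
log2 feature occupancy is normalized to its level before depletion
(t = 0), one regression line is fitted through all (time, relative
occupancy) points pooled over features and repeats, and the slope times
the horizon (90 min for ChIP, 60 min for ChEC) is the mean relative
change of that feature class. The Pearson correlation of relative
occupancy vs time expresses the confidence of the trend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack, smooth
from .features import GENE_REGION_TYPES, feature_mean_coverage

logger = logging.getLogger(__name__)

CHIP_HORIZON = 90
CHEC_HORIZON = 60
DEFAULT_PSEUDOCOUNT = 1.0
#: default log2-per-horizon threshold for calling exchange semantics
CLASSIFY_THRESHOLD = 0.25

TrackGrid = Mapping[tuple[int, int], CoverageTrack]  # (timepoint, repeat) -> track


@dataclass
class ChangeEstimate:
    """Slope-derived relative change with its trend confidence."""

    change: float          # log2 units per horizon
    correlation: float     # Pearson r of relative occupancy vs time
    p_value: float
    n_features: int
    n_points: int
    horizon: int

    def as_dict(self) -> dict:
        return {
            "change": self.change, "correlation": self.correlation,
            "p_value": self.p_value, "n_features": self.n_features,
            "n_points": self.n_points, "horizon": self.horizon,
        }


@dataclass
class DynamicsCall:
    """Sensor-semantics classification of a (myc, HA) change pair."""

    call: str  # replacement | incorporation | eviction | stable
    myc_change: float
    ha_change: float
    threshold: float


def _pooled_fit(times: np.ndarray, values: np.ndarray, horizon: int,
                n_features: int) -> ChangeEstimate:
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least 2 (time, value) points for a slope")
    # OLS with intercept; robust when t=0 repeats disagree
    slope, _ = np.polyfit(times, values, 1)
    if np.std(times) == 0 or np.std(values) == 0:
        r, p = 0.0, 1.0
    else:
        res = stats.pearsonr(times, values)
        r, p = float(res.statistic), float(res.pvalue)
    return ChangeEstimate(
        change=float(slope * horizon), correlation=r, p_value=p,
        n_features=n_features, n_points=len(times), horizon=horizon,
    )


def _occupancy_table(tracks: TrackGrid, features: pd.DataFrame) -> pd.DataFrame:
    """Long table (feature_id, time, repeat, occupancy=mean coverage)."""
    rows = []
    for (t, rep), track in tracks.items():
        means = feature_mean_coverage(track, features)
        for fid, m in means.items():
            rows.append({"feature_id": fid, "time": t, "repeat": rep, "occ": m})
    return pd.DataFrame(rows)


def feature_relative_change(
    tracks: TrackGrid,
    features: pd.DataFrame,
    feature_type: str | None = None,
    horizon: int = CHIP_HORIZON,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ChangeEstimate:
    """Mean relative change of one feature class after `horizon` minutes.

    Every feature's log2(mean coverage + pc) in every repeat is
    normalized to that repeat's t=0 value; a single line is fitted
    through all pooled (time, relative occupancy) points and its slope
    multiplied by the horizon. Features with zero coverage at t=0 (and
    pc = 0) are dropped with a warning.
    """
    sub = features if feature_type is None else features[features["type"] == feature_type]
    if sub.empty:
        raise ValueError(f"no features of type {feature_type!r}")
    times_avail = sorted({t for t, _ in tracks})
    if 0 not in times_avail:
        raise ValueError("t=0 tracks are required")
    occ = _occupancy_table(tracks, sub)
    occ["logocc"] = np.log2(occ["occ"] + pseudocount)
    base = occ[occ["time"] == 0].set_index(["feature_id", "repeat"])["logocc"]
    finite_base = base[np.isfinite(base)]
    if len(finite_base) < len(base):
        logger.warning("dropping %d features with zero t=0 coverage", len(base) - len(finite_base))
    occ = occ.join(finite_base.rename("base"), on=["feature_id", "repeat"], how="inner")
    rel = occ["logocc"] - occ["base"]
    keep = np.isfinite(rel)
    return _pooled_fit(
        occ.loc[keep, "time"].to_numpy(), rel[keep].to_numpy(), horizon,
        n_features=occ.loc[keep, "feature_id"].nunique(),
    )


def region_expression_change(
    tracks: TrackGrid,
    features: pd.DataFrame,
    regions: Sequence[str] = GENE_REGION_TYPES,
    groups: Sequence[int] = (1, 2, 3, 4, 5),
    horizon: int = CHIP_HORIZON,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """feature_relative_change per (gene region x expression group) stratum.

    Returns a tidy table (region, group, change, correlation, p_value,
    n_features, n_points); empty strata yield missing estimates.
    """
    rows = []
    for region in regions:
        for group in groups:
            stratum = features[(features["type"] == region) & (features["group"] == group)]
            rec: dict = {"region": region, "group": group}
            if stratum.empty:
                rec.update({"change": np.nan, "correlation": np.nan, "p_value": np.nan,
                            "n_features": 0, "n_points": 0, "horizon": horizon})
            else:
                est = feature_relative_change(tracks, stratum, None, horizon, pseudocount)
                rec.update(est.as_dict())
            rows.append(rec)
    return pd.DataFrame(rows)


def chec_relative_change(
    tracks: TrackGrid,
    regions: pd.DataFrame,
    horizon: int = CHEC_HORIZON,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ChangeEstimate:
    """Relative binding change for a stratum of regions (ChEC variant).

    Unlike the feature-level estimator, occupancies are first averaged
    across all regions of the stratum within each (repeat, timepoint),
    log2-transformed, normalized to the mean t=0 level, and then a line
    is fitted with one point per repeat per timepoint; slope x horizon.
    """
    if regions.empty:
        raise ValueError("empty stratum")
    occ = _occupancy_table(tracks, regions)
    if not (occ["time"] == 0).any():
        raise ValueError("t=0 tracks are required")
    per_point = occ.groupby(["time", "repeat"])["occ"].mean().reset_index()
    per_point["logocc"] = np.log2(per_point["occ"] + pseudocount)
    base = per_point.loc[per_point["time"] == 0, "logocc"].mean()
    rel = per_point["logocc"] - base
    return _pooled_fit(per_point["time"].to_numpy(), rel.to_numpy(), horizon,
                       n_features=regions["feature_id"].nunique())


def epitope_vs_expression_curve(
    track: CoverageTrack,
    features: pd.DataFrame,
    genes: pd.DataFrame,
    region: str,
    window: float = 1.0,
) -> pd.DataFrame:
    """Mean sensor level in a gene region as a smooth function of expression.

    Per gene the mean coverage over its `region` feature is computed;
    genes are sorted by expression (log-scale units) and the value at
    expression e is the mean over genes with expression in
    [e - window/2, e + window/2) (half-open, so boundary genes count once).
    """
    sub = features[features["type"] == region]
    means = feature_mean_coverage(track, sub)
    expr = dict(zip(genes["gene"], genes["expression"]))
    per_gene = pd.DataFrame({
        "gene": sub["gene"].unique(),
    })
    per_gene["level"] = per_gene["gene"].map(lambda g: means.get(f"{g}:{region}", np.nan))
    per_gene["expression"] = per_gene["gene"].map(expr)
    per_gene = per_gene.dropna().sort_values("expression", kind="mergesort").reset_index(drop=True)
    e = per_gene["expression"].to_numpy()
    v = per_gene["level"].to_numpy()
    half = window / 2.0
    smoothed = np.array([
        v[(e >= ei - half) & (e < ei + half)].mean() if ((e >= ei - half) & (e < ei + half)).any() else np.nan
        for ei in e
    ])
    return pd.DataFrame({"gene": per_gene["gene"], "expression": e, "level": v, "smoothed": smoothed})


def classify_dynamics(
    myc_change: float,
    ha_change: float,
    threshold: float = CLASSIFY_THRESHOLD,
) -> DynamicsCall:
    """Sensor semantics: replacement (myc up), incorporation (myc and HA
    up), eviction (HA down), otherwise stable. Total: every pair gets
    exactly one call; incorporation is tested before eviction.
    """
    if myc_change >= threshold and ha_change >= threshold:
        call = "incorporation"
    elif ha_change <= -threshold:
        call = "eviction"
    elif myc_change >= threshold:
        call = "replacement"
    else:
        call = "stable"
    return DynamicsCall(call, myc_change, ha_change, threshold)


def pca_scores(matrix: np.ndarray, n_components: int = 2) -> np.ndarray:
    """SVD-based PCA scores of samples (rows) after column mean-centering."""
    X = np.asarray(matrix, dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    return u[:, :n_components] * s[:n_components]


def segment_change_pca(
    sample_tracks: Mapping[str, CoverageTrack],
    segments: pd.DataFrame,
    sample_meta: pd.DataFrame | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    center_variables: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """PCA of genome-wide incorporation changes over gene-body segments.

    Each sample's log2 mean myc level per segment (5'/mid/3' of every
    gene) is compared against the segment's mean level across all
    samples; each sample's relative changes are z-score normalized
    (n-1 std) and the samples projected on the first two PCs.

    Returns (per-sample PC coordinates, per-(regulator, timepoint) mean
    and standard error across repeats when sample_meta is given with
    columns sample_id/regulator/timepoint/repeat).
    """
    sample_ids = list(sample_tracks)
    if len(sample_ids) < 2:
        raise ValueError("PCA needs at least 2 samples")
    seg_ids = sorted(segments["feature_id"].unique())
    mat = np.empty((len(sample_ids), len(seg_ids)))
    for i, sid in enumerate(sample_ids):
        means = feature_mean_coverage(sample_tracks[sid], segments)
        mat[i] = np.log2(means.reindex(seg_ids).to_numpy(dtype=float) + pseudocount)
    rel = mat - mat.mean(axis=0, keepdims=True)          # change vs all-sample mean
    sd = rel.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (rel - rel.mean(axis=1, keepdims=True)) / sd      # per-sample z-score
    if not center_variables:
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        scores = u[:, :2] * s[:2]
    else:
        scores = pca_scores(z, 2)
    coords = pd.DataFrame({"sample_id": sample_ids, "PC1": scores[:, 0], "PC2": scores[:, 1]})
    summary = None
    if sample_meta is not None:
        merged = coords.merge(sample_meta, on="sample_id")
        summary = (
            merged.groupby(["regulator", "timepoint"])[["PC1", "PC2"]]
            .agg(["mean", "sem"])
        )
        summary.columns = ["_".join(c) for c in summary.columns]
        summary = summary.reset_index()
    return coords, summary


def rna_expression_change(
    counts: pd.DataFrame,
    groups: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Median per-group log2 fold change vs t=0, 3-point moving average.

    counts: genes x timepoints (columns are timepoints in minutes,
    including 0); groups: expression group per gene (same index). Genes
    absent (NaN) at t=0 are dropped.
    """
    if 0 not in counts.columns:
        raise ValueError("t=0 counts required")
    counts = counts.dropna(subset=[0])
    lfc = np.log2(counts.add(pseudocount).div(counts[0] + pseudocount, axis=0))
    rows = []
    times = sorted(counts.columns)
    for g in sorted(groups.dropna().unique()):
        idx = groups[groups == g].index.intersection(counts.index)
        medians = lfc.loc[idx, times].median(axis=0).to_numpy()
        rows.append(pd.DataFrame({
            "group": g, "time": times,
            "median_lfc": medians,
            "smoothed": smooth(medians, 3),
        }))
    return pd.concat(rows, ignore_index=True)
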