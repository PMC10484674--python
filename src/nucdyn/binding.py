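"""ChEC-seq binding analytics.

Covers the regulator-centric statistics (enrichment z-scores across
feature types, promoter binding preference) and the TF-centric ones:
PWM motif scanning and genomic categorization, motif-centered occupancy
matrices, spike-in based absolute binding (via a control factor with
exactly three strong sites), bound/unbound motif classification at a
two-fold-over-background threshold, and sensor levels around motif
groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack
from .dynamics import ChangeEstimate, chec_relative_change

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MOTIF_WINDOW_HALFWIDTH = 80
SENSOR_WINDOW_HALFWIDTH = 75
SPIKEIN_FLANK = (6, 25)       # |offset| range used for unique TF reads
BOUND_FOLD_THRESHOLD = 2.0
MOTIF_CATEGORIES = ("telomere", "rRNA", "gene_body", "promoter")
MOTIF_ZONES = ("promoter", "5p", "mid", "3p", "terminator")


# ---------------------------------------------------------------- enrichment

def regulator_enrichment(occ: pd.DataFrame) -> pd.DataFrame:
    """Standardized log2 occupancy of each regulator at each feature type.

    Enr[R, T] = (log2 Occ[R, T] - mean_S log2 Occ[S, T]) / std_S log2 Occ[S, T]
    with the sample (n-1) standard deviation taken over regulators S.
    Zero occupancies are replaced by half the smallest positive entry;
    zero-variance columns are set to 0 with a warning.
    """
    occ = occ.astype(float).copy()
    if (occ.to_numpy() < 0).any():
        raise ValueError("occupancies must be non-negative")
    if (occ.to_numpy() == 0).any():
        smallest = occ.to_numpy()[occ.to_numpy() > 0].min()
        logger.warning("replacing zero occupancies with %g", smallest * 0.5)
        occ = occ.replace(0.0, smallest * 0.5)
    logocc = np.log2(occ)
    mean = logocc.mean(axis=0)
    std = logocc.std(axis=0, ddof=1)
    enr = (logocc - mean) / std
    degenerate = std == 0
    if degenerate.any():
        logger.warning("zero-variance feature-type columns set to 0: %s",
                       list(std.index[degenerate]))
        enr.loc[:, degenerate] = 0.0
    return enr


def promoter_preference(track: CoverageTrack, promoters: pd.DataFrame) -> pd.Series:
    """Promoter binding signal: total normalized coverage per promoter."""
    vals = {}
    for _, p in promoters.iterrows():
        arr = track.data[p["chrom"]]
        vals[p["gene"]] = float(arr[max(0, p["start"]) : min(len(arr), p["end"])].sum())
    return pd.Series(vals, dtype=float)


def preference_similarity(a: pd.Series, b: pd.Series) -> float:
    """Pearson correlation between two promoter binding signal vectors."""
    common = a.index.intersection(b.index)
    x, y = a[common].to_numpy(), b[common].to_numpy()
    if len(common) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


# ------------------------------------------------------------ motif scanning

def encode_sequence(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        out[arr == ord(base)] = i
    return out


def pwm_log_odds(pwm: np.ndarray, background: np.ndarray | None = None) -> np.ndarray:
    """log2 odds matrix (4 x width) of a probability PWM vs background."""
    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape[0] != 4:
        raise ValueError("PWM must have 4 rows (A, C, G, T)")
    if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("PWM columns must sum to 1")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    with np.errstate(divide="ignore"):
        return np.log2(pwm) - np.log2(bg)[:, None]


def reverse_complement_pwm(pwm: np.ndarray) -> np.ndarray:
    return np.asarray(pwm)[::-1, ::-1]


def _scan_strand(codes: np.ndarray, lod: np.ndarray) -> np.ndarray:
    """Scores of every window start position (NaN where ambiguous bases)."""
    w = lod.shape[1]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    for j in range(w):
        c = codes[j : j + n]
        ok = c >= 0
        bad |= ~ok
        scores += np.where(ok, lod[np.clip(c, 0, 3), j], 0.0)
    scores[bad] = -np.inf
    return scores


def scan_motifs(
    pwm: np.ndarray,
    sequences: Mapping[str, str],
    background: np.ndarray | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """All PWM occurrences on both strands with log-odds >= threshold.

    threshold defaults to 80% of the maximum attainable log-odds score.
    Positions are reported 0-based at the match start in + strand
    orientation. Returns columns (chrom, start, end, strand, score).
    """
    lod = pwm_log_odds(pwm, background)
    w = lod.shape[1]
    if threshold is None:
        threshold = 0.8 * float(np.max(lod, axis=0).sum())
    rc_lod = pwm_log_odds(reverse_complement_pwm(pwm), background)
    rows = []
    for chrom, seq in sequences.items():
        codes = encode_sequence(seq)
        for strand, mat in (("+", lod), ("-", rc_lod)):
            scores = _scan_strand(codes, mat)
            for pos in np.nonzero(scores >= threshold)[0]:
                rows.append({"chrom": chrom, "start": int(pos), "end": int(pos) + w,
                             "strand": strand, "score": float(scores[pos])})
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "score"])
    return out.sort_values(["chrom", "start", "strand"], kind="mergesort").reset_index(drop=True)


def categorize_motifs(
    motifs: pd.DataFrame,
    genes: pd.DataFrame,
    specials: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign each motif to telomere > rRNA > gene body > promoter.

    Promoter means "any remaining intergenic position". A motif is
    placed by its center; gene body = within the TSS-TTS span of any
    gene. specials provides telomere and rRNA intervals (types
    "telomere", "rRNA37"/"rRNA5"/"rRNA").
    """
    out = motifs.copy()
    centers = (out["start"] + out["end"]) // 2

    def in_any(sub: pd.DataFrame, chrom: str, pos: int) -> bool:
        rows = sub[sub["chrom"] == chrom]
        return bool(((rows["start"] <= pos) & (pos < rows["end"])).any())

    telo = specials[specials["type"] == "telomere"] if specials is not None else pd.DataFrame(columns=["chrom", "start", "end"])
    rrna = (specials[specials["type"].str.startswith("rRNA")]
            if specials is not None else pd.DataFrame(columns=["chrom", "start", "end"]))
    cats = []
    for (_, m), pos in zip(out.iterrows(), centers):
        if in_any(telo, m["chrom"], pos):
            cats.append("telomere")
        elif in_any(rrna, m["chrom"], pos):
            cats.append("rRNA")
        elif in_any(genes, m["chrom"], pos):
            cats.append("gene_body")
        else:
            cats.append("promoter")
    out["category"] = cats
    return out


# -------------------------------------------------------- motif-level signal

def _motif_window_values(track: CoverageTrack, motif: pd.Series, halfwidth: int) -> np.ndarray:
    """Strand-oriented coverage at offsets -halfwidth..+halfwidth around the
    motif center (midpoint of the match); NaN beyond chromosome edges."""
    arr = track.data[motif["chrom"]]
    center = (int(motif["start"]) + int(motif["end"])) // 2
    offsets = np.arange(-halfwidth, halfwidth + 1)
    pos = center + offsets if motif.get("strand", "+") == "+" else center - offsets
    ok = (pos >= 0) & (pos < len(arr))
    return np.where(ok, arr[np.clip(pos, 0, len(arr) - 1)], np.nan)


def motif_occupancy(
    track: CoverageTrack,
    motifs: pd.DataFrame,
    halfwidth: int = MOTIF_WINDOW_HALFWIDTH,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-motif occupancy matrix and per-category mean profiles.

    Matrix rows (one per motif) hold strand-oriented coverage at
    -halfwidth..+halfwidth around the motif center, sorted by category
    and total occupancy (descending). The second frame is the mean
    profile per category.
    """
    mat = np.vstack([
        _motif_window_values(track, m, halfwidth) for _, m in motifs.iterrows()
    ]) if len(motifs) else np.empty((0, 2 * halfwidth + 1))
    offsets = np.arange(-halfwidth, halfwidth + 1)
    matrix = pd.DataFrame(mat, columns=offsets, index=motifs.index)
    matrix.insert(0, "category", motifs["category"].to_numpy())
    totals = np.nansum(mat, axis=1) if len(motifs) else np.empty(0)
    matrix.insert(1, "total", totals)
    matrix = matrix.sort_values(["category", "total"], ascending=[True, False], kind="mergesort")
    means = matrix.groupby("category")[list(offsets)].mean()
    return matrix, means


@dataclass
class SpikeInResult:
    """Absolute TF binding referenced to an internal spike-in."""

    spikein_reads: float
    unique_tf_reads: dict[str, float]   # per category mean flank occupancy
    absolute_binding: dict[str, float]  # unique_tf_reads / spikein_reads


def spikein_absolute_binding(
    track: CoverageTrack,
    spikein_windows: Sequence[tuple[str, int, int]],
    motifs: pd.DataFrame,
    flank: tuple[int, int] = SPIKEIN_FLANK,
    categories: Sequence[str] = ("promoter", "gene_body"),
) -> SpikeInResult:
    """Spike-in normalized TF binding per motif category.

    spike-in reads = summed coverage in the three control windows;
    unique TF reads = mean coverage over flank offsets -25..-6 and
    +6..+25 around all motifs of the category (the exact binding site
    is excluded); absolute binding = unique TF reads / spike-in reads.
    The ratio is invariant to global depth rescaling.
    """
    if len(spikein_windows) != 3:
        raise ValueError("the spike-in factor has exactly 3 target sites")
    spike = 0.0
    for chrom, s, e in spikein_windows:
        arr = track.data[chrom]
        spike += float(arr[max(0, s) : min(len(arr), e)].sum())
    if spike <= 0:
        raise ValueError("no spike-in signal mass")
    near, far = flank
    offsets = np.concatenate([np.arange(-far, -near + 1), np.arange(near, far + 1)])
    tf_reads, absolute = {}, {}
    for cat in categories:
        sub = motifs[motifs["category"] == cat]
        vals = []
        for _, m in sub.iterrows():
            arr = track.data[m["chrom"]]
            center = (int(m["start"]) + int(m["end"])) // 2
            pos = center + offsets
            ok = (pos >= 0) & (pos < len(arr))
            vals.append(arr[pos[ok]])
        pooled = np.concatenate(vals) if vals else np.empty(0)
        tf_reads[cat] = float(pooled.mean()) if pooled.size else float("nan")
        absolute[cat] = tf_reads[cat] / spike
    return SpikeInResult(spike, tf_reads, absolute)


def gene_body_promoter_ratio(
    track: CoverageTrack,
    motifs: pd.DataFrame | None = None,
    positions: Mapping[str, Iterable[tuple[str, int, int]]] | None = None,
    halfwidth: int = MOTIF_WINDOW_HALFWIDTH,
) -> float:
    """log2 of mean gene-body over mean promoter occupancy.

    Motif variant (default): mean normalized occupancy over +/-halfwidth
    windows around gene-body motifs divided by the same over promoter
    motifs. Positional variant: pass positions={"gene_body": intervals,
    "promoter": intervals} to average over all category positions.
    """
    def motif_mean(cat: str) -> float:
        sub = motifs[motifs["category"] == cat]
        vals = [_motif_window_values(track, m, halfwidth) for _, m in sub.iterrows()]
        pooled = np.concatenate(vals) if vals else np.empty(0)
        return float(np.nanmean(pooled)) if pooled.size else float("nan")

    def positional_mean(cat: str) -> float:
        vals = []
        for chrom, s, e in positions[cat]:
            arr = track.data[chrom]
            vals.append(arr[max(0, s) : min(len(arr), e)])
        pooled = np.concatenate(vals) if vals else np.empty(0)
        return float(pooled.mean()) if pooled.size else float("nan")

    if positions is not None:
        gb, prom = positional_mean("gene_body"), positional_mean("promoter")
    else:
        gb, prom = motif_mean("gene_body"), motif_mean("promoter")
    if not np.isfinite(prom) or prom == 0:
        return float("nan")
    return float(np.log2(gb / prom))


def category_background(
    track: CoverageTrack,
    genes: pd.DataFrame,
    specials: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Genome-wide mean coverage at gene-body vs promoter (intergenic)
    positions, excluding telomere and rRNA stretches from both."""
    masks = {c: np.zeros(n, dtype=np.int8) for c, n in track.layout.items()}
    for _, g in genes.iterrows():
        masks[g["chrom"]][g["start"] : g["end"]] = 1
    if specials is not None:
        excl = specials[specials["type"].map(lambda t: t == "telomere" or str(t).startswith("rRNA"))]
        for _, sp in excl.iterrows():
            masks[sp["chrom"]][sp["start"] : sp["end"]] = 2
    gb_vals = np.concatenate([track.data[c][masks[c] == 1] for c in masks])
    prom_vals = np.concatenate([track.data[c][masks[c] == 0] for c in masks])
    return {
        "gene_body": float(gb_vals.mean()) if gb_vals.size else float("nan"),
        "promoter": float(prom_vals.mean()) if prom_vals.size else float("nan"),
    }


def classify_bound_motifs(
    track: CoverageTrack,
    motifs: pd.DataFrame,
    background: Mapping[str, float],
    halfwidth: int = MOTIF_WINDOW_HALFWIDTH,
    fold: float = BOUND_FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Bound/unbound call per promoter or gene-body motif.

    A motif is bound iff its mean occupancy over the +/-halfwidth window
    is at least `fold` times the mean occupancy of a position of its
    category (inclusive threshold). Motifs of categories with zero or
    undefined background stay unclassified (bound = NA). Adds columns
    bound, occupancy_ratio and group (e.g. "promoter-bound").
    """
    out = motifs.copy()
    ratios, bound, group = [], [], []
    for _, m in out.iterrows():
        bg = background.get(m["category"], float("nan"))
        vals = _motif_window_values(track, m, halfwidth)
        occ = float(np.nanmean(vals))
        if not np.isfinite(bg) or bg <= 0:
            ratios.append(float("nan")); bound.append(pd.NA); group.append(pd.NA)
            continue
        ratio = occ / bg
        ratios.append(ratio)
        b = bool(ratio >= fold)
        bound.append(b)
        group.append(f"{m['category']}-{'bound' if b else 'unbound'}")
    out["occupancy_ratio"] = ratios
    out["bound"] = pd.array(bound, dtype="boolean")
    out["group"] = group
    return out


def sensor_level_at_motif_groups(
    sensor_tracks: Mapping[int, CoverageTrack],
    grouped_motifs: pd.DataFrame,
    halfwidth: int = SENSOR_WINDOW_HALFWIDTH,
) -> pd.DataFrame:
    """Mean sensor (HA or myc) level around each motif group over time.

    Groups are fixed (taken from the post-depletion classification);
    per timepoint the coverage over +/-halfwidth windows is pooled
    across all motifs of a group. Empty groups yield missing values.
    """
    groups = [g for g in grouped_motifs["group"].dropna().unique()]
    rows = []
    for t, track in sorted(sensor_tracks.items()):
        for g in groups:
            sub = grouped_motifs[grouped_motifs["group"] == g]
            vals = [_motif_window_values(track, m, halfwidth) for _, m in sub.iterrows()]
            pooled = np.concatenate(vals) if vals else np.empty(0)
            rows.append({"timepoint": t, "group": g,
                         "level": float(np.nanmean(pooled)) if pooled.size else np.nan,
                         "n_motifs": len(sub)})
    return pd.DataFrame(rows)


def assign_motif_zones(motifs: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Attach each motif's genic zone (promoter/5p/mid/3p/terminator) and
    the parent gene's expression group, by feature membership of the
    motif center (first matching zone in MOTIF_ZONES order)."""
    out = motifs.copy()
    zones, groups = [], []
    by_zone = {z: features[features["type"] == z] for z in MOTIF_ZONES}
    for _, m in out.iterrows():
        center = (int(m["start"]) + int(m["end"])) // 2
        zone, grp = pd.NA, pd.NA
        for z in MOTIF_ZONES:
            sub = by_zone[z]
            hit = sub[(sub["chrom"] == m["chrom"]) & (sub["start"] <= center) & (center < sub["end"])]
            if len(hit):
                zone = z
                grp = hit.iloc[0]["group"]
                break
        zones.append(zone); groups.append(grp)
    out["zone"] = zones
    out["expr_group"] = pd.array(groups, dtype="Int64")
    return out


def tf_change_by_region(
    tracks: Mapping[tuple[int, int], CoverageTrack],
    zoned_motifs: pd.DataFrame,
    horizon: int = 60,
    halfwidth: int = MOTIF_WINDOW_HALFWIDTH,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Relative TF binding change per (genic zone x expression group).

    Motif +/-halfwidth windows form the regions of each stratum; the
    ChEC change estimator (stratum-mean occupancy, slope x horizon) is
    applied per stratum. Empty strata are missing.
    """
    rows = []
    zones = [z for z in MOTIF_ZONES if (zoned_motifs["zone"] == z).any()]
    for zone in zones:
        for grp in sorted(zoned_motifs.loc[zoned_motifs["zone"] == zone, "expr_group"].dropna().unique()):
            sub = zoned_motifs[(zoned_motifs["zone"] == zone) & (zoned_motifs["expr_group"] == grp)]
            regions = pd.DataFrame({
                "feature_id": [f"motif{i}" for i in sub.index],
                "chrom": sub["chrom"].to_numpy(),
                "start": ((sub["start"] + sub["end"]) // 2 - halfwidth).to_numpy(),
                "end": ((sub["start"] + sub["end"]) // 2 + halfwidth + 1).to_numpy(),
            })
            est = chec_relative_change(tracks, regions, horizon=horizon, pseudocount=pseudocount)
            rows.append({"zone": zone, "group": int(grp), **est.as_dict()})
    return pd.DataFrame(rows)
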