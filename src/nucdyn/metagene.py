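"""Scaled and unscaled metagene profiles.

The scaled metagene is a fixed 1350-bp coordinate frame: 250 bp before
the TSS, 350 bp after the TSS, a 300-point length-normalized middle,
350 bp before the TTS and 100 bp after the TTS. Fixed segments average
raw coverage position-wise across genes; the middle of each gene longer
than 1050 bp is smoothed (10-bp window) and resampled at 300 regular
positions before averaging. This preserves the nucleosome patterning at
gene starts and ends while aligning gene middles of different lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, smooth

SEGMENTS = (("pre_tss", 250), ("post_tss", 350), ("middle", 300), ("pre_tts", 350), ("post_tts", 100))
FRAME_LENGTH = sum(n for _, n in SEGMENTS)  # = 1350
MIN_GENE_LENGTH = 700
MIDDLE_MIN_LENGTH = 1050
MIDDLE_POINTS = 300
MIDDLE_SMOOTH_WINDOW = 10


@dataclass
class MetageneFrame:
    """Per-gene genomic position maps for the scaled metagene.

    fixed[gene] is an int array of length 1050 (pre_tss + post_tss +
    pre_tts + post_tts, in transcription order) of genomic positions,
    -1 where the position falls off the chromosome. middle[gene] holds
    (chrom slice bounds, strand) for genes long enough to contribute a
    rescaled middle.
    """

    genes: pd.DataFrame  # eligible genes (gene, chrom, start, end, strand)
    fixed: dict[str, np.ndarray]
    middle: dict[str, tuple[int, int]]  # genomic [lo, hi) of the middle span

    @property
    def eligible_genes(self) -> list[str]:
        return list(self.genes["gene"])


def _fixed_positions(gene: pd.Series) -> np.ndarray:
    start, end = int(gene["start"]), int(gene["end"])
    if gene["strand"] == "+":
        parts = [
            np.arange(start - 250, start),
            np.arange(start, start + 350),
            np.arange(end - 350, end),
            np.arange(end, end + 100),
        ]
        return np.concatenate(parts)
    parts = [
        np.arange(end + 249, end - 1, -1),
        np.arange(end - 1, end - 351, -1),
        np.arange(start + 349, start - 1, -1),
        np.arange(start - 1, start - 101, -1),
    ]
    return np.concatenate(parts)


def build_frame(genes: pd.DataFrame, layout: Mapping[str, int] | None = None) -> MetageneFrame:
    """Metagene frame over all genes with known TSS and TTS and length >= 700.

    Genes longer than 1050 bp additionally map their middle span
    (TSS+350 .. TTS-350) to the 300 interpolation points. Positions
    outside the chromosome are marked missing (-1).
    """
    lengths = genes["end"] - genes["start"]
    eligible = genes.loc[lengths >= MIN_GENE_LENGTH].reset_index(drop=True)
    if len(eligible) == 0:
        raise ValueError("no eligible genes (length >= 700 with TSS and TTS)")
    fixed: dict[str, np.ndarray] = {}
    middle: dict[str, tuple[int, int]] = {}
    for _, gene in eligible.iterrows():
        pos = _fixed_positions(gene)
        if layout is not None:
            n = layout[gene["chrom"]]
            pos = np.where((pos >= 0) & (pos < n), pos, -1)
        fixed[gene["gene"]] = pos
        if gene["end"] - gene["start"] > MIDDLE_MIN_LENGTH:
            middle[gene["gene"]] = (int(gene["start"]) + 350, int(gene["end"]) - 350)
    return MetageneFrame(genes=eligible, fixed=fixed, middle=middle)


def _middle_samples(track: CoverageTrack, gene: pd.Series, span: tuple[int, int],
                    points: int = MIDDLE_POINTS, window: int = MIDDLE_SMOOTH_WINDOW) -> np.ndarray:
    lo, hi = span
    vals = track.data[gene["chrom"]][lo:hi]
    if gene["strand"] == "-":
        vals = vals[::-1]
    # a centered even window is ill-defined; default to the symmetric w+1 window
    w = window + 1 if window % 2 == 0 else window
    sm = smooth(vals, w)
    length = len(vals)
    xk = np.arange(points) * (length - 1) / (points - 1)
    return np.interp(xk, np.arange(length), sm)


def metagene_profile(
    track: CoverageTrack,
    frame: MetageneFrame,
    gene_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean coverage along the 1350-bp scaled metagene for a gene subset.

    Returns a DataFrame (position, value, n_genes); positions 0..1349.
    Fixed segments are per-position means of raw coverage; the middle is
    the mean of each contributing gene's smoothed, resampled middle.
    """
    genes = frame.genes if gene_subset is None else frame.genes[frame.genes["gene"].isin(set(gene_subset))]
    if len(genes) == 0:
        raise ValueError("empty gene subset")
    fixed_rows, mid_rows = [], []
    for _, gene in genes.iterrows():
        pos = frame.fixed[gene["gene"]]
        arr = track.data[gene["chrom"]]
        vals = np.where(pos >= 0, arr[np.clip(pos, 0, len(arr) - 1)], np.nan)
        fixed_rows.append(vals)
        if gene["gene"] in frame.middle:
            mid_rows.append(_middle_samples(track, gene, frame.middle[gene["gene"]]))
    fixed_mat = np.vstack(fixed_rows)
    fixed_mean = np.nanmean(fixed_mat, axis=0)
    fixed_n = np.sum(~np.isnan(fixed_mat), axis=0)
    if mid_rows:
        mid_mat = np.vstack(mid_rows)
        mid_mean = mid_mat.mean(axis=0)
        mid_n = np.full(MIDDLE_POINTS, len(mid_rows))
    else:
        mid_mean = np.full(MIDDLE_POINTS, np.nan)
        mid_n = np.zeros(MIDDLE_POINTS, dtype=int)
    value = np.concatenate([fixed_mean[:600], mid_mean, fixed_mean[600:]])
    n = np.concatenate([fixed_n[:600], mid_n, fixed_n[600:]])
    return pd.DataFrame({"position": np.arange(FRAME_LENGTH), "value": value, "n_genes": n})


def minmax_scale(profile: pd.DataFrame) -> pd.DataFrame:
    """Affine rescale of a profile so its minimum is 0 and maximum 1.

    A constant profile has no defined scaling: all values become NaN.
    """
    out = profile.copy()
    v = out["value"].to_numpy(dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    out["value"] = np.full_like(v, np.nan) if hi == lo else (v - lo) / (hi - lo)
    return out


def metagene_relative_change(
    profiles: Mapping[int, Sequence[pd.DataFrame]],
    pseudocount: float = 1.0,
) -> dict[int, np.ndarray]:
    """log2 change of repeat-averaged metagene profiles vs the t=0 profile.

    profiles maps timepoint -> list of repeat profiles. Per position:
    log2(mean-across-repeats + pc) - log2(t0 mean-across-repeats + pc).
    """
    if 0 not in profiles:
        raise ValueError("t=0 profiles required")
    means = {
        t: np.mean([p["value"].to_numpy(dtype=float) for p in reps], axis=0)
        for t, reps in profiles.items()
    }
    base = np.log2(means[0] + pseudocount)
    return {t: np.log2(m + pseudocount) - base for t, m in means.items()}


def unscaled_metagene(
    track: CoverageTrack,
    genes: pd.DataFrame,
    window: tuple[int, int] = (-500, 1000),
) -> pd.DataFrame:
    """TSS-aligned strand-aware mean profile without length rescaling.

    window is (upstream, downstream) relative to the TSS; genes drop out
    of positions that leave their chromosome.
    """
    lo, hi = window
    offsets = np.arange(lo, hi)
    rows = []
    for _, gene in genes.iterrows():
        arr = track.data[gene["chrom"]]
        if gene["strand"] == "+":
            pos = int(gene["start"]) + offsets
        else:
            pos = int(gene["end"]) - 1 - offsets
        ok = (pos >= 0) & (pos < len(arr))
        rows.append(np.where(ok, arr[np.clip(pos, 0, len(arr) - 1)], np.nan))
    mat = np.vstack(rows)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
    return pd.DataFrame({
        "position": offsets,
        "value": mean,
        "n_genes": np.sum(~np.isnan(mat), axis=0),
    })


def modification_enrichment(
    mod_profile: np.ndarray,
    ha_profile: np.ndarray,
    window: int = 51,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Histone-modification enrichment along a metagene.

    Both profiles are smoothed with a centered running average (51 bp)
    and the enrichment per position is
    log2((smooth(mod)+pc) / (smooth(HA)+pc)).
    """
    m = smooth(np.asarray(mod_profile, dtype=float), window)
    h = smooth(np.asarray(ha_profile, dtype=float), window)
    return np.log2((m + pseudocount) / (h + pseudocount))
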