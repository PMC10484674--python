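"""Genomic feature taxonomy for the depletion screen.

Genes are carved into the regions whose histone dynamics are compared:
promoter (the -2 and -1 nucleosome footprints), NDR (the open stretch
between the -1 and +1 footprints), 5' (first 350 bp after the TSS),
3' (last 350 bp before the TTS), mid (the rest), and terminator
(100 bp downstream of the TTS). Special loci (histone promoters, rRNA,
ARS, centromeres, tRNA, TY+LTR, telomeres) are carried through as-is.
Genes are further stratified into five expression groups.

Coordinate convention: genes are stored as 0-based half-open bodies
(chrom, start, end, strand). For a + strand gene the TSS is `start` and
the TTS boundary is `end`; minus-strand genes are mirrored (TSS at
`end`, transcription toward lower coordinates).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .coverage import CoverageTrack

logger = logging.getLogger(__name__)

#: nucleosomes protect ~147 bp, i.e. dyad +/- 73
NUCLEOSOME_HALFWIDTH = 73
#: 5'/3' gene-body margins (bp after TSS / before TTS)
BODY_MARGIN = 350
TERMINATOR_LENGTH = 100
#: expression-group sizes of the reference gene set, lowest to highest
REFERENCE_GROUP_SIZES = (428, 1766, 3070, 832, 300)

GENE_REGION_TYPES = ("5p", "mid", "3p")
FEATURE_COLUMNS = ["feature_id", "type", "chrom", "start", "end", "gene", "group"]


def _footprint(dyad: int) -> tuple[int, int]:
    return dyad - NUCLEOSOME_HALFWIDTH, dyad + NUCLEOSOME_HALFWIDTH + 1


def gene_length(gene: pd.Series) -> int:
    return int(gene["end"] - gene["start"])


def upstream_window(gene: pd.Series, far: int, near: int) -> tuple[str, int, int]:
    """Strand-aware window [TSS-far, TSS-near) upstream of the TSS."""
    if gene["strand"] == "+":
        return gene["chrom"], int(gene["start"] - far), int(gene["start"] - near)
    return gene["chrom"], int(gene["end"] + near), int(gene["end"] + far)


def gene_body_segments(gene: pd.Series) -> dict[str, tuple[int, int]]:
    """5'/mid/3' genomic intervals of one gene (strand-aware, half-open).

    For genes of exactly 2*BODY_MARGIN the mid is empty and 5' abuts 3';
    shorter genes get the first min(350, L) bp as 5' and the remainder
    as 3' so the segments stay disjoint.
    """
    start, end = int(gene["start"]), int(gene["end"])
    length = end - start
    five_len = min(BODY_MARGIN, length)
    three_len = min(BODY_MARGIN, length - five_len)
    if gene["strand"] == "+":
        five = (start, start + five_len)
        three = (end - three_len, end)
        mid = (five[1], three[0])
    else:
        five = (end - five_len, end)
        three = (start, start + three_len)
        mid = (three[1], five[0])
    return {"5p": five, "mid": mid, "3p": three}


def assign_features(
    genes: pd.DataFrame,
    nucleosomes: pd.DataFrame,
    specials: pd.DataFrame | None = None,
    layout: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Build the feature table from gene annotation and nucleosome dyads.

    nucleosomes: columns (gene, label, chrom, pos) with labels counted
    along the transcription direction (..., -2, -1, +1, +2, ...).
    specials: optional (type, chrom, start, end) intervals copied through.
    Genes lacking a -1 or +1 dyad are skipped with a warning. A feature
    may span several disjoint intervals (the promoter = two footprints)
    sharing one feature_id.
    """
    rows: list[dict] = []
    dyads = {g: dict(zip(sub["label"], sub["pos"])) for g, sub in nucleosomes.groupby("gene")}

    def add(fid: str, ftype: str, chrom: str, start: int, end: int, gene: str | None) -> None:
        if layout is not None:
            start = max(0, start)
            end = min(layout[chrom], end)
        if end > start:
            rows.append(
                {"feature_id": fid, "type": ftype, "chrom": chrom,
                 "start": int(start), "end": int(end), "gene": gene, "group": pd.NA}
            )

    for _, gene in genes.iterrows():
        gid, chrom = gene["gene"], gene["chrom"]
        d = dyads.get(gid, {})
        if -1 not in d or 1 not in d:
            logger.warning("gene %s lacks -1/+1 dyads; skipped", gid)
            continue
        segs = gene_body_segments(gene)
        for region in GENE_REGION_TYPES:
            s, e = segs[region]
            add(f"{gid}:{region}", region, chrom, s, e, gid)
        # promoter = -2 and -1 nucleosome footprints (one feature, two intervals)
        for label in (-2, -1):
            if label in d:
                s, e = _footprint(int(d[label]))
                add(f"{gid}:promoter", "promoter", chrom, s, e, gid)
        # NDR: open interval between the -1 and +1 footprints
        minus1, plus1 = int(d[-1]), int(d[1])
        if gene["strand"] == "+":
            add(f"{gid}:NDR", "NDR", chrom, _footprint(minus1)[1], _footprint(plus1)[0], gid)
            add(f"{gid}:terminator", "terminator", chrom, gene["end"], gene["end"] + TERMINATOR_LENGTH, gid)
        else:
            add(f"{gid}:NDR", "NDR", chrom, _footprint(plus1)[1], _footprint(minus1)[0], gid)
            add(f"{gid}:terminator", "terminator", chrom, gene["start"] - TERMINATOR_LENGTH, gene["start"], gid)

    if specials is not None:
        for i, sp in specials.reset_index(drop=True).iterrows():
            add(f"{sp['type']}:{i}", sp["type"], sp["chrom"], int(sp["start"]), int(sp["end"]), None)

    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def expression_bins(
    genes: pd.DataFrame,
    scheme: Iterable[int | float] = REFERENCE_GROUP_SIZES,
) -> pd.Series:
    """Rank-based split of genes into 5 expression groups (5 = highest).

    The scheme gives relative group sizes (lowest expression first);
    cumulative boundaries are ceil(n * cumulative proportion), which
    reproduces the reference counts on the reference gene set. Ties are
    broken by stable gene-id order, so the grouping depends only on
    expression ranks (monotone-relabeling invariant).
    """
    scheme = np.asarray(list(scheme), dtype=float)
    if scheme.ndim != 1 or len(scheme) < 1 or (scheme <= 0).any():
        raise ValueError("scheme must be positive group sizes/proportions")
    props = np.cumsum(scheme) / scheme.sum()
    n = len(genes)
    bounds = [math.ceil(n * p) for p in props]
    bounds[-1] = n
    order = genes.sort_values(["expression", "gene"], kind="mergesort").index
    groups = pd.Series(0, index=genes.index, dtype=int)
    lo = 0
    for k, hi in enumerate(bounds, start=1):
        groups.loc[order[lo:hi]] = k
        lo = hi
    return groups


def add_expression_groups(features: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Attach each gene's expression group to its features."""
    groups = expression_bins(genes)
    mapping = dict(zip(genes["gene"], groups))
    out = features.copy()
    out["group"] = out["gene"].map(mapping).astype("Int64")
    return out


def opn_score(
    track: CoverageTrack,
    gene: pd.Series,
    proximal: tuple[int, int] = (150, 0),
    distal: tuple[int, int] = (400, 200),
) -> float:
    """Promoter-architecture score: TSS-proximal over distal occupancy.

    Mean coverage over [TSS-150, TSS) divided by the mean over
    [TSS-400, TSS-200), strand-aware. Scores above 1 indicate an
    occupied proximal nucleosome (OPN), below 1 a depleted one (DPN).
    NaN when the distal mean is zero or a window leaves the chromosome.
    """
    def window_mean(far: int, near: int) -> float:
        chrom, s, e = upstream_window(gene, far, near)
        arr = track.data[chrom]
        if s < 0 or e > len(arr) or e <= s:
            return float("nan")
        return float(arr[s:e].mean())

    prox = window_mean(*proximal)
    dist = window_mean(*distal)
    if not np.isfinite(dist) or dist == 0 or not np.isfinite(prox):
        return float("nan")
    return prox / dist


def define_promoter_intervals(
    genes: pd.DataFrame,
    layout: Mapping[str, int],
    min_length: int = 700,
    cap: bool = False,
) -> pd.DataFrame:
    """Per-gene promoter: upstream from the TSS to the closest upstream ORF,
    but at least `min_length` bp (clipped at chromosome edges).

    With cap=True the alternative reading is used: the promoter never
    exceeds min_length even when the upstream ORF is farther.
    """
    rows = []
    for chrom, sub in genes.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for _, gene in sub.iterrows():
            if gene["strand"] == "+":
                tss = int(gene["start"])
                upstream_ends = ends[(ends <= tss) & (starts < gene["start"])]
                boundary = int(upstream_ends.max()) if len(upstream_ends) else None
                lo = tss - min_length if boundary is None else min(boundary, tss - min_length)
                if cap and boundary is not None:
                    lo = max(boundary, tss - min_length)
                s, e = max(0, lo), tss
            else:
                tss = int(gene["end"])
                downstream_starts = starts[(starts >= tss) & (ends > gene["end"])]
                boundary = int(downstream_starts.min()) if len(downstream_starts) else None
                hi = tss + min_length if boundary is None else max(boundary, tss + min_length)
                if cap and boundary is not None:
                    hi = min(boundary, tss + min_length)
                s, e = tss, min(layout[chrom], hi)
            rows.append({"gene": gene["gene"], "chrom": chrom, "start": s, "end": e})
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def feature_positions(features: pd.DataFrame, feature_id: str) -> list[tuple[str, int, int]]:
    sub = features[features["feature_id"] == feature_id]
    return [(r["chrom"], r["start"], r["end"]) for _, r in sub.iterrows()]


def feature_mean_coverage(track: CoverageTrack, features: pd.DataFrame) -> pd.Series:
    """Mean coverage per feature_id, pooling all of a feature's intervals."""
    sums: dict[str, float] = {}
    lens: dict[str, int] = {}
    for _, r in features.iterrows():
        arr = track.data[r["chrom"]]
        s, e = max(0, r["start"]), min(len(arr), r["end"])
        if e <= s:
            continue
        sums[r["feature_id"]] = sums.get(r["feature_id"], 0.0) + float(arr[s:e].sum())
        lens[r["feature_id"]] = lens.get(r["feature_id"], 0) + (e - s)
    return pd.Series({fid: sums[fid] / lens[fid] for fid in sums}, dtype=float)
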