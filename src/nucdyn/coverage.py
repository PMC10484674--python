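"""Per-base coverage tracks and the arithmetic shared by all analyses.

Coverage is the universal currency here: every aligned fragment pair
contributes a single "coverage unit" at its midpoint, tracks are
normalized to a fixed total mass over the nuclear genome excluding the
ribosomal locus, and biological repeats are averaged position-wise.
All genomic coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: chromatin ChIP libraries keep mononucleosome-sized fragments only
CHIP_SIZE_RANGE = (100, 200)
#: library normalization target: total coverage over the non-rDNA genome
NORMALIZATION_TARGET = 10_000_000
#: smoothing windows used for genome-wide sample similarity (bp)
SIMILARITY_WINDOW = {"ChEC": 141, "ChIP": 250}

Interval = tuple[str, int, int]


class CoverageError(ValueError):
    """Raised for invalid coverage operations (bad layout, zero mass...)."""


@dataclass
class SampleMeta:
    """Identity of one sequencing sample.

    regulator : depleted chromatin regulator ("none" for the control)
    epitope   : "myc" | "HA" for the exchange sensor, the ChEC target
                name for ChEC libraries, or "RNA"
    timepoint : minutes after rapamycin addition
    repeat    : biological repeat index (1-based)
    assay     : "ChIP" | "ChEC" | "RNA"
    """

    regulator: str
    epitope: str
    timepoint: int
    repeat: int
    assay: str

    def __post_init__(self) -> None:
        if self.timepoint < 0:
            raise ValueError("timepoint must be >= 0")
        if self.assay not in ("ChIP", "ChEC", "RNA"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.assay == "ChIP" and self.epitope not in ("myc", "HA"):
            raise ValueError("ChIP epitope must be myc or HA")

    @property
    def sample_id(self) -> str:
        return f"{self.regulator}_{self.epitope}_t{self.timepoint}_r{self.repeat}"


@dataclass
class CoverageTrack:
    """Real-valued per-base signal over a genome.

    data maps chromosome name -> float array of per-bp coverage.
    """

    data: dict[str, np.ndarray]
    normalized: bool = False
    sample_id: str | None = None

    def __post_init__(self) -> None:
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}

    @property
    def layout(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            {c: v.copy() for c, v in self.data.items()},
            normalized=self.normalized,
            sample_id=self.sample_id,
        )

    def scale(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {c: v * factor for c, v in self.data.items()},
            normalized=self.normalized,
            sample_id=self.sample_id,
        )

    @classmethod
    def zeros(cls, layout: Mapping[str, int]) -> "CoverageTrack":
        return cls({c: np.zeros(n) for c, n in layout.items()})

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]


def _check_layouts(tracks: Sequence[CoverageTrack]) -> None:
    first = tracks[0].layout
    for t in tracks[1:]:
        if t.layout != first:
            raise CoverageError("tracks have mismatched genome layouts")


def fragment_midpoints(start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Midpoint of a 0-based half-open fragment: floor((start+end)/2)."""
    return (np.asarray(start) + np.asarray(end)) // 2


def fragments_to_coverage(
    fragments: pd.DataFrame,
    layout: Mapping[str, int],
    size_min: int | None = None,
    size_max: int | None = None,
) -> CoverageTrack:
    """Midpoint coverage from aligned fragments with an optional size filter.

    Each fragment whose length lies in [size_min, size_max] (both
    inclusive; no filter when bounds are None, as for ChEC libraries)
    adds exactly 1.0 at floor((start+end)/2). Total coverage mass
    therefore equals the number of retained fragments.
    """
    track = CoverageTrack.zeros(layout)
    if len(fragments) == 0:
        return track
    lengths = fragments["end"].to_numpy() - fragments["start"].to_numpy()
    keep = np.ones(len(fragments), dtype=bool)
    if size_min is not None:
        keep &= lengths >= size_min
    if size_max is not None:
        keep &= lengths <= size_max
    kept = fragments.loc[keep]
    for chrom, sub in kept.groupby("chrom", sort=False, observed=True):
        if chrom not in layout:
            raise CoverageError(f"fragment on unknown chromosome {chrom!r}")
        mids = fragment_midpoints(sub["start"].to_numpy(), sub["end"].to_numpy())
        if mids.size and (mids.min() < 0 or mids.max() >= layout[chrom]):
            raise CoverageError(f"fragment midpoint outside chromosome {chrom!r}")
        np.add.at(track.data[chrom], mids, 1.0)
    return track


def _interval_mask(layout: Mapping[str, int], intervals: Iterable[Interval]) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(n, dtype=bool) for c, n in layout.items()}
    for chrom, start, end in intervals:
        if chrom in masks:
            masks[chrom][max(0, start) : min(len(masks[chrom]), end)] = True
    return masks


def normalize_library(
    track: CoverageTrack,
    exclude: Iterable[Interval] = (),
    target_total: float = NORMALIZATION_TARGET,
) -> CoverageTrack:
    """Scale a track so the total coverage outside `exclude` equals target.

    The excluded (ribosomal) positions are scaled by the same factor —
    they are only left out of the denominator, not zeroed. Idempotent:
    renormalizing applies a factor of 1.
    """
    exclude = list(exclude)
    masks = _interval_mask(track.layout, exclude)
    outside = sum(float(v[~masks[c]].sum()) for c, v in track.data.items())
    if outside <= 0:
        raise CoverageError("no coverage mass outside excluded intervals")
    out = track.scale(target_total / outside)
    out.normalized = True
    return out


def average_repeats(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Position-wise arithmetic mean of repeat tracks (identical layouts)."""
    if not tracks:
        raise CoverageError("no tracks to average")
    _check_layouts(tracks)
    data = {
        c: np.mean([t.data[c] for t in tracks], axis=0) for c in tracks[0].data
    }
    return CoverageTrack(data, normalized=tracks[0].normalized)


def smooth(values: np.ndarray, window: int, even: str = "error") -> np.ndarray:
    """Centered moving average; the window shrinks at the edges.

    For odd windows the average is symmetric around each position. Even
    windows are ill-defined for a centered filter: by default they raise,
    with even="asymmetric" the window covers window//2 positions to the
    left and window//2 - 1 to the right (plus the center).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        if even != "asymmetric":
            raise ValueError("even smoothing window; pass even='asymmetric' to allow")
        left, right = window // 2, window // 2 - 1
    else:
        left = right = window // 2
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n == 0:
        return x.copy()
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth_track(track: CoverageTrack, window: int, even: str = "error") -> CoverageTrack:
    return CoverageTrack(
        {c: smooth(v, window, even=even) for c, v in track.data.items()},
        normalized=track.normalized,
        sample_id=track.sample_id,
    )


def sample_similarity(
    a: CoverageTrack,
    b: CoverageTrack,
    assay: str,
    mask: Iterable[Interval],
) -> float:
    """Genome-wide similarity of two samples of the same assay.

    Both tracks are smoothed with a running average (141 bp for ChEC,
    250 bp for ChIP) and the Pearson correlation is computed across all
    positions in `mask` (the union of promoter and gene-body intervals).
    Returns NaN when either masked vector has zero variance.
    """
    _check_layouts([a, b])
    try:
        window = SIMILARITY_WINDOW[assay]
    except KeyError:
        raise ValueError(f"unknown assay {assay!r}") from None
    masks = _interval_mask(a.layout, mask)
    xs, ys = [], []
    for chrom in a.data:
        m = masks[chrom]
        if not m.any():
            continue
        xs.append(smooth(a.data[chrom], window, even="asymmetric")[m])
        ys.append(smooth(b.data[chrom], window, even="asymmetric")[m])
    if not xs:
        return float("nan")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
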