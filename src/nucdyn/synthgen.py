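"""Synthetic depletion-screen generator with known ground truth.

Builds a small yeast-like genome (genes with TSS/TTS/strand/expression,
phased nucleosome dyads with an NDR between -1 and +1, planted PWM
motifs in promoters and gene bodies, a ribosomal locus, telomeres and
other special loci, and three spike-in sites outside genes) and samples
sequencing fragments for the two assay families:

* exchange-sensor ChIP: ~150-bp fragments centered on nucleosome dyads;
  the HA channel tracks occupancy, the myc channel occupancy times a
  per-region incorporation (myc) fraction. Depleting a regulator
  multiplies the myc fraction of its affected region/expression strata
  by 2^(a * t / 90), i.e. a log-linear trend whose slope the change
  estimator should recover as `a`.
* ChEC: short fragments drawn from per-regulator footprint intensities
  (promoter/gene-body bumps or motif-anchored bumps for TFs) on an
  absolute scale, plus uniform background and, optionally, a spike-in
  population at the three control sites.

Every sample has its own deterministic random stream derived from the
master seed and the sample id, so adding samples never perturbs
existing ones. Noise-free mode replaces Poisson counts by rounded
expectations; exact real-valued expectation tracks are available via
expected_chip_coverage / expected_chec_coverage for closed-form tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, SampleMeta
from .features import expression_bins, gene_body_segments

CHIP_TIMEPOINTS = (0, 20, 40, 60, 90)
CHEC_TIMEPOINTS = (0, 60)

#: steady-state incorporation (myc) fraction by region type
DEFAULT_MYC_BASELINE = {
    "promoter": 0.40, "NDR": 0.40, "5p": 0.15, "mid": 0.10, "3p": 0.12,
    "rDNA": 0.20,
}

#: strong 10-bp consensus PWM (rows A, C, G, T)
def default_pwm() -> np.ndarray:
    consensus = "ACGTGACTCA"
    pwm = np.full((4, len(consensus)), 0.01)
    for j, b in enumerate(consensus):
        pwm["ACGT".index(b), j] = 0.97
    return pwm / pwm.sum(axis=0, keepdims=True)


@dataclass(frozen=True)
class DepletionEffect:
    """True log2 change per ChIP horizon planted for one stratum."""

    regulator: str
    region_type: str
    groups: tuple[int, ...]
    a: float
    epitope: str = "myc"


@dataclass(frozen=True)
class ChecEffect:
    """True log2 binding change per ChEC horizon for one target/zone."""

    regulator: str       # depleted regulator driving the change
    target: str          # ChEC target whose binding changes
    zone: str            # promoter | 5p | mid | 3p | gene_body_motifs | promoter_motifs
    groups: tuple[int, ...]
    a: float


@dataclass
class ChecComponent:
    """One footprint component of a ChEC target's binding model."""

    kind: str            # "tss" | "body" | "motif"
    weight: float        # expected fragments per gene/motif at reference depth units
    sd: float            # Gaussian footprint width (bp)
    offset: int = 0      # bp relative to TSS (kind="tss")
    frac: float = 0.5    # position along the gene body (kind="body")
    times: tuple[int, ...] | None = None  # restrict to timepoints (re-localization)


@dataclass
class ChecTargetModel:
    components: list[ChecComponent]
    background: float = 0.05  # relative per-bp weight


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic screen."""

    chrom_lengths: tuple[int, ...] = (108_000, 122_000)
    n_genes: int = 72
    gene_length_range: tuple[int, int] = (800, 2600)
    intergenic_range: tuple[int, int] = (600, 1200)
    expression_mu: float = 4.0      # log2 expression units
    expression_sigma: float = 1.5
    nucleosome_spacing: int = 165
    plus1_offset: int = 80          # +1 dyad bp downstream of the TSS
    minus1_offset: int = 120        # -1 dyad bp upstream of the TSS
    myc_baseline: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MYC_BASELINE))
    depletion_effects: tuple[DepletionEffect, ...] = ()
    chec_effects: tuple[ChecEffect, ...] = ()
    chec_models: Mapping[str, ChecTargetModel] = field(default_factory=dict)
    chip_depth: float = 200.0       # expected retained fragments per nucleosome (HA)
    chec_depth: float = 50_000.0    # expected fragments per ChEC library
    dinucleosome_fraction: float = 0.15  # of all ChIP fragments; removed by the size filter
    spikein_fraction: float = 0.10
    spikein_sites: tuple[tuple[str, int], ...] | None = None  # resolved by make_genome
    spikein_halfwidth: int = 100
    n_promoter_motifs: int = 24
    n_body_motifs: int = 24
    bound_fraction: float = 0.5
    bound_multiplier: float = 24.0
    chip_timepoints: tuple[int, ...] = CHIP_TIMEPOINTS
    chec_timepoints: tuple[int, ...] = CHEC_TIMEPOINTS
    noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.n_genes <= 0 or self.gene_length_range[0] <= 0:
            raise ValueError("gene counts/lengths must be positive")
        if self.chip_depth <= 0 or self.chec_depth <= 0:
            raise ValueError("depth must be positive")
        if self.spikein_sites is not None and len(self.spikein_sites) != 3:
            raise ValueError("exactly 3 spike-in sites are required")
        valid = {"promoter", "NDR", "5p", "mid", "3p", "terminator"}
        for eff in self.depletion_effects:
            if eff.region_type not in valid:
                raise ValueError(f"unknown region type {eff.region_type!r} in depletion effect")


class SizingError(ValueError):
    """Genome too small for the requested gene count."""


@dataclass
class SyntheticGenome:
    layout: dict[str, int]
    genes: pd.DataFrame          # gene, chrom, start, end, strand, expression, gene_class, group
    nucleosomes: pd.DataFrame    # gene, label, chrom, pos, region
    specials: pd.DataFrame       # type, chrom, start, end
    sequences: dict[str, str]
    pwm: np.ndarray
    motifs: pd.DataFrame         # chrom, start, end, strand, category, gene
    rdna: tuple[str, int, int]
    spikein_sites: list[tuple[str, int]]


@dataclass
class GroundTruth:
    """Everything the recovery analyses compare against."""

    config: SimulationConfig
    motif_truth: pd.DataFrame    # bound flag + occupancy multiplier per motif
    rdna: tuple[str, int, int]
    spikein_windows: list[tuple[str, int, int]]
    spikein_fraction: float

    def chip_factor(self, sample: SampleMeta, region: str, group: int | None, t: int) -> float:
        f = 1.0
        horizon = max(self.config.chip_timepoints)
        for eff in self.config.depletion_effects:
            if (eff.regulator == sample.regulator and eff.epitope == sample.epitope
                    and eff.region_type == region and group in eff.groups):
                f *= 2.0 ** (eff.a * t / horizon)
        return f

    def true_change(self, regulator: str, epitope: str, region: str, group: int) -> float:
        a = 0.0
        for eff in self.config.depletion_effects:
            if (eff.regulator == regulator and eff.epitope == epitope
                    and eff.region_type == region and group in eff.groups):
                a += eff.a
        return a

    def chec_factor(self, regulator: str, target: str, zone: str, group: int | None, t: int) -> float:
        f = 1.0
        horizon = max(self.config.chec_timepoints)
        for eff in self.config.chec_effects:
            if (eff.regulator == regulator and eff.target == target
                    and eff.zone == zone and group in eff.groups):
                f *= 2.0 ** (eff.a * t / horizon)
        return f


def sample_rng(master_seed: int, sample_id: str) -> np.random.Generator:
    """Independent deterministic stream per sample id."""
    return np.random.default_rng([master_seed % (2**31), zlib.crc32(sample_id.encode()) % (2**31)])


# ------------------------------------------------------------------- genome

def _place_genes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = [f"chr{i+1}" for i in range(len(config.chrom_lengths))]
    reserve = {chroms[-1]: 12_000}  # gene-free zone for rDNA + spike-in sites
    rows = []
    placed = 0
    for chrom, length in zip(chroms, config.chrom_lengths):
        cursor = 500
        limit = length - 500 - reserve.get(chrom, 0)
        while placed < config.n_genes:
            gap = int(rng.integers(*config.intergenic_range))
            glen = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
            start = cursor + gap
            if start + glen > limit:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append({"gene": f"g{placed:04d}", "chrom": chrom, "start": start,
                         "end": start + glen, "strand": strand})
            cursor = start + glen
            placed += 1
    if placed < config.n_genes:
        raise SizingError(f"genome too small: placed {placed}/{config.n_genes} genes")
    return pd.DataFrame(rows)


def _nucleosomes_for_gene(gene: pd.Series, config: SimulationConfig) -> list[dict]:
    spacing = config.nucleosome_spacing
    rows = []
    segs = gene_body_segments(gene)

    def region_of(pos: int) -> str:
        for region, (s, e) in segs.items():
            if s <= pos < e:
                return region
        return "mid"

    if gene["strand"] == "+":
        tss, tts = int(gene["start"]), int(gene["end"])
        direction = 1
    else:
        tss, tts = int(gene["end"]) - 1, int(gene["start"]) - 1
        direction = -1
    # upstream: -1 and -2 dyads
    for k, label in ((1, -1), (2, -2)):
        pos = tss - direction * (config.minus1_offset + (k - 1) * spacing)
        rows.append({"gene": gene["gene"], "label": label, "chrom": gene["chrom"],
                     "pos": int(pos), "region": "promoter"})
    # genic: +1 onward at fixed spacing, keeping 80 bp off the TTS
    pos = tss + direction * config.plus1_offset
    label = 1
    while direction * (tts - pos) > 80:
        rows.append({"gene": gene["gene"], "label": label, "chrom": gene["chrom"],
                     "pos": int(pos), "region": region_of(int(pos))})
        pos += direction * spacing
        label += 1
    return rows


def _plant_motifs(config: SimulationConfig, genes: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Choose planted motif positions: promoter motifs ~30 bp upstream of the
    TSS (intergenic), gene-body motifs at the middle of the gene body."""
    rows = []
    order = rng.permutation(len(genes))
    n_prom = min(config.n_promoter_motifs, len(genes))
    n_body = min(config.n_body_motifs, len(genes))
    width = default_pwm().shape[1]
    for i in order[:n_prom]:
        g = genes.iloc[i]
        pos = int(g["start"]) - 30 - width if g["strand"] == "+" else int(g["end"]) + 30
        rows.append({"chrom": g["chrom"], "start": pos, "end": pos + width,
                     "strand": "+" if i % 2 == 0 else "-", "category": "promoter",
                     "gene": g["gene"]})
    for i in order[:n_body]:
        g = genes.iloc[i]
        center = (int(g["start"]) + int(g["end"])) // 2
        pos = center - width // 2
        rows.append({"chrom": g["chrom"], "start": pos, "end": pos + width,
                     "strand": "+" if i % 2 == 0 else "-", "category": "gene_body",
                     "gene": g["gene"]})
    return pd.DataFrame(rows).reset_index(drop=True)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _write_motif_into(seq: np.ndarray, motif: pd.Series, pwm: np.ndarray) -> None:
    consensus = "".join("ACGT"[i] for i in pwm.argmax(axis=0))
    if motif["strand"] == "-":
        consensus = consensus.translate(_COMPLEMENT)[::-1]
    arr = np.frombuffer(consensus.encode(), dtype=np.uint8)
    seq[motif["start"] : motif["end"]] = arr


def make_genome(config: SimulationConfig) -> tuple[SyntheticGenome, GroundTruth]:
    """Build the synthetic genome, annotation and ground truth."""
    config.validate()
    rng = np.random.default_rng([config.seed % (2**31), zlib.crc32(b"genome")])
    genes = _place_genes(config, rng)
    genes["expression"] = rng.normal(config.expression_mu, config.expression_sigma, len(genes))
    genes["gene_class"] = "ordinary"
    genes["group"] = expression_bins(genes)

    nuc_rows: list[dict] = []
    for _, gene in genes.iterrows():
        nuc_rows.extend(_nucleosomes_for_gene(gene, config))

    chroms = [f"chr{i+1}" for i in range(len(config.chrom_lengths))]
    layout = dict(zip(chroms, config.chrom_lengths))
    last = chroms[-1]
    rdna = (last, layout[last] - 11_500, layout[last] - 8_500)
    # rDNA nucleosomes (excluded from library normalization, not from coverage)
    pos = rdna[1] + 100
    k = 1
    while pos < rdna[2] - 100:
        nuc_rows.append({"gene": "rDNA", "label": k, "chrom": last, "pos": pos, "region": "rDNA"})
        pos += config.nucleosome_spacing
        k += 1
    nucs = pd.DataFrame(nuc_rows)

    if config.spikein_sites is None:
        sites = [(last, layout[last] - 7_500), (last, layout[last] - 6_000),
                 (last, layout[last] - 4_500)]
    else:
        sites = [tuple(s) for s in config.spikein_sites]

    specials = [{"type": "rRNA37", "chrom": rdna[0], "start": rdna[1], "end": rdna[2]}]
    for chrom in chroms:
        specials.append({"type": "telomere", "chrom": chrom, "start": 0, "end": 300})
        specials.append({"type": "telomere", "chrom": chrom, "start": layout[chrom] - 300, "end": layout[chrom]})
        specials.append({"type": "centromere", "chrom": chrom, "start": layout[chrom] // 2 - 60,
                         "end": layout[chrom] // 2 + 60})

    pwm = default_pwm()
    motifs = _plant_motifs(config, genes, rng)

    sequences = {}
    for chrom in chroms:
        seq = rng.integers(0, 4, layout[chrom]).astype(np.uint8)
        seq = np.frombuffer(b"ACGT", dtype=np.uint8)[seq].copy()
        for _, m in motifs[motifs["chrom"] == chrom].iterrows():
            _write_motif_into(seq, m, pwm)
        sequences[chrom] = seq.tobytes().decode()

    # bound/unbound truth: alternate within each category, multiplier >= 2 when bound
    truth_rows = []
    for cat in ("promoter", "gene_body"):
        idx = motifs.index[motifs["category"] == cat]
        n_bound = int(round(config.bound_fraction * len(idx)))
        for j, i in enumerate(idx):
            bound = j < n_bound
            truth_rows.append({"motif": int(i), "bound": bound,
                               "multiplier": config.bound_multiplier if bound else 0.0})
    motif_truth = pd.DataFrame(truth_rows).set_index("motif").sort_index()

    genome = SyntheticGenome(
        layout=layout, genes=genes, nucleosomes=nucs, specials=pd.DataFrame(specials),
        sequences=sequences, pwm=pwm, motifs=motifs, rdna=rdna, spikein_sites=sites,
    )
    hw = config.spikein_halfwidth
    truth = GroundTruth(
        config=config, motif_truth=motif_truth, rdna=rdna,
        spikein_windows=[(c, p - hw, p + hw) for c, p in sites],
        spikein_fraction=config.spikein_fraction,
    )
    return genome, truth


# --------------------------------------------------------------------- ChIP

def _chip_expectations(genome: SyntheticGenome, sample: SampleMeta,
                       truth: GroundTruth) -> pd.DataFrame:
    """Expected retained (mononucleosome) fragment count per dyad."""
    cfg = truth.config
    group_of = dict(zip(genome.genes["gene"], genome.genes["group"]))
    nucs = genome.nucleosomes
    group = nucs["gene"].map(group_of).fillna(-1).astype(int)
    expect = np.full(len(nucs), float(cfg.chip_depth))
    if sample.epitope == "myc":
        expect *= nucs["region"].map(lambda r: cfg.myc_baseline.get(r, 0.2)).to_numpy()
    pairs = pd.DataFrame({"region": nucs["region"].to_numpy(), "group": group.to_numpy()})
    factors = {
        key: truth.chip_factor(sample, key[0], key[1], sample.timepoint)
        for key in set(map(tuple, pairs.itertuples(index=False)))
    }
    expect *= np.array([factors[(r, g)] for r, g in pairs.itertuples(index=False)])
    out = nucs[["chrom", "pos"]].copy()
    out["expect"] = expect
    return out


def expected_chip_coverage(genome: SyntheticGenome, sample: SampleMeta,
                           truth: GroundTruth) -> CoverageTrack:
    """Exact expected post-filter midpoint coverage (real-valued)."""
    track = CoverageTrack.zeros(genome.layout)
    exp = _chip_expectations(genome, sample, truth)
    for chrom, sub in exp.groupby("chrom", sort=False):
        np.add.at(track.data[chrom], sub["pos"].to_numpy(), sub["expect"].to_numpy())
    track.sample_id = sample.sample_id
    return track


def simulate_chip_fragments(genome: SyntheticGenome, sample: SampleMeta,
                            truth: GroundTruth, seed: int | None = None) -> pd.DataFrame:
    """Sample ChIP fragment intervals (BED-like DataFrame).

    Mononucleosome fragments (length ~ N(151, 10) truncated to [80, 250],
    fixed 150 when noise is off) are centered on dyads with Poisson (or
    rounded) counts; a dinucleosome population (length ~ N(300, 30),
    fixed 300 noise-free) rides along and is removed by the 100-200 bp
    size filter downstream.
    """
    if sample.assay != "ChIP":
        raise ValueError("simulate_chip_fragments requires a ChIP sample")
    cfg = truth.config
    if sample.timepoint not in cfg.chip_timepoints:
        raise KeyError(f"timepoint {sample.timepoint} not in the ChIP grid")
    rng = sample_rng(cfg.seed if seed is None else seed, sample.sample_id)
    exp = _chip_expectations(genome, sample, truth)
    di_ratio = cfg.dinucleosome_fraction / (1.0 - cfg.dinucleosome_fraction)
    if cfg.noise:
        mono = rng.poisson(exp["expect"].to_numpy())
        di = rng.poisson(exp["expect"].to_numpy() * di_ratio)
    else:
        mono = np.rint(exp["expect"].to_numpy()).astype(int)
        di = np.rint(exp["expect"].to_numpy() * di_ratio).astype(int)
    frames = []
    for counts, mean_len, sd_len, lo, hi, fixed in (
        (mono, 151, 10, 80, 250, 150),
        (di, 300, 30, 250, 400, 300),
    ):
        mids = np.repeat(exp["pos"].to_numpy(), counts)
        chrom = np.repeat(exp["chrom"].to_numpy(), counts)
        n = len(mids)
        if cfg.noise:
            lengths = np.clip(np.rint(rng.normal(mean_len, sd_len, n)), lo, hi).astype(int)
        else:
            lengths = np.full(n, fixed)
        starts = mids - lengths // 2
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + lengths}))
    frags = pd.concat(frames, ignore_index=True)
    frags = frags.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    frags["name"] = sample.sample_id
    return frags


# --------------------------------------------------------------------- ChEC

def default_chec_model(kind: str = "regulator") -> ChecTargetModel:
    """A generic binding model: promoter-anchored plus gene-body footprints
    for chromatin regulators, motif-anchored footprints for TFs."""
    if kind == "tf":
        return ChecTargetModel(
            components=[ChecComponent(kind="motif", weight=1.0, sd=15.0)],
            background=0.05,
        )
    return ChecTargetModel(
        components=[
            ChecComponent(kind="tss", weight=6.0, sd=40.0, offset=-100),
            ChecComponent(kind="body", weight=3.0, sd=80.0, frac=0.25),
        ],
        background=0.05,
    )


def _add_bump(arr: np.ndarray, center: int, sd: float, weight: float) -> None:
    half = int(4 * sd) + 1
    lo, hi = max(0, center - half), min(len(arr), center + half + 1)
    if hi <= lo:
        return
    x = np.arange(lo, hi)
    kern = np.exp(-0.5 * ((x - center) / sd) ** 2)
    arr[lo:hi] += weight * kern / kern.sum()


def _zone_of_position(gene: pd.Series, pos: int) -> str:
    segs = gene_body_segments(gene)
    for region, (s, e) in segs.items():
        if s <= pos < e:
            return region
    return "promoter"


def chec_intensity(genome: SyntheticGenome, sample: SampleMeta, truth: GroundTruth,
                   spikein: bool = False, depth_scale: float = 1.0) -> CoverageTrack:
    """Expected ChEC fragment-midpoint intensity per bp (absolute scale).

    The footprint model of sample.epitope (the ChEC target) is laid down
    per gene/motif, scaled so the no-effect (t=0) library totals
    chec_depth fragments; depletion effects then multiply affected
    components by 2^(a*t/60). Because intensities are absolute, a true
    binding gain increases total mass while the spike-in mass stays
    constant per cell equivalent, which is what makes the spike-in
    quantification meaningful.
    """
    cfg = truth.config
    target = sample.epitope
    model = cfg.chec_models.get(target, default_chec_model("tf" if target.lower().startswith(("msn", "reb", "tf")) else "regulator"))
    group_of = dict(zip(genome.genes["gene"], genome.genes["group"]))

    def build(t: int, with_effects: bool) -> dict[str, np.ndarray]:
        arrs = {c: np.full(n, model.background, dtype=float) for c, n in genome.layout.items()}
        for comp in model.components:
            if comp.times is not None and t not in comp.times:
                continue
            if comp.kind == "motif":
                for i, m in genome.motifs.iterrows():
                    mult = float(truth.motif_truth.loc[i, "multiplier"]) if i in truth.motif_truth.index else 0.0
                    if mult == 0.0:
                        continue
                    zone_key = f"{m['category']}_motifs"
                    f = truth.chec_factor(sample.regulator, target, zone_key,
                                          group_of.get(m["gene"]), t) if with_effects else 1.0
                    center = (int(m["start"]) + int(m["end"])) // 2
                    _add_bump(arrs[m["chrom"]], center, comp.sd, comp.weight * mult * f)
            else:
                for _, g in genome.genes.iterrows():
                    if comp.kind == "tss":
                        tss = int(g["start"]) if g["strand"] == "+" else int(g["end"]) - 1
                        sign = 1 if g["strand"] == "+" else -1
                        center = tss + sign * comp.offset
                        zone = "promoter"
                    else:
                        length = int(g["end"] - g["start"])
                        if g["strand"] == "+":
                            center = int(g["start"]) + int(comp.frac * length)
                        else:
                            center = int(g["end"]) - 1 - int(comp.frac * length)
                        zone = _zone_of_position(g, center)
                    f = truth.chec_factor(sample.regulator, target, zone,
                                          group_of.get(g["gene"]), t) if with_effects else 1.0
                    _add_bump(arrs[g["chrom"]], center, comp.sd, comp.weight * f)
        return arrs

    reference = build(0, with_effects=False)
    z0 = sum(a.sum() for a in reference.values())
    norm = cfg.chec_depth / z0
    arrs = build(sample.timepoint, with_effects=True)
    main_fraction = 1.0 - cfg.spikein_fraction if spikein else 1.0
    arrs = {c: a * norm * main_fraction * depth_scale for c, a in arrs.items()}
    if spikein:
        mass = cfg.spikein_fraction * cfg.chec_depth * depth_scale / 3.0
        for chrom, p in genome.spikein_sites:
            _add_bump(arrs[chrom], p, 15.0, mass)
    track = CoverageTrack(arrs)
    track.sample_id = sample.sample_id
    return track


def expected_chec_coverage(genome: SyntheticGenome, sample: SampleMeta, truth: GroundTruth,
                           spikein: bool = False, depth_scale: float = 1.0) -> CoverageTrack:
    """Exact expected midpoint coverage of a ChEC library."""
    return chec_intensity(genome, sample, truth, spikein=spikein, depth_scale=depth_scale)


def simulate_chec_fragments(genome: SyntheticGenome, sample: SampleMeta, truth: GroundTruth,
                            spikein: bool = False, seed: int | None = None,
                            depth_scale: float = 1.0) -> pd.DataFrame:
    """Sample ChEC fragment intervals from the target's intensity model.

    Fragment midpoints follow the intensity; lengths ~ N(60, 20)
    truncated to >= 20 (fixed 60 noise-free). The total count is Poisson
    around the intensity mass (rounded when noise is off).
    """
    if sample.assay != "ChEC":
        raise ValueError("simulate_chec_fragments requires a ChEC sample")
    cfg = truth.config
    rng = sample_rng(cfg.seed if seed is None else seed, sample.sample_id)
    lam = chec_intensity(genome, sample, truth, spikein=spikein, depth_scale=depth_scale)
    chroms = list(lam.data)
    concat = np.concatenate([lam.data[c] for c in chroms])
    total = concat.sum()
    n = int(rng.poisson(total)) if cfg.noise else int(round(total))
    cdf = np.cumsum(concat)
    picks = np.searchsorted(cdf, rng.random(n) * cdf[-1], side="right")
    # map flat positions back to chromosomes
    offsets = np.cumsum([0] + [len(lam.data[c]) for c in chroms])
    chrom_idx = np.searchsorted(offsets, picks, side="right") - 1
    pos = picks - offsets[chrom_idx]
    if cfg.noise:
        lengths = np.maximum(np.rint(rng.normal(60, 20, n)), 20).astype(int)
    else:
        lengths = np.full(n, 60)
    starts = pos - lengths // 2
    frags = pd.DataFrame({
        "chrom": np.array(chroms, dtype=object)[chrom_idx],
        "start": starts, "end": starts + lengths,
    })
    # keep midpoints on-chromosome; shift edge fragments inward
    for c in chroms:
        m = frags["chrom"] == c
        frags.loc[m, "start"] = frags.loc[m, "start"].clip(0)
        frags.loc[m, "end"] = frags.loc[m, "end"].clip(upper=genome.layout[c])
    frags = frags[frags["end"] > frags["start"]]
    frags = frags.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    frags["name"] = sample.sample_id
    return frags


# ------------------------------------------------------------------ samples

def build_chip_samples(regulators: Sequence[str], timepoints: Sequence[int] = CHIP_TIMEPOINTS,
                       repeats: int = 3, epitopes: Sequence[str] = ("myc", "HA")) -> list[SampleMeta]:
    return [
        SampleMeta(regulator=r, epitope=e, timepoint=t, repeat=rep, assay="ChIP")
        for r in regulators for e in epitopes for t in timepoints
        for rep in range(1, repeats + 1)
    ]


def build_chec_samples(pairs: Sequence[tuple[str, str]], timepoints: Sequence[int] = CHEC_TIMEPOINTS,
                       repeats: int = 2) -> list[SampleMeta]:
    """pairs: (depleted regulator, ChEC target) combinations."""
    return [
        SampleMeta(regulator=r, epitope=target, timepoint=t, repeat=rep, assay="ChEC")
        for r, target in pairs for t in timepoints for rep in range(1, repeats + 1)
    ]
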