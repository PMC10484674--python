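"""End-to-end orchestration: sample sheet -> coverage -> features ->
dynamics -> metagene -> binding, with reproducibility plumbing.

A run is fully determined by its RunConfig (including the seed): tables
are emitted as TSV with the config hash recorded, and re-running with
the same config reproduces them byte-identically. When the inputs are
simulated, a recovery report compares every estimated stratum change
with the generator's planted truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import binding as binding_mod
from . import dynamics as dynamics_mod
from . import features as features_mod
from . import metagene as metagene_mod
from .coverage import (CHIP_SIZE_RANGE, NORMALIZATION_TARGET, CoverageTrack,
                       SampleMeta, average_repeats, fragments_to_coverage,
                       normalize_library)
from .synthgen import (GroundTruth, SimulationConfig, SyntheticGenome,
                       build_chec_samples, build_chip_samples,
                       simulate_chec_fragments, simulate_chip_fragments)

logger = logging.getLogger(__name__)

FEATURE_TYPES_FOR_SCREEN = ("promoter", "NDR", "5p", "mid", "3p")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    outdir: str = "results/run"
    seed: int = 0
    regulators: tuple[str, ...] = ("Spt6", "none")
    chip_repeats: int = 3
    chec_pairs: tuple[tuple[str, str], ...] = ()
    chec_repeats: int = 2
    size_min: int = CHIP_SIZE_RANGE[0]
    size_max: int = CHIP_SIZE_RANGE[1]
    normalization_target: float = NORMALIZATION_TARGET
    chip_horizon: int = 90
    chec_horizon: int = 60
    pseudocount: float = 1.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of every analysis-relevant parameter (not the output path)."""
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    config_hash: str
    tables: dict[str, pd.DataFrame]
    genome: SyntheticGenome | None = None
    truth: GroundTruth | None = None

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            out = df.copy()
            out.insert(0, "config_hash", self.config_hash)
            out.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        return outdir


def _normalized_tracks(
    samples: Sequence[SampleMeta],
    fragments: Mapping[str, pd.DataFrame],
    layout: Mapping[str, int],
    rdna: tuple[str, int, int],
    config: RunConfig,
) -> dict[str, CoverageTrack]:
    tracks = {}
    for s in samples:
        frags = fragments[s.sample_id]
        bounds = (config.size_min, config.size_max) if s.assay == "ChIP" else (None, None)
        raw = fragments_to_coverage(frags, layout, *bounds)
        tracks[s.sample_id] = normalize_library(raw, [rdna], config.normalization_target)
        tracks[s.sample_id].sample_id = s.sample_id
        logger.info("coverage %s: %d fragments read, %.0f retained", s.sample_id,
                    len(frags), raw.total())
    return tracks


def _track_grid(samples: Sequence[SampleMeta], tracks: Mapping[str, CoverageTrack],
                regulator: str, epitope: str, assay: str) -> dict[tuple[int, int], CoverageTrack]:
    return {
        (s.timepoint, s.repeat): tracks[s.sample_id]
        for s in samples
        if s.regulator == regulator and s.epitope == epitope and s.assay == assay
    }


def simulate_screen(config: RunConfig) -> tuple[SyntheticGenome, GroundTruth,
                                                list[SampleMeta], dict[str, pd.DataFrame]]:
    """Generate the synthetic screen defined by the config."""
    from .synthgen import make_genome

    genome, truth = make_genome(config.simulation)
    samples = build_chip_samples(config.regulators, config.simulation.chip_timepoints,
                                 config.chip_repeats)
    samples += build_chec_samples(config.chec_pairs, config.simulation.chec_timepoints,
                                  config.chec_repeats)
    fragments = {}
    for s in samples:
        if s.assay == "ChIP":
            fragments[s.sample_id] = simulate_chip_fragments(genome, s, truth)
        else:
            fragments[s.sample_id] = simulate_chec_fragments(genome, s, truth)
    return genome, truth, samples, fragments


def run_screen(
    config: RunConfig,
    genome: SyntheticGenome | None = None,
    truth: GroundTruth | None = None,
    samples: Sequence[SampleMeta] | None = None,
    fragments: Mapping[str, pd.DataFrame] | None = None,
    write: bool = True,
) -> ResultBundle:
    """Run the full screen analysis; simulates inputs when none are given.

    Stages: coverage (size filter + library normalization), feature
    assignment + expression groups, per-feature-type and per-stratum
    change estimation for every ChIP series, metagene relative-change
    profiles, and ChEC change/enrichment tables when ChEC samples exist.
    """
    if samples is None:
        genome, truth, samples, fragments = simulate_screen(config)
    if not samples:
        raise StageError("validation: empty sample sheet")
    assert genome is not None and fragments is not None

    tables: dict[str, pd.DataFrame] = {}
    try:
        tracks = _normalized_tracks(samples, fragments, genome.layout, genome.rdna, config)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"coverage: {exc}") from exc

    try:
        feats = features_mod.assign_features(genome.genes, genome.nucleosomes,
                                             genome.specials, genome.layout)
        feats = features_mod.add_expression_groups(feats, genome.genes)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"features: {exc}") from exc

    chip_series = sorted({(s.regulator, s.epitope) for s in samples if s.assay == "ChIP"})
    type_rows, strat_rows = [], []
    for regulator, epitope in chip_series:
        grid = _track_grid(samples, tracks, regulator, epitope, "ChIP")
        for ftype in FEATURE_TYPES_FOR_SCREEN:
            est = dynamics_mod.feature_relative_change(
                grid, feats, ftype, config.chip_horizon, config.pseudocount)
            type_rows.append({"regulator": regulator, "epitope": epitope,
                              "feature_type": ftype, **est.as_dict()})
        strata = dynamics_mod.region_expression_change(
            grid, feats, horizon=config.chip_horizon, pseudocount=config.pseudocount)
        strata.insert(0, "epitope", epitope)
        strata.insert(0, "regulator", regulator)
        strat_rows.append(strata)
    tables["feature_type_changes"] = pd.DataFrame(type_rows)
    tables["stratum_changes"] = pd.concat(strat_rows, ignore_index=True) if strat_rows else pd.DataFrame()

    # scaled metagene relative change at the last timepoint, per series
    try:
        frame = metagene_mod.build_frame(genome.genes, genome.layout)
        meta_rows = []
        for regulator, epitope in chip_series:
            grid = _track_grid(samples, tracks, regulator, epitope, "ChIP")
            times = sorted({t for t, _ in grid})
            profiles = {
                t: [metagene_mod.metagene_profile(trk, frame)
                    for (tt, _), trk in sorted(grid.items()) if tt == t]
                for t in times
            }
            change = metagene_mod.metagene_relative_change(profiles, config.pseudocount)
            for t, vec in change.items():
                meta_rows.append(pd.DataFrame({
                    "regulator": regulator, "epitope": epitope, "timepoint": t,
                    "position": np.arange(len(vec)), "log2_change": vec,
                }))
        tables["metagene_change"] = pd.concat(meta_rows, ignore_index=True)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"metagene: {exc}") from exc

    chec_series = sorted({(s.regulator, s.epitope) for s in samples if s.assay == "ChEC"})
    if chec_series:
        chec_rows = []
        for regulator, target in chec_series:
            grid = _track_grid(samples, tracks, regulator, target, "ChEC")
            for region in ("5p", "mid", "3p"):
                for group in (1, 2, 3, 4, 5):
                    stratum = feats[(feats["type"] == region) & (feats["group"] == group)]
                    if stratum.empty:
                        continue
                    est = dynamics_mod.chec_relative_change(
                        grid, stratum, config.chec_horizon, config.pseudocount)
                    chec_rows.append({"regulator": regulator, "target": target,
                                      "region": region, "group": group, **est.as_dict()})
        tables["chec_changes"] = pd.DataFrame(chec_rows)
        # steady-state enrichment of each target over feature types
        occ_rows = {}
        for regulator, target in chec_series:
            grid = _track_grid(samples, tracks, regulator, target, "ChEC")
            t0 = average_repeats([trk for (t, _), trk in sorted(grid.items()) if t == 0])
            occ_rows[target] = {
                ftype: features_mod.feature_mean_coverage(
                    t0, feats[feats["type"] == ftype]).mean()
                for ftype in sorted(feats["type"].unique())
            }
        occ = pd.DataFrame(occ_rows).T
        if len(occ) >= 2:
            tables["chec_enrichment"] = binding_mod.regulator_enrichment(occ).reset_index(names="target")

    # summary: strongest positive stratum per series
    summary = []
    strat = tables["stratum_changes"]
    for (regulator, epitope), sub in strat.groupby(["regulator", "epitope"]):
        best = sub.loc[sub["change"].idxmax()]
        summary.append({"regulator": regulator, "epitope": epitope,
                        "top_region": best["region"], "top_group": best["group"],
                        "top_change": best["change"]})
    tables["summary"] = pd.DataFrame(summary)

    bundle = ResultBundle(config.config_hash(), tables, genome=genome, truth=truth)
    if write:
        bundle.write(config.outdir)
    return bundle


#: planted truth of the standard stratum-recovery experiment:
#: log2-per-90-min changes in chosen (region, expression-group) strata
RECOVERY_EFFECTS = (
    ("5p", 5, 1.0),
    ("mid", 4, 0.5),
    ("3p", 5, -1.0),
    ("5p", 2, 0.0),  # explicit null alongside the implicit ones
)


def stratum_recovery_experiment(
    master_seed: int,
    n_seeds: int = 20,
    repeats: int = 3,
    effects: Sequence[tuple[str, int, float]] = RECOVERY_EFFECTS,
) -> pd.DataFrame:
    """Repeated-simulation recovery of planted stratum changes.

    Per seed: simulate a full myc ChIP depletion series (5 timepoints x
    `repeats` repeats, Poisson noise, the default ~200 expected fragments
    per nucleosome) with the planted effects, run the fragment ->
    coverage -> normalization -> stratified slope-estimation chain, and
    record every stratum's estimate next to its truth. Returns a tidy
    table (seed, region, group, estimated, true).
    """
    from .synthgen import DepletionEffect, make_genome

    planted = tuple(
        DepletionEffect("Spt6", region, (group,), a)
        for region, group, a in effects if a != 0.0
    )
    truth_map = {(region, group): a for region, group, a in effects}
    rows = []
    for k in range(n_seeds):
        sim = SimulationConfig(seed=(master_seed + 7919 * k) % (2**31),
                               depletion_effects=planted)
        genome, truth = make_genome(sim)
        feats = features_mod.add_expression_groups(
            features_mod.assign_features(genome.genes, genome.nucleosomes,
                                         genome.specials, genome.layout),
            genome.genes)
        grid = {}
        for t in sim.chip_timepoints:
            for rep in range(1, repeats + 1):
                s = SampleMeta("Spt6", "myc", t, rep, "ChIP")
                frags = simulate_chip_fragments(genome, s, truth)
                cov = fragments_to_coverage(frags, genome.layout,
                                            CHIP_SIZE_RANGE[0], CHIP_SIZE_RANGE[1])
                grid[(t, rep)] = normalize_library(cov, [genome.rdna])
        tab = dynamics_mod.region_expression_change(grid, feats)
        for _, r in tab.dropna(subset=["change"]).iterrows():
            rows.append({
                "seed": sim.seed, "region": r["region"], "group": int(r["group"]),
                "estimated": r["change"],
                "true": truth_map.get((r["region"], int(r["group"])), 0.0),
            })
    return pd.DataFrame(rows)


def recovery_report(bundle: ResultBundle, truth: GroundTruth,
                    tolerance: float = 0.1) -> pd.DataFrame:
    """Estimated vs planted change per stratum, with absolute errors.

    Returns a table (regulator, epitope, region, group, estimated, true,
    abs_error, within_tolerance). Raises if the bundle was not produced
    from simulated inputs matching this truth.
    """
    strat = bundle.tables.get("stratum_changes")
    if strat is None or strat.empty:
        raise ValueError("bundle has no stratum changes; was it produced by run_screen?")
    rows = []
    for _, r in strat.iterrows():
        true_a = truth.true_change(r["regulator"], r["epitope"], r["region"], int(r["group"]))
        rows.append({
            "regulator": r["regulator"], "epitope": r["epitope"],
            "region": r["region"], "group": int(r["group"]),
            "estimated": r["change"], "true": true_a,
            "abs_error": abs(r["change"] - true_a),
        })
    report = pd.DataFrame(rows)
    report["within_tolerance"] = report["abs_error"] < tolerance
    return report
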