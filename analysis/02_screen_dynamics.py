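#!/usr/bin/env python
"""Run the screen analysis end to end and quantify histone dynamics.

Recreates the simulated screen from its config (deterministic), builds
normalized coverage, estimates the relative myc/HA change per feature
type and per (gene region x expression group) stratum, and verifies the
planted Spt6-like effect is recovered. Tables land in results/screen/.
"""

from pathlib import Path

from nucdyn.dynamics import classify_dynamics
from nucdyn.pipeline import RunConfig, recovery_report, run_screen
from nucdyn.synthgen import DepletionEffect, SimulationConfig

SEED = 1
OUT = Path("results/screen")


def main() -> None:
    cfg = RunConfig(
        outdir=str(OUT), seed=SEED,
        regulators=("Spt6", "none"), chip_repeats=3,
        chec_pairs=(("Spt6", "Spt6"), ("Spt6", "Msn2")),
        simulation=SimulationConfig(
            depletion_effects=(DepletionEffect("Spt6", "5p", (5,), 1.0),)),
    )
    bundle = run_screen(cfg)
    print(f"wrote {len(bundle.tables)} tables to {OUT} (config {bundle.config_hash})")

    summary = bundle.tables["summary"]
    print("\nstrongest positive stratum per series:")
    print(summary.to_string(index=False))

    strat = bundle.tables["stratum_changes"]
    spt6 = strat[(strat["regulator"] == "Spt6") & (strat["epitope"] == "myc")]
    hit = spt6[(spt6["region"] == "5p") & (spt6["group"] == 5)].iloc[0]
    call = classify_dynamics(hit["change"],
                             strat[(strat["regulator"] == "Spt6") & (strat["epitope"] == "HA")
                                   & (strat["region"] == "5p") & (strat["group"] == 5)]["change"].iloc[0])
    print(f"\n5' x top-expression stratum: myc change {hit['change']:+.3f} log2/90min "
          f"(r = {hit['correlation']:.2f}) -> classified as {call.call}")

    rep = recovery_report(bundle, bundle.truth)
    rep.to_csv(OUT / "recovery_report.tsv", sep="\t", index=False)
    print(f"recovery vs planted truth: max abs error {rep['abs_error'].max():.3f} log2 "
          f"across {len(rep)} strata")


if __name__ == "__main__":
    main()
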