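import numpy as np
import pandas as pd
import pytest

from nucdyn.coverage import CoverageTrack, SampleMeta
from nucdyn.synthgen import DepletionEffect, SimulationConfig, make_genome

LAYOUT = {"chrA": 5000, "chrB": 3000}


@pytest.fixture
def layout():
    return dict(LAYOUT)


@pytest.fixture
def toy_genes():
    """Two plus-strand and one minus-strand gene on a toy layout."""
    return pd.DataFrame([
        {"gene": "gA", "chrom": "chrA", "start": 1000, "end": 2000, "strand": "+", "expression": 5.0},
        {"gene": "gB", "chrom": "chrA", "start": 2800, "end": 4100, "strand": "-", "expression": 3.0},
        {"gene": "gC", "chrom": "chrB", "start": 900, "end": 1600, "strand": "+", "expression": 7.0},
    ])


@pytest.fixture
def toy_nucleosomes(toy_genes):
    rows = []
    for _, g in toy_genes.iterrows():
        if g["strand"] == "+":
            tss = g["start"]
            rows += [
                {"gene": g["gene"], "label": -2, "chrom": g["chrom"], "pos": tss - 285},
                {"gene": g["gene"], "label": -1, "chrom": g["chrom"], "pos": tss - 120},
                {"gene": g["gene"], "label": 1, "chrom": g["chrom"], "pos": tss + 80},
                {"gene": g["gene"], "label": 2, "chrom": g["chrom"], "pos": tss + 245},
            ]
        else:
            tss = g["end"] - 1
            rows += [
                {"gene": g["gene"], "label": -2, "chrom": g["chrom"], "pos": tss + 285},
                {"gene": g["gene"], "label": -1, "chrom": g["chrom"], "pos": tss + 120},
                {"gene": g["gene"], "label": 1, "chrom": g["chrom"], "pos": tss - 80},
                {"gene": g["gene"], "label": 2, "chrom": g["chrom"], "pos": tss - 245},
            ]
    return pd.DataFrame(rows)


def constant_track(layout, value=1.0):
    return CoverageTrack({c: np.full(n, float(value)) for c, n in layout.items()})


@pytest.fixture
def small_config():
    """A small but complete synthetic screen configuration."""
    return SimulationConfig(
        seed=11,
        depletion_effects=(DepletionEffect("Spt6", "5p", (5,), 1.0),),
    )


@pytest.fixture(scope="session")
def default_genome():
    """One default genome + truth shared across read-only tests."""
    cfg = SimulationConfig(seed=42)
    return make_genome(cfg)


def chip_sample(regulator="Spt6", epitope="myc", t=0, rep=1):
    return SampleMeta(regulator=regulator, epitope=epitope, timepoint=t, repeat=rep, assay="ChIP")


def chec_sample(regulator="none", target="Msn2", t=0, rep=1):
    return SampleMeta(regulator=regulator, epitope=target, timepoint=t, repeat=rep, assay="ChEC")
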