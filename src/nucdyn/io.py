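"""Plain-text file formats: BED6 fragments, TSV annotation tables,
bedGraph coverage, FASTA sequence and the 4-row PWM matrix.

All interval files are 0-based half-open (BED native; convert GFF-style
1-based inputs before calling these). write_fixtures/read_fixtures give
a lossless round trip for a complete synthetic dataset.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import CoverageTrack, SampleMeta
from .synthgen import GroundTruth, SyntheticGenome

FRAGMENT_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_fragments_bed(fragments: pd.DataFrame, path: str | Path) -> None:
    """Fragments as header-free BED6 (name = sample id, score 0, strand '.')."""
    df = fragments.copy()
    if "name" not in df:
        df["name"] = "."
    df["score"] = 0
    df["strand"] = "."
    df[FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=FRAGMENT_COLUMNS,
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    return df[["chrom", "start", "end", "name"]]


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Coverage as bedGraph, merging runs of equal value, zeros omitted."""
    with open(path, "w") as fh:
        for chrom, arr in track.data.items():
            change = np.nonzero(np.diff(arr))[0] + 1
            bounds = np.concatenate([[0], change, [len(arr)]])
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path: str | Path, layout: Mapping[str, int]) -> CoverageTrack:
    track = CoverageTrack.zeros(layout)
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    for _, r in df.iterrows():
        track.data[r["chrom"]][int(r["start"]) : int(r["end"])] = r["value"]
    return track


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pwm(pwm: np.ndarray, path: str | Path) -> None:
    """4-row (A, C, G, T) probability matrix, tab-separated."""
    np.savetxt(path, np.asarray(pwm), delimiter="\t", fmt="%.6f")


def read_pwm(path: str | Path) -> np.ndarray:
    pwm = np.loadtxt(path, delimiter="\t")
    if pwm.ndim == 1:
        pwm = pwm.reshape(4, -1)
    if pwm.shape[0] != 4:
        raise ValueError("PWM file must have 4 rows (A, C, G, T)")
    return pwm


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=c, description="") for c, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_sample_sheet(samples: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(s) for s in samples])
    write_tsv(df, path)


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    df = read_tsv(path)
    return [
        SampleMeta(regulator=str(r["regulator"]), epitope=str(r["epitope"]),
                   timepoint=int(r["timepoint"]), repeat=int(r["repeat"]),
                   assay=str(r["assay"]))
        for _, r in df.iterrows()
    ]


def write_fixtures(
    genome: SyntheticGenome,
    truth: GroundTruth,
    samples: Sequence[SampleMeta],
    fragments: Mapping[str, pd.DataFrame],
    outdir: str | Path,
) -> Path:
    """Write a complete synthetic dataset as plain-text files.

    Layout: genes.tsv, nucleosomes.tsv, expression.tsv, specials.bed,
    sample_sheet.tsv, ground_truth.tsv (ChIP effects), motif_truth.tsv,
    motifs.tsv, spikein.tsv, pwm.txt, genome.fa, layout.tsv and one
    fragments/<sample_id>.bed per sample.
    """
    outdir = Path(outdir)
    (outdir / "fragments").mkdir(parents=True, exist_ok=True)
    write_tsv(genome.genes, outdir / "genes.tsv")
    write_tsv(genome.nucleosomes, outdir / "nucleosomes.tsv")
    write_tsv(genome.genes[["gene", "expression"]], outdir / "expression.tsv")
    genome.specials.assign(name=genome.specials["type"])[
        ["chrom", "start", "end", "name"]
    ].to_csv(outdir / "specials.bed", sep="\t", header=False, index=False)
    write_tsv(genome.motifs, outdir / "motifs.tsv")
    write_sample_sheet(samples, outdir / "sample_sheet.tsv")
    effects = pd.DataFrame([
        {"regulator": e.regulator, "epitope": e.epitope, "region": e.region_type,
         "groups": ",".join(map(str, e.groups)), "a": e.a}
        for e in truth.config.depletion_effects
    ], columns=["regulator", "epitope", "region", "groups", "a"])
    write_tsv(effects, outdir / "ground_truth.tsv")
    write_tsv(truth.motif_truth.reset_index(), outdir / "motif_truth.tsv")
    spike = pd.DataFrame(truth.spikein_windows, columns=["chrom", "start", "end"])
    spike["fraction"] = truth.spikein_fraction
    write_tsv(spike, outdir / "spikein.tsv")
    write_pwm(genome.pwm, outdir / "pwm.txt")
    write_fasta(genome.sequences, outdir / "genome.fa")
    write_tsv(pd.DataFrame({"chrom": list(genome.layout), "length": list(genome.layout.values())}),
              outdir / "layout.tsv")
    for sid, frags in fragments.items():
        write_fragments_bed(frags, outdir / "fragments" / f"{sid}.bed")
    return outdir


def read_fixtures(indir: str | Path) -> dict:
    """Read a fixture directory back into in-memory objects."""
    indir = Path(indir)
    layout_df = read_tsv(indir / "layout.tsv")
    layout = dict(zip(layout_df["chrom"].astype(str), layout_df["length"].astype(int)))
    out = {
        "layout": layout,
        "genes": read_tsv(indir / "genes.tsv"),
        "nucleosomes": read_tsv(indir / "nucleosomes.tsv"),
        "expression": read_tsv(indir / "expression.tsv"),
        "motifs": read_tsv(indir / "motifs.tsv"),
        "motif_truth": read_tsv(indir / "motif_truth.tsv").set_index("motif"),
        "ground_truth": read_tsv(indir / "ground_truth.tsv"),
        "spikein": read_tsv(indir / "spikein.tsv"),
        "pwm": read_pwm(indir / "pwm.txt"),
        "sequences": read_fasta(indir / "genome.fa"),
        "samples": read_sample_sheet(indir / "sample_sheet.tsv"),
        "specials": pd.read_csv(indir / "specials.bed", sep="\t", header=None,
                                names=["chrom", "start", "end", "type"], dtype={"chrom": str}),
    }
    frag_dir = indir / "fragments"
    out["fragments"] = {
        p.stem: read_fragments_bed(p) for p in sorted(frag_dir.glob("*.bed"))
    }
    return out
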