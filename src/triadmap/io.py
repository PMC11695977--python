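"""Readers and writers for the plain-text formats the pipeline exchanges:
FASTA genomes, FASTQ read pairs, gene-annotation TSVs, bedGraph crosslink
tracks, peak/count TSVs, loop and DEG tables, and the ground-truth JSON.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import GroundTruthManifest, SyntheticDataset


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    """Per-nt track (chrom, pos, count-or-score) as bedGraph lines."""
    value_col = [c for c in track.columns if c not in ("chrom", "pos")][0]
    out = pd.DataFrame(
        {
            "chrom": track.chrom,
            "start": track.pos,
            "end": track.pos + 1,
            "value": track[value_col],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path, value_name: str = "count") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", value_name])
    return pd.DataFrame({"chrom": df.chrom, "pos": df.start, value_name: df[value_name]})


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write every artifact of a simulated dataset under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.genome, out / "genome.fa")
    ds.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    ds.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    write_fastq(ds.reads1, out / "reads_1.fastq")
    write_fastq(ds.reads2, out / "reads_2.fastq")
    ds.read_meta.to_csv(out / "read_meta.tsv", sep="\t", index=False)
    for i, rep in enumerate(ds.iclip_replicates, start=1):
        write_bedgraph(rep, out / f"iclip_rep{i}.bedgraph")
    write_bedgraph(ds.iclip_scores, out / "iclip_scores.bedgraph")
    ds.peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)
    ds.brg1_counts.to_csv(out / "brg1_counts.tsv", sep="\t", index=False)
    ds.atac.to_csv(out / "atac.tsv", sep="\t", index=False)
    ds.loops.to_csv(out / "loops.tsv", sep="\t", index=False)
    ds.activities.to_csv(out / "activities.tsv", sep="\t", index=False)
    for cond, table in ds.deg_tables.items():
        table.to_csv(out / f"deg_{cond}.tsv", sep="\t", index=False)
    for cell, seg in ds.segmentations.items():
        seg.to_csv(out / f"segmentation_{cell}.bed", sep="\t", header=False, index=False)
    (out / "truth.json").write_text(ds.truth.to_json())


def read_truth(path: str | Path) -> GroundTruthManifest:
    return GroundTruthManifest.from_json(Path(path).read_text())


def write_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=1, default=float))
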