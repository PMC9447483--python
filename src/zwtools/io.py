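"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA via Biopython; depth tables, BED6 and RepeatMasker .out as pandas
frames.  All interval tables are 0-based half-open internally (RepeatMasker
.out coordinates, 1-based closed, are converted on read).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_depth_tsv",
    "write_depth_tsv",
    "read_bed6",
    "write_bed6",
    "read_repeatmasker_out",
    "read_gametolog_fasta",
]

DEPTH_COLUMNS = ["chrom", "start", "end", "sample", "depth"]
BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_depth_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DEPTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"depth table missing columns: {sorted(missing)}")
    return df


def write_depth_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    """BED6 with the repeat family carried in the name field."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED6_COLUMNS)]
    df.columns = BED6_COLUMNS[: df.shape[1]]
    if "name" in df.columns:
        df = df.rename(columns={"name": "family"})
    return df


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df.get("family", "."),
            "score": df.get("score", 0),
            "strand": df.get("strand", "+"),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_repeatmasker_out(path: str | Path) -> pd.DataFrame:
    """Parse a RepeatMasker .out table to (chrom, start, end, family, divergence).

    Coordinates are converted to 0-based half-open; the repeat family is the
    class/family column; divergence is the percent-divergence column.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 11 or not parts[0].replace(".", "").isdigit():
                continue  # header / blank lines
            rows.append(
                {
                    "chrom": parts[4],
                    "start": int(parts[5]) - 1,
                    "end": int(parts[6]),
                    "family": parts[10],
                    "divergence": float(parts[1]),
                }
            )
    return pd.DataFrame(rows)


def read_gametolog_fasta(path: str | Path, z_suffix: str = "_Z", w_suffix: str = "_W"):
    """Paired aligned CDS FASTA (two records per gene, suffix-tagged) ->
    list of (gene, z_seq, w_seq)."""
    seqs = read_fasta(path)
    genes: dict[str, dict[str, str]] = {}
    for name, seq in seqs.items():
        for suffix, key in ((z_suffix, "Z"), (w_suffix, "W")):
            if name.endswith(suffix):
                genes.setdefault(name[: -len(suffix)], {})[key] = seq
    out = []
    for gene, parts in sorted(genes.items()):
        if set(parts) != {"Z", "W"}:
            raise ValueError(f"{gene}: missing Z or W record")
        out.append((gene, parts["Z"], parts["W"]))
    return out
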