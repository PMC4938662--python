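"""File format helpers: FASTA, BED, GFF3, TSV.

Internal coordinates are 0-based half-open; BED files follow the same
convention, GFF3 output is converted to 1-based closed on write.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA -> {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Mapping[str, str], width: int = 80) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ -> DataFrame with columns chrom, start, end (extra columns kept)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + [f"col{i}" for i in range(len(names), df.shape[1])]
    return df


def write_bed(path: str | Path, intervals: Iterable[tuple], extra_cols: bool = True) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = iv if extra_cols else iv[:3]
            fh.write("\t".join(str(x) for x in fields) + "\n")


def write_gff3(path: str | Path, features: Iterable[dict]) -> None:
    """Write feature dicts as GFF3.

    Each feature dict needs: chrom, source, type, start, end (0-based
    half-open; converted here), strand, attributes (dict).  Optional: score,
    phase.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f["attributes"].items())
            fh.write(
                "\t".join(
                    [
                        f["chrom"],
                        f.get("source", "cactakit"),
                        f["type"],
                        str(f["start"] + 1),
                        str(f["end"]),
                        str(f.get("score", ".")),
                        f.get("strand", "."),
                        str(f.get("phase", ".")),
                        attrs,
                    ]
                )
                + "\n"
            )


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
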