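"""Plain-text readers and writers for the pipeline's file formats.

FASTA/FASTQ go through Biopython; tabular formats are TSV via pandas.
Coordinates in the mature-annotation TSV are 0-based half-open, plus
strand only.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .consensus import PlatformRatioMatrix
from .read_processing import MiRNAReference, ReadRecord


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_reference(
    reference: MiRNAReference, fasta_path: str | Path, tsv_path: str | Path
) -> None:
    write_fasta(reference.precursors, fasta_path)
    rows = [
        {"locus_id": locus, "precursor_id": pre, "start": s, "end": e}
        for locus, (pre, s, e) in sorted(reference.matures.items())
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_reference(fasta_path: str | Path, tsv_path: str | Path) -> MiRNAReference:
    precursors = read_fasta(fasta_path)
    table = pd.read_csv(tsv_path, sep="\t")
    matures = {
        row["locus_id"]: (row["precursor_id"], int(row["start"]), int(row["end"]))
        for _, row in table.iterrows()
    }
    return MiRNAReference(precursors=precursors, matures=matures)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        out.append(
            ReadRecord(rec.id, str(rec.seq).upper(), "".join(chr(q + 33) for q in quals))
        )
    return out


def write_ratio_matrix(matrix: PlatformRatioMatrix, path: str | Path) -> None:
    matrix.log2ratio.rename_axis("mirna").to_csv(path, sep="\t")


def read_ratio_matrix(path: str | Path, platform: str) -> PlatformRatioMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PlatformRatioMatrix(platform=platform, log2ratio=df)


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
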