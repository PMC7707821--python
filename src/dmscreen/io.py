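"""Readers and writers for the pipeline's file formats.

Reads come in as FASTQ or one-sequence-per-line TSV; references as FASTA;
everything tabular (designed-variant manifests, barcode maps, count tables,
activity tables, annotation inputs) is plain TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import ReceptorDesign, Variant, split_segments


def read_reads(path: str | Path) -> list[str]:
    """Merged reads from FASTQ (.fastq/.fq) or one-sequence-per-line text."""
    path = Path(path)
    if path.suffix.lower() in (".fastq", ".fq"):
        return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
    with open(path) as fh:
        return [line.strip().split("\t")[-1] for line in fh if line.strip()]


def write_reads_fastq(reads: list[str], path: str | Path) -> None:
    records = (
        SeqRecord(Seq(seq), id=f"read{i}", description="",
                  letter_annotations={"phred_quality": [40] * len(seq)})
        for i, seq in enumerate(reads)
    )
    SeqIO.write(records, str(path), "fastq")


def read_reference(path: str | Path) -> str:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()


def write_reference(cds: str, path: str | Path, name: str = "reference") -> None:
    SeqIO.write([SeqRecord(Seq(cds), id=name, description="")], str(path), "fasta")


def write_design(design: ReceptorDesign, fasta_path: str | Path,
                 manifest_path: str | Path) -> None:
    """Reference FASTA plus designed-variant manifest TSV.

    Manifest columns: position (1-based residue), wt_aa, mut_aa, codon,
    segment (0-based index).
    """
    write_reference(design.cds, fasta_path)
    rows = [{"position": v.position, "wt_aa": v.wt_aa, "mut_aa": v.mut_aa,
             "codon": v.codon, "segment": design.segment_of(v.position)}
            for v in design.variants]
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)


def read_design(fasta_path: str | Path, manifest_path: str | Path) -> ReceptorDesign:
    cds = read_reference(fasta_path)
    man = pd.read_csv(manifest_path, sep="\t")
    n_segments = int(man["segment"].max()) + 1 if "segment" in man else 1
    segments = split_segments(len(cds) // 3, n_segments)
    variants = [Variant(int(r.position), r.wt_aa, r.mut_aa, r.codon)
                for r in man.itertuples(index=False)]
    return ReceptorDesign(cds=cds, segments=segments, variants=variants)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
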