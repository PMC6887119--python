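"""Readers and writers for the pipeline's external formats.

Alignments: minimal SAM (via pysam) or 3-column tabular
(read_id, ref, pos_5prime). Sequences: FASTA (via Biopython). Count
matrices, designs, curves and dose-response tables: TSV/YAML. Coverage
export: bedGraph / BED (0-based half-open, converted from the 1-based
inclusive internal convention).
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd

from .rtts import AlignedRead, RTStopProfile

FLAG_REVERSE = 16


def write_sam(
    alignments: Iterable[AlignedRead],
    path: str,
    reference_name: str,
    reference_length: int,
    read_length: int = 30,
) -> None:
    """Write minimal SAM records (no sequence/quality stored)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{reference_name}\tLN:{reference_length}\n")
        for rec in alignments:
            flag = FLAG_REVERSE if rec.reverse else 0
            # clip the CIGAR at the reference end
            span = min(read_length, reference_length - rec.pos + 1)
            fh.write(
                f"{rec.read_id}\t{flag}\t{rec.reference}\t{rec.pos}\t255\t"
                f"{span}M\t*\t0\t0\t*\t*\n"
            )


def read_sam(path: str) -> list[AlignedRead]:
    """Read alignments from SAM/BAM; the POS field is the 5' end for forward
    reads, the rightmost aligned base for reverse reads."""
    import pysam

    out = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            pos = (
                rec.reference_end
                if rec.is_reverse and rec.reference_end is not None
                else rec.reference_start + 1
            )
            out.append(
                AlignedRead(
                    read_id=rec.query_name,
                    reference=rec.reference_name,
                    pos=int(pos),
                    reverse=rec.is_reverse,
                )
            )
    return out


def write_tabular_alignments(
    alignments: Iterable[AlignedRead], path: str
) -> None:
    pd.DataFrame(
        {
            "read_id": [a.read_id for a in alignments],
            "ref": [a.reference for a in alignments],
            "pos_5prime": [a.pos for a in alignments],
        }
    ).to_csv(path, sep="\t", index=False)


def read_tabular_alignments(path: str) -> list[AlignedRead]:
    df = pd.read_csv(path, sep="\t")
    return [
        AlignedRead(read_id=str(r.read_id), reference=str(r.ref), pos=int(r.pos_5prime))
        for r in df.itertuples()
    ]


def read_alignments(path: str) -> list[AlignedRead]:
    """Dispatch on extension: .sam/.bam via pysam, else tabular TSV."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".sam", ".bam"):
        return read_sam(path)
    return read_tabular_alignments(path)


def write_fasta(records: Iterable[tuple[str, str]], path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        (
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records
        ),
        path,
        "fasta",
    )


def read_fasta(path: str) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def write_bedgraph(profile: RTStopProfile, path: str) -> None:
    """Per-position termination counts as bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        for i, c in enumerate(profile.counts):
            if c > 0:
                fh.write(f"{profile.reference_name}\t{i}\t{i + 1}\t{int(c)}\n")


def write_bed_sites(
    sites: list[tuple[int, int]], reference_name: str, path: str
) -> None:
    """Top sites as BED6 (0-based half-open, score = count)."""
    with open(path, "w") as fh:
        for rank, (pos, count) in enumerate(sites, start=1):
            fh.write(
                f"{reference_name}\t{pos - 1}\t{pos}\tsite_{rank}\t"
                f"{count}\t+\n"
            )


def read_design_yaml(path: str):
    """Sample design from YAML: a list of {sample_id, fraction, condition,
    replicate} mappings (or a mapping with key 'samples')."""
    import yaml

    from .te import SampleDesign

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        data = data["samples"]
    return SampleDesign(pd.DataFrame(data))


def read_counts_tsv(path: str) -> pd.DataFrame:
    """Gene x sample count matrix; first column is the gene id."""
    return pd.read_csv(path, sep="\t", index_col=0)
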