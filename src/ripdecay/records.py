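"""Transcript records and sequence canonicalization.

All sequences are stored in the RNA alphabet {A, C, G, U}; DNA input (T) is
accepted and converted on ingest. Coordinates are 1-based inclusive in all
user-facing interfaces, matching NCBI RefSeq conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

_DNA_TO_RNA = str.maketrans("acgtuACGTU", "ACGUUACGUU")


def canonicalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and convert T to U.

    Raises
    ------
    ValueError
        If the result contains characters outside {A, C, G, U}.
    """
    out = seq.translate(_DNA_TO_RNA)
    bad = set(out) - RNA_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-ACGU symbols: {sorted(bad)}")
    return out


@dataclass
class TranscriptRecord:
    """A transcript with its coding interval and derived 3'UTR.

    ``cds`` is a 1-based inclusive interval on ``sequence``; the stop codon is
    part of the CDS, so the 3'UTR is everything strictly after ``cds[1]``.
    ``is_planted_target`` / ``planted_motif`` carry synthetic ground truth and
    are meaningful only for simulated records.
    """

    transcript_id: str
    gene_symbol: str
    sequence: str
    cds: tuple[int, int]
    is_planted_target: bool = False
    planted_motif: Optional[str] = None
    utr3: str = field(init=False)

    def __post_init__(self) -> None:
        self.sequence = canonicalize_rna(self.sequence)
        start, end = self.cds
        if start < 1:
            raise ValueError(f"{self.transcript_id}: cds start {start} < 1")
        if end > len(self.sequence):
            raise ValueError(
                f"{self.transcript_id}: cds end {end} beyond sequence "
                f"length {len(self.sequence)}"
            )
        if start > end:
            raise ValueError(f"{self.transcript_id}: cds start > end")
        if (end - start + 1) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: cds length {end - start + 1} not a "
                "multiple of 3"
            )
        self.utr3 = self.sequence[end:]


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.transcript_id, description=r.gene_symbol)
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def annotation_frame(records: Iterable[TranscriptRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "gene_symbol": [r.gene_symbol for r in records],
            "cds_start": [r.cds[0] for r in records],
            "cds_end": [r.cds[1] for r in records],
            "is_planted_target": [r.is_planted_target for r in records],
            "planted_motif": [r.planted_motif or "" for r in records],
        }
    )


def read_transcripts(fasta_path: str | Path, annotation_path: str | Path) -> list[TranscriptRecord]:
    """Load transcripts from a FASTA file plus a TSV annotation table.

    The annotation table must have columns ``transcript_id``, ``cds_start``
    and ``cds_end``; ``gene_symbol`` and the planted-truth columns are
    optional.
    """
    ann = pd.read_csv(annotation_path, sep="\t", comment="#")
    for col in ("transcript_id", "cds_start", "cds_end"):
        if col not in ann.columns:
            raise ValueError(f"annotation table missing column {col!r}")
    ann = ann.set_index("transcript_id")
    records = []
    for sr in SeqIO.parse(str(fasta_path), "fasta"):
        if sr.id not in ann.index:
            raise ValueError(f"transcript {sr.id} not in annotation table")
        row = ann.loc[sr.id]
        records.append(
            TranscriptRecord(
                transcript_id=sr.id,
                gene_symbol=str(row.get("gene_symbol", sr.id)),
                sequence=str(sr.seq),
                cds=(int(row["cds_start"]), int(row["cds_end"])),
                is_planted_target=bool(row.get("is_planted_target", False)),
                planted_motif=str(row["planted_motif"]) or None
                if "planted_motif" in row and str(row.get("planted_motif", "")) != ""
                else None,
            )
        )
    return records
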