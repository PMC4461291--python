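"""CDS FASTA ingestion, quality filtering and in-frame codon counting.

Input is one nucleotide record per coding sequence.  Records are normalised
to an upper-case DNA alphabet (U -> T) on ingestion.  Filtering drops, with
a per-reason report, anything the downstream codon arithmetic cannot handle:
sequences shorter than the minimum length (300 bp by default, to avoid
small-sample outliers in per-gene indices), sequences whose length is not a
multiple of three, and sequences with an in-frame internal stop codon.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import ALL_CODONS, GeneticCode, standard_code

__all__ = [
    "CdsRecord",
    "CodonCounts",
    "FastaParseError",
    "read_cds_fasta",
    "write_cds_fasta",
    "filter_cds",
    "count_codons",
    "pool_counts",
]

_VALID_CHARS = set("ACGT")
# IUPAC ambiguity codes are tolerated in sequences; codons containing them
# are skipped during counting rather than imputed.
_AMBIGUOUS = set("NRYWSKMBDHV")


class FastaParseError(ValueError):
    """Raised when a FASTA record cannot be interpreted as a nucleotide CDS."""


@dataclass(frozen=True)
class CdsRecord:
    """A single coding sequence: identifier plus normalised DNA string."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CodonCounts:
    """In-frame codon counts for one gene (or a pooled set of genes).

    ``n_skipped`` counts triplets dropped because they contained ambiguity
    codes; conservation ``3 * (sum(counts) + n_skipped) == length`` holds
    whenever a whole CDS was counted.
    """

    gene_id: str
    counts: dict[str, int] = field(default_factory=dict)
    n_skipped: int = 0

    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(codon, 0)


def _normalise(seq: str, record_id: str) -> str:
    out = seq.upper().replace("U", "T")
    bad = set(out) - _VALID_CHARS - _AMBIGUOUS
    if bad:
        raise FastaParseError(
            f"record {record_id!r}: illegal characters {sorted(bad)} "
            "(expected nucleotide sequence)"
        )
    return out


def read_cds_fasta(path: str | Path) -> list[CdsRecord]:
    """Read a multi-FASTA of coding sequences.

    IDs are the FASTA header up to the first whitespace; sequences are
    upper-cased with U converted to T.  An empty file yields an empty list
    with a warning.
    """
    path = Path(path)
    records = [
        CdsRecord(id=rec.id, sequence=_normalise(str(rec.seq), rec.id))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_cds_fasta(records: list[CdsRecord], path: str | Path) -> None:
    """Write records back to FASTA (round-trips exactly with read_cds_fasta)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(Path(path)), "fasta")


def _has_internal_stop(seq: str, code: GeneticCode) -> bool:
    # scan frame-0 codons excluding the terminal one
    for i in range(0, len(seq) - 3, 3):
        if seq[i : i + 3] in code.stop_codons:
            return True
    return False


def filter_cds(
    records: list[CdsRecord],
    min_len: int = 300,
    code: GeneticCode | None = None,
) -> tuple[list[CdsRecord], pd.DataFrame]:
    """Keep CDS of at least ``min_len`` bp, in frame, with no internal stop.

    Returns the kept records and a per-record report DataFrame with columns
    ``id, length, kept, reason`` (reason is one of ``""``, ``"too_short"``,
    ``"frame"``, ``"internal_stop"``; the first failing check is reported).
    Filtering is total (never raises) and idempotent.
    """
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    code = code or standard_code()
    rows = []
    kept: list[CdsRecord] = []
    for rec in records:
        n = len(rec)
        if n < min_len:
            reason = "too_short"
        elif n % 3 != 0:
            reason = "frame"
        elif _has_internal_stop(rec.sequence, code):
            reason = "internal_stop"
        else:
            reason = ""
            kept.append(rec)
        rows.append({"id": rec.id, "length": n, "kept": reason == "", "reason": reason})
    report = pd.DataFrame(rows, columns=["id", "length", "kept", "reason"])
    return kept, report


def drop_reason_tally(report: pd.DataFrame) -> Counter:
    return Counter(report.loc[~report["kept"], "reason"])


def count_codons(
    record: CdsRecord,
    include_terminal_stop: bool = True,
    code: GeneticCode | None = None,
) -> CodonCounts:
    """Count in-frame, non-overlapping codons of a filtered CDS.

    Triplets containing any non-ACGT symbol are tallied in ``n_skipped``.
    The terminal stop codon is counted by default so that genome-level RSCU
    tables can include the stop family; pass ``include_terminal_stop=False``
    to reproduce annotation conventions that strip stops.
    """
    code = code or standard_code()
    seq = record.sequence
    counts: dict[str, int] = {}
    n_skipped = 0
    last = len(seq) - len(seq) % 3
    for i in range(0, last, 3):
        codon = seq[i : i + 3]
        if not set(codon) <= _VALID_CHARS:
            n_skipped += 1
            continue
        if (
            not include_terminal_stop
            and i == last - 3
            and codon in code.stop_codons
        ):
            continue
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(gene_id=record.id, counts=counts, n_skipped=n_skipped)


def pool_counts(counts_list: list[CodonCounts], gene_id: str = "pooled") -> CodonCounts:
    """Sum per-gene codon counts into one pooled vector."""
    pooled: dict[str, int] = {}
    n_skipped = 0
    for cc in counts_list:
        n_skipped += cc.n_skipped
        for codon, n in cc.counts.items():
            pooled[codon] = pooled.get(codon, 0) + n
    return CodonCounts(gene_id=gene_id, counts=pooled, n_skipped=n_skipped)


def counts_vector(counts: CodonCounts) -> pd.Series:
    """Counts as a 64-long Series indexed by codon in TCAG order."""
    return pd.Series({c: counts[c] for c in ALL_CODONS}, dtype=int)
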