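"""Reading, writing and quality-filtering of coding sequences.

Codon usage indices are only meaningful on clean, full-length CDS, so the
analysis starts from three filters commonly applied to GenBank CDS dumps:
a proper ATG start, a terminal stop codon, and a minimum length (strictly
more than ``min_len_nt`` nucleotides). Exact duplicate sequences are
removed, keeping the first occurrence. Sequences whose length is not a
multiple of three cannot be decomposed into codons and are tallied as a
separate rejection class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import GeneticCode, standard_code

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")


@dataclass
class CdsRecord:
    """One coding sequence, uppercased and DNA-normalized (U -> T)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")

    @property
    def codons(self) -> list[str]:
        """Complete in-frame 3-mers; a trailing partial codon is dropped."""
        s = self.seq
        return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]

    @property
    def is_triplet(self) -> bool:
        return len(self.seq) % 3 == 0

    @property
    def has_start(self) -> bool:
        return self.seq.startswith("ATG")

    def has_terminal_stop(self, code: GeneticCode | None = None) -> bool:
        code = code or standard_code()
        return self.seq[-3:] in code.stop_codons

    def internal_stops(self, code: GeneticCode | None = None) -> list[int]:
        """Codon indices (0-based) of stop codons before the last codon."""
        code = code or standard_code()
        return [i for i, c in enumerate(self.codons[:-1]) if c in code.stop_codons]

    @property
    def coding_codons(self) -> list[str]:
        """Codons minus a terminal stop, if present."""
        cods = self.codons
        if cods and self.has_terminal_stop():
            return cods[:-1]
        return cods


@dataclass
class FilterReport:
    """Tally of the QC outcome, one rejection class per record."""

    n_input: int = 0
    n_no_start: int = 0
    n_no_stop: int = 0
    n_too_short: int = 0
    n_not_triplet: int = 0
    n_duplicate: int = 0
    n_retained: int = 0
    retained_ids: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return (
            self.n_no_start
            + self.n_no_stop
            + self.n_too_short
            + self.n_not_triplet
            + self.n_duplicate
        )

    def to_tsv(self, path: str | Path) -> None:
        lines = ["metric\tcount"]
        for k in (
            "n_input",
            "n_no_start",
            "n_no_stop",
            "n_too_short",
            "n_not_triplet",
            "n_duplicate",
            "n_retained",
        ):
            lines.append(f"{k}\t{getattr(self, k)}")
        Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> list[CdsRecord]:
    """Parse a nucleotide FASTA into :class:`CdsRecord` objects.

    Sequences are uppercased and U is mapped to T; records of non-triplet
    length are kept (they fail :func:`filter_cds` later) but logged.
    """
    path = Path(path)
    records = [CdsRecord(id=r.id, seq=str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        logger.warning("no FASTA records found in %s", path)
    for r in records:
        if not r.is_triplet:
            logger.warning("sequence %s has non-triplet length %d", r.id, len(r.seq))
    return records


def write_fasta(records: list[CdsRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def filter_cds(
    records: list[CdsRecord],
    min_len_nt: int = 300,
    code: GeneticCode | None = None,
) -> tuple[list[CdsRecord], FilterReport]:
    """Apply the start / stop / length / triplet / duplicate filters.

    Each record is attributed to the first rule it fails, in that order, so
    the tallies plus ``n_retained`` always add up to ``n_input``. The length
    rule is strict (``> min_len_nt``); combined with the triplet rule the
    shortest surviving CDS has 303 nt with the default. Internal stop codons
    do not reject a record (they are logged); ambiguous bases are handled
    downstream by skipping the affected codons.
    """
    code = code or standard_code()
    report = FilterReport(n_input=len(records))
    seen: set[str] = set()
    kept: list[CdsRecord] = []
    for rec in records:
        if not rec.has_start:
            report.n_no_start += 1
        elif not rec.has_terminal_stop(code):
            report.n_no_stop += 1
        elif len(rec.seq) <= min_len_nt:
            report.n_too_short += 1
        elif not rec.is_triplet:
            report.n_not_triplet += 1
        elif rec.seq in seen:
            report.n_duplicate += 1
        else:
            seen.add(rec.seq)
            kept.append(rec)
            if rec.internal_stops(code):
                logger.info("retained %s with internal stop codon(s)", rec.id)
    report.n_retained = len(kept)
    report.retained_ids = [r.id for r in kept]
    return kept, report
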