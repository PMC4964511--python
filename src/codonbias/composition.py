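"""Per-gene nucleotide composition: GC, positional GC, GC3s and base-wise
third-position fractions.

Conventions (CodonW-style, made self-consistent):

* the terminal stop codon is excluded from every per-gene index;
* codons containing non-ACGT characters are skipped;
* GC1/GC2/GC3 are the G+C fractions at codon positions 1/2/3 over the same
  codon set, so GC == (GC1+GC2+GC3)/3 exactly;
* GC12 is the plain average of GC1 and GC2 (the neutrality-plot ordinate);
* GC3s and A3s/T3s/C3s/G3s use only third positions of *synonymous* codons
  (families of size >= 2: Met, Trp and stop codons excluded from the
  denominator), so the four base fractions sum to 1.

Undefined values (empty denominators) are returned as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .cds_io import CdsRecord, VALID_BASES
from .genetic_code import GeneticCode, standard_code

#: order of the numeric indices in tabular output
INDEX_COLUMNS = (
    "gc", "gc1", "gc2", "gc3", "gc12", "gc3s", "t3s", "c3s", "a3s", "g3s",
)


@dataclass
class CompositionProfile:
    gene_id: str
    length_nt: int
    n_codons: int
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float
    a3s: float
    t3s: float
    c3s: float
    g3s: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _gc_fraction(bases: list[str]) -> float:
    if not bases:
        return math.nan
    return sum(b in "GC" for b in bases) / len(bases)


def composition_profile(
    record: CdsRecord, code: GeneticCode | None = None
) -> CompositionProfile:
    """Compute all composition indices for one CDS.

    Raises
    ------
    ValueError
        If no countable (unambiguous) codon remains after exclusions.
    """
    code = code or standard_code()
    codons = [c for c in record.coding_codons if set(c) <= VALID_BASES]
    if not codons:
        raise ValueError(f"gene {record.id}: no countable codons")

    pos = [[c[i] for c in codons] for i in range(3)]
    gc1, gc2, gc3 = (_gc_fraction(p) for p in pos)

    syn = set(code.synonymous_codons)
    third_syn = [c[2] for c in codons if c in syn]
    n3 = len(third_syn)
    if n3:
        counts = {b: third_syn.count(b) / n3 for b in "ATCG"}
        gc3s = counts["G"] + counts["C"]
    else:
        counts = {b: math.nan for b in "ATCG"}
        gc3s = math.nan

    return CompositionProfile(
        gene_id=record.id,
        length_nt=len(record.seq),
        n_codons=len(codons),
        gc=(gc1 + gc2 + gc3) / 3,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc12=(gc1 + gc2) / 2,
        gc3s=gc3s,
        a3s=counts["A"],
        t3s=counts["T"],
        c3s=counts["C"],
        g3s=counts["G"],
    )


def profiles_to_frame(profiles: list[CompositionProfile]) -> pd.DataFrame:
    """One row per gene, indexed by gene id."""
    df = pd.DataFrame([p.as_dict() for p in profiles]).set_index("gene_id")
    return df


@dataclass
class PooledComposition:
    """Across-gene summary: unweighted mean and sample SD of each index."""

    summary: pd.DataFrame  # rows = index names, columns = mean, sd
    n_genes: int
    total_codons: int


def pooled_composition(profiles: list[CompositionProfile]) -> PooledComposition:
    """Mean +/- sample standard deviation (ddof=1) of every index.

    A single gene yields SD 0 by convention. The total codon count pools
    the per-gene countable codons.
    """
    if not profiles:
        raise ValueError("no profiles to pool")
    df = profiles_to_frame(profiles)[list(INDEX_COLUMNS)]
    mean = df.mean()
    sd = df.std(ddof=1) if len(df) > 1 else pd.Series(0.0, index=df.columns)
    sd = sd.fillna(0.0) if len(df) == 1 else sd
    summary = pd.DataFrame({"mean": mean, "sd": sd})
    return PooledComposition(
        summary=summary,
        n_genes=len(profiles),
        total_codons=int(np.sum([p.n_codons for p in profiles])),
    )
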