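"""Codon-usage bias indices: RSCU, Wright's ENC, CAI, GRAVY and aromaticity.

RSCU
    Relative synonymous codon usage. For codon *i* of an amino acid with
    family size *k* and family total *X*: ``RSCU_i = k * x_i / X``. Values
    above 1 mark codons used more often than the uniform expectation.

ENC
    Wright's effective number of codons, built from the corrected codon
    homozygosity per amino acid, ``F = (n * sum(p_i^2) - 1) / (n - 1)``,
    averaged within degeneracy classes and combined as
    ``ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``. ENC is 20 when one codon is
    used per amino acid and approaches 61 under uniform usage; finite-sample
    estimates slightly above 61 are capped at 61.

CAI
    Codon adaptation index (Sharp & Li): the count-weighted geometric mean
    of relative adaptiveness weights ``w_i = x_i / max(x_family)`` taken
    from a reference set of highly biased / highly expressed genes. Met,
    Trp and stop codons are excluded.

GRAVY / aromaticity
    Mean Kyte-Doolittle hydropathy and the Phe+Tyr+Trp fraction of the
    translated product; both are classic covariates of codon bias trends.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .cds_io import CdsRecord, VALID_BASES
from .composition import composition_profile
from .genetic_code import GeneticCode, standard_code, to_rna

logger = logging.getLogger(__name__)

AROMATIC = frozenset("FYW")

ENC_MAX = 61.0


@dataclass
class CodonCountTable:
    """Counts over the 64 codons, for one gene or pooled over many."""

    counts: dict[str, int]
    scope: str = "gene"

    def __post_init__(self) -> None:
        code = standard_code()
        full = {c: 0 for c in code.sense_codons}
        full.update({c: 0 for c in sorted(code.stop_codons)})
        for codon, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {codon}")
            if codon in full:
                full[codon] += int(n)
        self.counts = full

    @property
    def n_sense(self) -> int:
        stops = standard_code().stop_codons
        return sum(n for c, n in self.counts.items() if c not in stops)

    @property
    def n_stop(self) -> int:
        stops = standard_code().stop_codons
        return sum(n for c, n in self.counts.items() if c in stops)

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = {c: self.counts[c] + other.counts[c] for c in self.counts}
        return CodonCountTable(counts=merged, scope="pooled")

    def __getitem__(self, codon: str) -> int:
        return self.counts[codon]


def count_codons(record: CdsRecord) -> CodonCountTable:
    """Count every unambiguous codon of a record (terminal stop included,
    tallied under ``n_stop``); codons with non-ACGT characters are skipped."""
    counts: dict[str, int] = {}
    skipped = 0
    for codon in record.codons:
        if set(codon) <= VALID_BASES:
            counts[codon] = counts.get(codon, 0) + 1
        else:
            skipped += 1
    if skipped:
        logger.info("%s: skipped %d ambiguous codon(s)", record.id, skipped)
    return CodonCountTable(counts=counts, scope="gene")


def pool_counts(tables: list[CodonCountTable]) -> CodonCountTable:
    if not tables:
        raise ValueError("nothing to pool")
    out = tables[0]
    for t in tables[1:]:
        out = out + t
    return out


@dataclass
class RscuTable:
    """RSCU per codon plus per-family sums; unobserved families are NaN."""

    values: dict[str, float]
    family_sums: dict[str, float]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values)


def rscu(
    table: CodonCountTable,
    code: GeneticCode | None = None,
    include_stops: bool = False,
) -> RscuTable:
    """RSCU for every sense codon (optionally the stop family as well).

    Families with zero observations yield NaN entries; observed families
    satisfy ``sum(RSCU) == family size``.
    """
    code = code or standard_code()
    families: dict[str, tuple[str, ...]] = dict(code.families)
    if include_stops:
        families["*"] = tuple(sorted(code.stop_codons))
    values: dict[str, float] = {}
    sums: dict[str, float] = {}
    for aa, fam in families.items():
        k = len(fam)
        total = sum(table[c] for c in fam)
        if total == 0:
            for c in fam:
                values[c] = math.nan
            sums[aa] = math.nan
            continue
        for c in fam:
            values[c] = k * table[c] / total
        sums[aa] = float(sum(values[c] for c in fam))
    return RscuTable(values=values, family_sums=sums)


def mean_rscu_over_genes(
    tables: list[CodonCountTable], code: GeneticCode | None = None
) -> pd.Series:
    """Average of per-gene RSCU (NaN families dropped per gene).

    Complements the pooled-count RSCU: genome-wide tables can be built
    either by pooling counts first or by averaging per-gene RSCU, and the
    two differ whenever usage covaries with gene length or bias.
    """
    code = code or standard_code()
    rows = [rscu(t, code).as_series() for t in tables]
    return pd.concat(rows, axis=1).mean(axis=1, skipna=True)


def family_homozygosity(family_counts: list[int] | np.ndarray) -> float:
    """Wright's corrected codon homozygosity for one amino acid.

    ``F = (n * sum(p^2) - 1) / (n - 1)`` with ``n`` the family total;
    undefined (NaN) for ``n <= 1``. Bounded in [0, 1].
    """
    counts = np.asarray(family_counts, dtype=float)
    n = counts.sum()
    if n <= 1:
        return math.nan
    p = counts / n
    return float((n * np.sum(p * p) - 1.0) / (n - 1.0))


def enc(table: CodonCountTable, code: GeneticCode | None = None) -> float:
    """Effective number of codons for a single gene, capped at 61.

    Per-amino-acid homozygosities are averaged within the degeneracy
    classes (nine 2-fold, Ile as the lone 3-fold, five 4-fold, three
    6-fold amino acids; Met and Trp contribute the constant 2). A class
    average is formed over amino acids with at least two codons observed.
    If the 3-fold or 6-fold class has no estimate, the harmonic mean
    ``2/(1/F2 + 1/F4)`` substitutes; if the 2-fold or 4-fold class itself
    is empty, or any class average is zero, ENC is undefined (NaN).
    """
    code = code or standard_code()
    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in code.families.items():
        k = len(fam)
        if k == 1:
            continue
        f = family_homozygosity([table[c] for c in fam])
        if not math.isnan(f):
            per_class[k].append(f)

    if not per_class[2] or not per_class[4]:
        return math.nan
    f2 = float(np.mean(per_class[2]))
    f4 = float(np.mean(per_class[4]))
    if f2 == 0.0 or f4 == 0.0:
        return math.nan
    fallback = 2.0 / (1.0 / f2 + 1.0 / f4)
    f3 = float(np.mean(per_class[3])) if per_class[3] else fallback
    f6 = float(np.mean(per_class[6])) if per_class[6] else fallback
    if f3 == 0.0 or f6 == 0.0:
        return math.nan
    value = 2.0 + 9.0 / f2 + 1.0 / f3 + 5.0 / f4 + 3.0 / f6
    return min(value, ENC_MAX)


@dataclass
class ReferenceWeights:
    """Relative adaptiveness weights for CAI, one per sense codon."""

    w: dict[str, float]
    source: str = "user table"

    def __getitem__(self, codon: str) -> float:
        return self.w[codon]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("codon\tweight\n")
            for c, v in self.w.items():
                fh.write(f"{to_rna(c)}\t{v:.6f}\n")


def cai_weights(
    reference: CodonCountTable,
    code: GeneticCode | None = None,
    floor: float = 0.01,
    source: str = "reference counts",
) -> ReferenceWeights:
    """Relative adaptiveness ``w_i = x_i / max(x_family)`` from pooled
    reference counts; zero-count codons are floored at ``floor`` so the
    geometric mean stays finite. Families entirely absent from the
    reference are uninformative and get weight 1 throughout."""
    code = code or standard_code()
    if reference.n_sense == 0:
        raise ValueError("empty CAI reference set")
    w: dict[str, float] = {}
    for aa, fam in code.families.items():
        best = max(reference[c] for c in fam)
        for c in fam:
            if best == 0:
                w[c] = 1.0
            else:
                w[c] = max(reference[c] / best, floor)
    return ReferenceWeights(w=w, source=source)


def cai(
    gene: CodonCountTable,
    weights: ReferenceWeights,
    code: GeneticCode | None = None,
) -> float:
    """Count-weighted geometric mean of weights over the gene's codons.

    Met, Trp and stop codons carry no synonymous signal and are excluded;
    undefined (NaN) when no countable codon remains.
    """
    code = code or standard_code()
    syn = code.synonymous_codons
    total = 0
    log_sum = 0.0
    for c in syn:
        n = gene[c]
        if n:
            total += n
            log_sum += n * math.log(weights[c])
    if total == 0:
        logger.warning("CAI undefined: no synonymous codons counted")
        return math.nan
    return math.exp(log_sum / total)


def translate(record: CdsRecord, code: GeneticCode | None = None) -> str:
    """Conceptual translation of the coding codons; terminal stop excluded,
    internal stops and ambiguous codons skipped."""
    code = code or standard_code()
    return "".join(
        code.codon_to_aa[c]
        for c in record.coding_codons
        if c in code.codon_to_aa
    )


def gravy(record: CdsRecord, code: GeneticCode | None = None) -> float:
    """Grand average of hydropathy (Kyte-Doolittle) of the translation."""
    protein = translate(record, code)
    if not protein:
        return math.nan
    return float(np.mean([KYTE_DOOLITTLE[a] for a in protein]))


def aromaticity(record: CdsRecord, code: GeneticCode | None = None) -> float:
    """Fraction of aromatic residues (Phe, Tyr, Trp) in the translation."""
    protein = translate(record, code)
    if not protein:
        return math.nan
    return sum(a in AROMATIC for a in protein) / len(protein)


def profile_genes(
    records: list[CdsRecord],
    code: GeneticCode | None = None,
    weights: ReferenceWeights | None = None,
) -> pd.DataFrame:
    """Per-gene table of every index (composition, ENC, expected ENC and
    ENC ratio, CAI if weights are given, GRAVY, aromaticity).

    Returns a DataFrame indexed by gene id — the substrate for neutrality
    fits, correspondence analysis and optimal-codon detection.
    """
    from .enc_neutrality import enc_expected, enc_ratio  # local: avoid cycle at import time

    code = code or standard_code()
    rows = []
    for rec in records:
        comp = composition_profile(rec, code)
        counts = count_codons(rec)
        enc_obs = enc(counts, code)
        row = comp.as_dict()
        row["length_codons"] = len(rec.coding_codons)
        row["enc"] = enc_obs
        if not math.isnan(comp.gc3s):
            row["enc_exp"] = enc_expected(comp.gc3s)
            row["enc_ratio"] = enc_ratio(enc_obs, comp.gc3s)
        else:
            row["enc_exp"] = math.nan
            row["enc_ratio"] = math.nan
        row["cai"] = cai(counts, weights, code) if weights is not None else math.nan
        row["gravy"] = gravy(rec, code)
        row["aromo"] = aromaticity(rec, code)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("gene_id")
    front = ["length_nt", "length_codons", "n_codons"]
    return df[front + [c for c in df.columns if c not in front]]
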