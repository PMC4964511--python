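"""Optimal-codon detection from the extremes of the ENC-ratio ordering.

Genes are ranked by their ENC ratio (how far observed ENC falls below the
mutation-only expectation). The top 5% form the "high bias" subset —
putatively highly expressed, selection-shaped genes — and the bottom 5%
the "low bias" subset. Codon counts are pooled within each subset, RSCU is
computed per subset, and a codon is called optimal when its usage is
elevated in the high-bias subset by more than a fixed margin:
``delta RSCU = RSCU_high - RSCU_low > 0.08``. Stop codons and the
single-codon amino acids (Met, Trp) are never called optimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .bias_indices import CodonCountTable, rscu
from .genetic_code import GeneticCode, standard_code, to_rna

DEFAULT_FRACTION = 0.05
DEFAULT_DELTA = 0.08


@dataclass
class BiasSubsets:
    """Gene ids of the high- and low-bias extremes of the ENC-ratio order."""

    high_ids: list[str]
    low_ids: list[str]
    subset_size: int
    fraction: float


def subset_size(n_genes: int, fraction: float = DEFAULT_FRACTION) -> int:
    """Number of genes per extreme subset: ceiling(fraction * N)."""
    return math.ceil(fraction * n_genes)


def select_bias_subsets(
    enc_ratios: pd.Series | dict[str, float],
    fraction: float = DEFAULT_FRACTION,
) -> BiasSubsets:
    """Split the ENC-ratio ordering into its 5% extremes.

    High bias = largest ENC ratios (observed ENC far below expected); ties
    are broken by gene id so the selection is deterministic. Genes with
    undefined ratios are excluded before sizing.

    Raises
    ------
    ValueError
        If the two subsets would overlap (too few genes for ``fraction``).
    """
    s = pd.Series(enc_ratios, dtype=float).dropna()
    n = len(s)
    size = subset_size(n, fraction)
    if n == 0 or 2 * size > n:
        raise ValueError(
            f"{n} genes cannot support disjoint {fraction:.0%} subsets of size {size}"
        )
    df = s.rename("enc_ratio").rename_axis("gene_id").reset_index()
    high = df.sort_values(["enc_ratio", "gene_id"], ascending=[False, True])
    low = df.sort_values(["enc_ratio", "gene_id"], ascending=[True, True])
    return BiasSubsets(
        high_ids=high["gene_id"].head(size).tolist(),
        low_ids=low["gene_id"].head(size).tolist(),
        subset_size=size,
        fraction=fraction,
    )


def optimal_codon_table(
    high: CodonCountTable,
    low: CodonCountTable,
    code: GeneticCode | None = None,
    threshold: float = DEFAULT_DELTA,
) -> pd.DataFrame:
    """Per-codon subset RSCU, delta RSCU and the optimal call.

    Subset RSCU is pooled (counts summed over the subset's genes first).
    ``optimal`` is True for synonymous sense codons with
    ``delta_rscu > threshold``; stop codons, Met and Trp are excluded.
    Codons of a family absent from either subset have NaN delta and are
    never optimal. Rows follow the amino-acid family layout.
    """
    code = code or standard_code()
    if high.n_sense == 0 or low.n_sense == 0:
        raise ValueError("both subsets must contain sense codons")
    rscu_high = rscu(high, code, include_stops=True).values
    rscu_low = rscu(low, code, include_stops=True).values

    families: dict[str, tuple[str, ...]] = dict(code.families)
    families["*"] = tuple(sorted(code.stop_codons))
    rows = []
    for aa, fam in families.items():
        multi = len(fam) > 1 and aa != "*"
        for c in fam:
            rh, rl = rscu_high[c], rscu_low[c]
            delta = rh - rl
            rows.append(
                {
                    "amino_acid": aa,
                    "codon": to_rna(c),
                    "rscu_high": rh,
                    "n_high": high[c],
                    "rscu_low": rl,
                    "n_low": low[c],
                    "delta_rscu": delta,
                    "optimal": bool(multi and not math.isnan(delta) and delta > threshold),
                }
            )
    return pd.DataFrame(rows)


def ending_base_tally(table: pd.DataFrame) -> dict[str, int]:
    """Count optimal codons by third-position base (RNA alphabet)."""
    tally = {b: 0 for b in "UCAG"}
    for codon in table.loc[table["optimal"], "codon"]:
        tally[codon[-1]] += 1
    return tally
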