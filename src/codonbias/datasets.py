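"""Packaged reference tables: published genome-wide codon usage of the
grass endophyte *Epichloë festucae* (4870 filtered CDS).

Two tables ship with the package, transcribed from the published study of
that genome:

* the genome-wide codon usage table (per-codon total counts and the
  RSCU values as printed — note the printed RSCU column reflects the
  authors' own computation and is not exactly reproducible from the
  printed counts under the pooled formula);
* the high-/low-bias subset RSCU table (5% extremes of the ENC-ratio
  ordering, 244 genes each) with the published optimal-codon calls.

They serve as ready-made inputs for the optimal-codon rule and as
regression fixtures for the index implementations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .bias_indices import CodonCountTable
from .genetic_code import to_dna


def _read(name: str) -> pd.DataFrame:
    with resources.files("codonbias.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["codon_dna"] = df["codon"].map(to_dna)
    return df


def load_efestucae_codon_usage() -> pd.DataFrame:
    """Genome-wide per-codon totals and published RSCU (64 rows)."""
    return _read("efestucae_codon_usage.tsv")


def efestucae_codon_counts() -> CodonCountTable:
    """The genome-wide totals as a pooled :class:`CodonCountTable`."""
    df = load_efestucae_codon_usage()
    return CodonCountTable(
        counts=dict(zip(df["codon_dna"], df["total_count"])), scope="pooled"
    )


def load_efestucae_subset_rscu() -> pd.DataFrame:
    """High-/low-bias subset RSCU values, counts and published optimal
    flags (64 rows; ``optimal_published`` is 0/1)."""
    return _read("efestucae_subset_rscu.tsv")
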