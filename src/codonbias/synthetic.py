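"""Synthetic CDS generation with controlled mutation pressure and
translational selection.

Each gene is generated under a two-force model:

* a **mutation kernel** sets third-position base probabilities from the
  gene's GC3 target (``P(G) = P(C) = gc3/2``, ``P(A) = P(T) = (1-gc3)/2``),
  renormalized within each synonymous family — mutation pressure alone
  therefore drives genes along the ENC-plot null curve;
* a **selection tilt** multiplies the probability of the family's
  preferred codon by ``exp(s)`` before renormalizing, a discrete-choice
  form that nests neutrality at ``s = 0`` and pins usage to the preferred
  set as ``s`` grows.

Defaults emulate a fungal genome-scale dataset: 4870 genes, mean length
around 500 codons (all > 300 nt), per-gene GC3 targets spread uniformly
over 0.20-0.95, and per-gene selection strengths drawn from an
exponential distribution so most genes sit near the mutational null while
a tail of selection-shaped genes reaches strong bias. Every gene starts
with ATG and ends with a stop codon, so the whole set passes the QC
filters by construction. Generation is fully deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cds_io import CdsRecord
from .genetic_code import GeneticCode, standard_code

#: average amino-acid composition of well-annotated proteomes
#: (Swiss-Prot-style frequencies, normalized at use)
DEFAULT_AA_FREQUENCIES: dict[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}


def default_preferred_codons(code: GeneticCode | None = None) -> dict[str, str]:
    """One preferred codon per multi-codon family: the C-ending codon
    (first in TCAG order) when the family has one, else a G-ending codon —
    mirroring the G/C-ending optima typical of GC-rich fungal genomes."""
    code = code or standard_code()
    preferred = {}
    for aa, fam in code.families.items():
        if len(fam) == 1:
            continue
        by_end = {c[2]: c for c in reversed(fam)}
        preferred[aa] = by_end.get("C") or by_end.get("G") or fam[0]
    return preferred


@dataclass
class SyntheticSpec:
    """Parameters of the generative model (defaults = genome-scale study
    conditions; lengths are coding codons excluding start and stop)."""

    n_genes: int = 4870
    length_log_mean: float = math.log(420.0)
    length_log_sd: float = 0.6
    min_length_codons: int = 101
    max_length_codons: int = 3000
    gc3_range: tuple[float, float] = (0.20, 0.95)
    selection_mean: float = 0.7
    selection_strength: float | None = None  # fixed s, overrides the draw
    selected_fraction: float = 1.0  # share of genes carrying the fixed s; rest get s = 0
    preferred_codons: dict[str, str] = field(default_factory=default_preferred_codons)
    amino_acid_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_FREQUENCIES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        code = standard_code()
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.min_length_codons < 101:
            # 101 coding codons + start + stop = 309 nt; anything shorter
            # than 303 nt cannot survive the strict >300 nt filter
            raise ValueError("min_length_codons must be >= 101 to pass QC filtering")
        lo, hi = self.gc3_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("gc3_range must be an increasing pair within [0, 1]")
        if not 0.0 < self.selected_fraction <= 1.0:
            raise ValueError("selected_fraction must lie in (0, 1]")
        for aa, codon in self.preferred_codons.items():
            if codon not in code.families[aa]:
                raise ValueError(f"preferred codon {codon} is not a synonym of {aa}")


def _family_probs(
    fam: tuple[str, ...], gc3: float, s: float, preferred: str | None
) -> np.ndarray:
    tb = {"G": gc3 / 2, "C": gc3 / 2, "A": (1 - gc3) / 2, "T": (1 - gc3) / 2}
    w = np.array([tb[c[2]] for c in fam], dtype=float)
    if preferred is not None and s > 0:
        w[fam.index(preferred)] *= math.exp(s)
    total = w.sum()
    if total == 0:  # gc3 exactly 0/1 with a family of only G/C (or A/T) ends
        w = np.ones(len(fam))
        total = float(len(fam))
    return w / total


def generate_genes(
    spec: SyntheticSpec, code: GeneticCode | None = None
) -> tuple[list[CdsRecord], pd.DataFrame]:
    """Draw the synthetic gene set.

    Returns the records plus a ground-truth table (per-gene GC3 target,
    selection strength, length) whose attrs carry the planted
    preferred-codon map.
    """
    code = code or standard_code()
    rng = np.random.default_rng(spec.seed)
    aas = list(spec.amino_acid_frequencies)
    freqs = np.array([spec.amino_acid_frequencies[a] for a in aas], dtype=float)
    freqs = freqs / freqs.sum()
    stops = tuple(sorted(code.stop_codons))

    lengths = np.exp(
        rng.normal(spec.length_log_mean, spec.length_log_sd, spec.n_genes)
    )
    lengths = np.clip(
        np.rint(lengths), spec.min_length_codons, spec.max_length_codons
    ).astype(int)
    gc3s = rng.uniform(*spec.gc3_range, spec.n_genes)
    if spec.selection_strength is not None:
        # planted-selection mixture: a chosen share of "highly expressed"
        # genes carries the tilt, the remainder is neutral
        strengths = np.zeros(spec.n_genes)
        n_sel = max(1, int(round(spec.selected_fraction * spec.n_genes)))
        chosen = rng.choice(spec.n_genes, size=min(n_sel, spec.n_genes), replace=False)
        strengths[chosen] = float(spec.selection_strength)
    else:
        strengths = rng.exponential(spec.selection_mean, spec.n_genes)

    records: list[CdsRecord] = []
    rows = []
    width = len(str(spec.n_genes))
    for i in range(spec.n_genes):
        L, gc3, s = int(lengths[i]), float(gc3s[i]), float(strengths[i])
        aa_seq = rng.choice(len(aas), size=L, p=freqs)
        codons = np.empty(L, dtype=object)
        for ai, aa in enumerate(aas):
            idx = np.flatnonzero(aa_seq == ai)
            if idx.size == 0:
                continue
            fam = code.families[aa]
            if len(fam) == 1:
                codons[idx] = fam[0]
                continue
            p = _family_probs(fam, gc3, s, spec.preferred_codons.get(aa))
            codons[idx] = rng.choice(np.array(fam, dtype=object), size=idx.size, p=p)
        stop = stops[rng.choice(3, p=_family_probs(stops, gc3, 0.0, None))]
        gid = f"synth_{i:0{width}d}"
        records.append(CdsRecord(id=gid, seq="ATG" + "".join(codons) + stop))
        rows.append(
            {"gene_id": gid, "length_codons": L, "gc3_target": gc3, "selection_s": s}
        )
    truth = pd.DataFrame(rows).set_index("gene_id")
    truth.attrs["preferred_codons"] = dict(spec.preferred_codons)
    return records, truth


def generate_neutrality_set(
    n: int,
    relation: tuple[float, float, float],
    seed: int = 0,
    length_codons: int = 300,
) -> tuple[list[CdsRecord], pd.DataFrame]:
    """Genes whose (GC3, GC12) pairs follow a planted linear relation.

    Codons are assembled from a position-controllable pool: positions 1-2
    are either ``GG`` or ``AA`` and position 3 either ``G`` or ``A``, with
    deterministic per-gene counts ``round(target * length)``, so realized
    compositions hit their targets up to rounding. GC3 targets are spread
    evenly over [0.05, 0.95]; each gene's GC12 target is
    ``intercept + slope * gc3 + Normal(0, noise_sd)``. With zero noise and
    slope 1 the construction collapses to the two-codon {GGG, AAA} pool
    and the fitted slope is exactly 1 (the shared ATG start shifts both
    axes by a constant, leaving the slope untouched).

    Raises
    ------
    ValueError
        If the noise-free relation leaves [0.05, 0.95] anywhere on the
        GC3 grid (infeasible composition).
    """
    slope, intercept, noise_sd = relation
    if n < 3:
        raise ValueError("need at least 3 genes")
    rng = np.random.default_rng(seed)
    gc3_targets = np.linspace(0.05, 0.95, n)
    gc12_clean = intercept + slope * gc3_targets
    if gc12_clean.min() < 0.05 or gc12_clean.max() > 0.95:
        raise ValueError("relation drives GC12 outside [0.05, 0.95]; infeasible")
    gc12_targets = np.clip(gc12_clean + rng.normal(0, noise_sd, n), 0.0, 1.0)

    L = length_codons
    records, rows = [], []
    width = len(str(n))
    for i in range(n):
        n12 = int(round(gc12_targets[i] * L))
        n3 = int(round(gc3_targets[i] * L))
        pos12 = ["GG"] * n12 + ["AA"] * (L - n12)
        pos3 = ["G"] * n3 + ["A"] * (L - n3)
        body = "".join(a + b for a, b in zip(pos12, pos3))
        gid = f"neut_{i:0{width}d}"
        records.append(CdsRecord(id=gid, seq="ATG" + body + "TAA"))
        rows.append(
            {
                "gene_id": gid,
                "gc3_target": gc3_targets[i],
                "gc12_target": gc12_targets[i],
            }
        )
    return records, pd.DataFrame(rows).set_index("gene_id")
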