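"""ENC-plot analytics and the GC12-on-GC3 neutrality regression.

The ENC plot compares each gene's observed effective number of codons with
the value expected if composition (GC3s) alone drove codon choice:

    ENC_exp(s) = 2 + s + 29 / (s^2 + (1 - s)^2)

where ``s`` is GC3s. Genes sitting below this null dome are more biased
than mutation pressure can explain. The gap is summarized per gene by the
ENC ratio ``(ENC_exp - ENC_obs) / ENC_exp``; its frequency distribution
(0.1-wide bins) shows how far the genome departs from the null.

The neutrality plot regresses GC12 on GC3 across genes. A slope of 1 means
third-position composition drifts with the rest of the codon (pure
mutational neutrality); a slope of 0 means third positions vary while
positions 1-2 are held still (selective constraint). The fitted slope is
reported as the mutational share, 1 - slope as the selection share,
without endorsing a strict causal reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


def enc_expected(s: float) -> float:
    """Null-model (mutation-only) ENC at synonymous GC content ``s``.

    The denominator is Wright's ``s^2 + (1-s)^2``; the dome peaks at 60.5
    for s = 0.5 and falls to 31 / 32 at the pure-AT / pure-GC extremes.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def enc_ratio(enc_obs: float, s: float) -> float:
    """(expected - observed) / expected; positive below the null curve."""
    if math.isnan(enc_obs):
        return math.nan
    exp = enc_expected(s)
    return (exp - enc_obs) / exp


@dataclass
class EncRatioDistribution:
    """Histogram of per-gene ENC ratios on fixed-width, half-open bins."""

    bin_edges: np.ndarray
    bin_counts: np.ndarray
    ratios: dict[str, float]

    @property
    def modal_bin(self) -> tuple[float, float]:
        i = int(np.argmax(self.bin_counts))
        return float(self.bin_edges[i]), float(self.bin_edges[i + 1])


def enc_ratio_histogram(
    ratios: dict[str, float] | list[float], bin_width: float = 0.1
) -> EncRatioDistribution:
    """Bin defined ENC ratios into [m*w, (m+1)*w) bins spanning the data.

    Bins are left-closed / right-open and aligned to multiples of
    ``bin_width``; a value landing exactly on the top edge opens one more
    bin, so every defined ratio is counted exactly once.
    """
    if not isinstance(ratios, dict):
        ratios = {str(i): r for i, r in enumerate(ratios)}
    defined = {g: r for g, r in ratios.items() if not math.isnan(r)}
    if not defined:
        raise ValueError("no defined ENC ratios to bin")
    vals = np.array(list(defined.values()))
    lo = math.floor(vals.min() / bin_width)
    hi = math.floor(vals.max() / bin_width) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    idx = np.floor(vals / bin_width).astype(int) - lo
    counts = np.bincount(idx, minlength=len(edges) - 1)
    return EncRatioDistribution(bin_edges=edges, bin_counts=counts, ratios=defined)


@dataclass
class NeutralityFit:
    """OLS fit of GC12 on GC3 with its Pearson correlation."""

    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_value: float
    n_genes: int

    @property
    def mutation_share(self) -> float:
        return self.slope

    @property
    def selection_share(self) -> float:
        return 1.0 - self.slope

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("quantity\tvalue\n")
            for k in (
                "slope", "intercept", "pearson_r", "r_squared", "p_value",
                "n_genes", "mutation_share", "selection_share",
            ):
                fh.write(f"{k}\t{getattr(self, k)}\n")


def neutrality_fit(points: list[tuple[float, float]]) -> NeutralityFit:
    """Ordinary least squares of GC12 (y) on GC3 (x) over genes.

    Pairs containing NaN are dropped; at least three complete pairs with
    non-degenerate x-variance are required. The p-value is the two-sided
    t-test on the Pearson correlation.
    """
    arr = np.asarray(points, dtype=float)
    arr = arr[~np.isnan(arr).any(axis=1)]
    if len(arr) < 3:
        raise ValueError("need at least 3 complete (gc3, gc12) points")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("GC3 has zero variance; regression undefined")
    res = stats.linregress(x, y)
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n_genes=len(arr),
    )
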