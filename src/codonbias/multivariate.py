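"""Correspondence analysis of the genes x codons RSCU matrix, and the
correlation structure of axis coordinates with the per-gene indices.

Correspondence analysis (CA) is the standard ordination for codon usage:
it decomposes the chi-square-standardized residuals of the table into
orthogonal axes ordered by explained inertia, placing genes (rows) and
codons (columns) in a common space. The input here is the per-gene RSCU
matrix over the 59 synonymous codons (stops, Met and Trp excluded), the
variant that removes amino-acid-composition effects before ordination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .bias_indices import CodonCountTable, rscu
from .genetic_code import GeneticCode, standard_code


@dataclass
class RscuMatrix:
    """Genes x 59-codon RSCU values plus the per-gene imputation flags."""

    values: pd.DataFrame          # rows: gene ids, columns: 59 codons
    imputed: pd.DataFrame         # same shape, True where family was absent

    @property
    def n_genes(self) -> int:
        return len(self.values)


def build_rscu_matrix(
    genes: dict[str, CodonCountTable] | list[CodonCountTable],
    code: GeneticCode | None = None,
) -> RscuMatrix:
    """Per-gene RSCU over the 59 synonymous codons.

    Families absent from a gene would yield undefined RSCU; their codons
    are imputed at the neutral value 1.0 (and flagged) so short genes need
    not be dropped. Observed families keep their exact RSCU, so family
    sums remain equal to family sizes.
    """
    code = code or standard_code()
    if not isinstance(genes, dict):
        genes = {f"gene_{i}": t for i, t in enumerate(genes)}
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for an RSCU matrix")
    cols = list(code.synonymous_codons)
    rows, flags = [], []
    for gid, table in genes.items():
        r = rscu(table, code).as_series().reindex(cols)
        flags.append(r.isna())
        rows.append(r.fillna(1.0).rename(gid))
    values = pd.DataFrame(rows)
    imputed = pd.DataFrame([f.rename(g) for f, g in zip(flags, values.index)])
    return RscuMatrix(values=values, imputed=imputed)


@dataclass
class CoaResult:
    """Principal coordinates and inertia decomposition of a CA."""

    row_coordinates: pd.DataFrame      # genes x Axis1..A
    column_coordinates: pd.DataFrame   # codons x Axis1..A
    inertia: np.ndarray                # per retained axis
    inertia_share: np.ndarray
    total_inertia: float
    rank: int


def correspondence_analysis(
    matrix: RscuMatrix | pd.DataFrame, n_axes: int = 4
) -> CoaResult:
    """Classical (chi-square metric) correspondence analysis.

    Row and column masses come from the grand total; the standardized
    residual matrix ``(P - r c') / sqrt(r c')`` is decomposed by SVD and
    principal coordinates are returned for the leading ``n_axes`` axes.
    Axis signs are fixed by making the column with the largest absolute
    loading positive on each axis. All-zero columns (codons never used)
    are dropped before the decomposition.
    """
    df = matrix.values if isinstance(matrix, RscuMatrix) else matrix
    X = df.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("CA requires a non-negative matrix")
    keep = X.sum(axis=0) > 0
    X = X[:, keep]
    cols = df.columns[keep]

    total = X.sum()
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    S = (P - E) / np.sqrt(E)
    total_inertia = float((S * S).sum())

    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    max_rank = min(X.shape[0] - 1, X.shape[1] - 1)
    tol = max(X.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    rank = int(min(np.sum(sv > max(tol, 1e-12)), max_rank))
    a = min(n_axes, rank) if rank else 0

    row = (U[:, :a] * sv[:a]) / np.sqrt(r)[:, None] if a else np.zeros((len(r), 0))
    col = (Vt[:a].T * sv[:a]) / np.sqrt(c)[:, None] if a else np.zeros((len(c), 0))
    for k in range(a):
        j = int(np.argmax(np.abs(col[:, k])))
        if col[j, k] < 0:
            col[:, k] *= -1.0
            row[:, k] *= -1.0

    axes = [f"Axis{i + 1}" for i in range(a)]
    inertia = sv[:a] ** 2
    share = inertia / total_inertia if total_inertia > 0 else np.zeros(a)
    return CoaResult(
        row_coordinates=pd.DataFrame(row, index=df.index, columns=axes),
        column_coordinates=pd.DataFrame(col, index=cols, columns=axes),
        inertia=inertia,
        inertia_share=share,
        total_inertia=total_inertia,
        rank=rank,
    )


@dataclass
class CorrelationReport:
    """Pairwise correlation matrix over indices and CA axes."""

    coefficients: pd.DataFrame
    p_values: pd.DataFrame
    method: str

    def render(self) -> pd.DataFrame:
        """Coefficients annotated with significance stars
        (** p < 0.01, * p < 0.05)."""
        def fmt(c, p):
            if math.isnan(c):
                return "NA"
            star = "**" if p < 0.01 else ("*" if p < 0.05 else "")
            return f"{c:.3f} {star}".rstrip()

        out = self.coefficients.copy().astype(object)
        for i in out.index:
            for j in out.columns:
                out.loc[i, j] = fmt(
                    self.coefficients.loc[i, j], self.p_values.loc[i, j]
                )
        return out


#: default profile columns entering the correlation report
CORRELATION_COLUMNS = (
    "length_codons", "gc", "gc1", "gc2", "gc3", "gc3s",
    "a3s", "t3s", "c3s", "g3s", "gravy", "aromo", "enc", "cai",
)


def correlation_report(
    profiles: pd.DataFrame,
    coa: CoaResult | None = None,
    method: str = "spearman",
    columns: tuple[str, ...] = CORRELATION_COLUMNS,
) -> CorrelationReport:
    """Pairwise correlations (Spearman by default, Pearson by flag) among
    gene indices and, if given, CA axis coordinates.

    Pairs with undefined entries are dropped pairwise; a constant column
    yields NaN coefficients against everything (flagged as NA in the
    rendered table). P-values are two-sided.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    data = profiles[[c for c in columns if c in profiles.columns]].copy()
    if coa is not None:
        data = data.join(coa.row_coordinates)
    names = list(data.columns)
    coef = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pval = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for x, y in combinations(names, 2):
        pair = data[[x, y]].dropna()
        if len(pair) < 3 or pair[x].nunique() < 2 or pair[y].nunique() < 2:
            c, p = math.nan, math.nan
        elif method == "spearman":
            c, p = stats.spearmanr(pair[x], pair[y])
        else:
            c, p = stats.pearsonr(pair[x], pair[y])
        coef.loc[x, y] = coef.loc[y, x] = c
        pval.loc[x, y] = pval.loc[y, x] = p
    return CorrelationReport(coefficients=coef, p_values=pval, method=method)
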