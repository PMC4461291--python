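"""Correspondence analysis (CA) of the gene x codon RSCU matrix.

CA decomposes a non-negative table into orthogonal axes ranked by the
fraction of total inertia (chi-squared-like variance) they explain: the
table is scaled to proportions, row and column masses computed, and the
standardized residual matrix

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}

is factored by SVD.  Gene (row) and codon (column) coordinates are
reported in principal coordinates; the inertia of axis k is sigma_k^2.

Run on the 59 informative codons, the residual matrix carries at most
41 = 59 - 18 non-trivial axes because RSCU values are constrained to sum
to the family size within each of the 18 degenerate families.

A gene that never uses some family has no RSCU there; such cells are
imputed with the family-neutral value 1.0 (and tallied) so the table is
complete and non-negative.  Axis signs are arbitrary under SVD; axis 1 is
normalised to correlate non-negatively with GC3s when composition data
are supplied, other axes by the sign of their largest-magnitude codon
loading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cds_io import CodonCounts
from .genetic_code import GeneticCode, standard_code
from .indices import rscu

__all__ = ["CoaResult", "rscu_matrix", "correspondence_analysis", "axis_correlations"]


@dataclass
class CoaResult:
    """CA coordinates and inertia decomposition.

    ``gene_coords`` and ``codon_coords`` hold principal coordinates for the
    retained axes (columns ``axis1..axisK``); ``inertia_fractions`` spans
    *all* axes and sums to 1 (0 for a rank-0 residual).
    """

    gene_coords: pd.DataFrame
    codon_coords: pd.DataFrame
    inertia_fractions: np.ndarray
    #: singular values of the standardized residual matrix, all axes
    singular_values: np.ndarray
    n_imputed: int

    @property
    def n_axes(self) -> int:
        return self.gene_coords.shape[1]

    def retained_inertia(self) -> np.ndarray:
        return self.inertia_fractions[: self.n_axes]


def rscu_matrix(
    counts_list: list[CodonCounts],
    code: GeneticCode | None = None,
) -> tuple[pd.DataFrame, int]:
    """Per-gene RSCU over the 59 informative codons, NaN-imputed with 1.0.

    Returns the complete matrix and the number of imputed cells.
    """
    code = code or standard_code()
    rows = [rscu(cc, code, include_stops=False) for cc in counts_list]
    mat = pd.DataFrame(rows)
    mat = mat[[c for c in code.informative_codons]]
    n_imputed = int(mat.isna().sum().sum())
    return mat.fillna(1.0), n_imputed


def correspondence_analysis(
    table: pd.DataFrame,
    n_axes: int = 4,
    n_imputed: int = 0,
) -> CoaResult:
    """Classic CA of a non-negative genes x codons table.

    Requires >= 3 rows.  If all rows are proportional (rank-0 residual) all
    coordinates and inertia are zero.
    """
    if len(table) < 3:
        raise ValueError("need >= 3 genes")
    n = table.to_numpy(dtype=float)
    if (n < 0).any() or not np.isfinite(n).all():
        raise ValueError("CA table must be non-negative and complete")
    p = n / n.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise ValueError("CA table has an all-zero row or column")
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sig, vt = np.linalg.svd(s, full_matrices=False)
    total_inertia = float((sig**2).sum())
    k = min(n_axes, len(sig))
    if total_inertia <= 1e-14:
        frac = np.zeros(len(sig))
        row_pc = np.zeros((len(r), k))
        col_pc = np.zeros((len(c), k))
    else:
        frac = sig**2 / total_inertia
        row_pc = (u[:, :k] * sig[:k]) / np.sqrt(r)[:, None]
        col_pc = (vt.T[:, :k] * sig[:k]) / np.sqrt(c)[:, None]
        # deterministic sign: largest |codon loading| positive per axis
        for j in range(k):
            lead = np.argmax(np.abs(col_pc[:, j]))
            if col_pc[lead, j] < 0:
                col_pc[:, j] *= -1
                row_pc[:, j] *= -1
    axes = [f"axis{i + 1}" for i in range(k)]
    return CoaResult(
        gene_coords=pd.DataFrame(row_pc, index=table.index, columns=axes),
        codon_coords=pd.DataFrame(col_pc, index=table.columns, columns=axes),
        inertia_fractions=frac,
        singular_values=sig,
        n_imputed=n_imputed,
    )


def axis_correlations(
    coa: CoaResult,
    per_gene: pd.DataFrame,
    metrics: tuple[str, ...] = ("cai", "enc", "gc3s"),
) -> tuple[pd.DataFrame, pd.DataFrame, CoaResult]:
    """Spearman correlations of CA axes with per-gene indices.

    ``per_gene`` carries the metric columns indexed by gene id.  Axis 1 is
    sign-normalised to correlate non-negatively with GC3s first (flipping a
    CA axis is a pure relabelling).  Returns ``(rho, p, coa)`` where the
    returned result has the normalised signs.
    """
    common = coa.gene_coords.index.intersection(per_gene.index)
    coords = coa.gene_coords.loc[common]
    meta = per_gene.loc[common]
    if "gc3s" in meta.columns and coords.shape[1] >= 1:
        pair = pd.concat([coords["axis1"], meta["gc3s"]], axis=1).dropna()
        if len(pair) >= 3 and pair["gc3s"].nunique() > 1:
            rho1, _ = stats.spearmanr(pair["axis1"], pair["gc3s"])
            if rho1 < 0:
                coords = coords.copy()
                coords["axis1"] *= -1
                codon_coords = coa.codon_coords.copy()
                codon_coords["axis1"] *= -1
                coa = CoaResult(
                    gene_coords=coa.gene_coords.assign(
                        axis1=-coa.gene_coords["axis1"]
                    ),
                    codon_coords=codon_coords,
                    inertia_fractions=coa.inertia_fractions,
                    singular_values=coa.singular_values,
                    n_imputed=coa.n_imputed,
                )
    rho = pd.DataFrame(index=coords.columns, columns=list(metrics), dtype=float)
    pval = rho.copy()
    for axis in coords.columns:
        for m in metrics:
            pair = pd.concat([coords[axis], meta[m]], axis=1).dropna()
            if len(pair) < 3 or pair[m].nunique() == 1:
                continue
            r, p = stats.spearmanr(pair[axis], pair[m])
            rho.loc[axis, m] = r
            pval.loc[axis, m] = p
    return rho, pval, coa
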