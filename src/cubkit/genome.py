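"""Genome-level inference: optimal/rare codons, neutrality regression,
correlation structure, group tests and inter-genome clustering.

Optimal codons are called by contrasting codon usage between the genes in
the upper and lower tails of the CAI distribution (high- vs low-expression
proxies).  For each codon of a degenerate family a 2x2 table — this codon
vs the rest of its family, high pool vs low pool — is tested with Pearson's
chi-squared (no continuity correction); a codon is *optimal* when its
family-conditional frequency is significantly higher in the high pool
(p < 0.05, flagged "*" below 0.01 and "@" between 0.01 and 0.05).  Codons
with genome-wide RSCU > 1 are *preferred*; RSCU < 0.1 marks *rare* codons.

The neutrality plot regresses P12 (mean GC of codon positions 1 and 2) on
P3: a slope near 1 is compatible with undirected mutation pressure acting
equally on all positions, a slope near 0 with directional pressure or
selection constraining positions 1-2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .cds_io import CodonCounts
from .genetic_code import GeneticCode, standard_code
from .indices import rscu

__all__ = [
    "select_expression_tails",
    "call_optimal_codons",
    "optimal_codon_summary",
    "NeutralityFit",
    "neutrality_fit",
    "correlation_matrix",
    "group_comparison",
    "cluster_species",
    "linkage_to_newick",
]


def select_expression_tails(
    indices: pd.DataFrame, fraction: float = 0.05
) -> tuple[list[str], list[str]]:
    """Gene ids in the upper and lower ``fraction`` tails of CAI.

    Each tail holds ``ceil(fraction * N)`` genes; ties at the boundary are
    broken by gene id order so the selection is reproducible.  Requires at
    least 40 genes so each 5% tail holds at least two.
    """
    cai_col = indices["cai"].dropna()
    n = len(cai_col)
    if n < 40:
        raise ValueError(f"need >= 40 genes with defined CAI, got {n}")
    k = math.ceil(fraction * n)
    df = cai_col.rename_axis("gene_id").reset_index()
    high = df.sort_values(["cai", "gene_id"], ascending=[False, True])
    low = df.sort_values(["cai", "gene_id"], ascending=[True, True])
    return list(high["gene_id"].head(k)), list(low["gene_id"].head(k))


def _chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction on [[a,b],[c,d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return math.nan, math.nan
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def call_optimal_codons(
    high_counts: CodonCounts,
    low_counts: CodonCounts,
    genome_counts: CodonCounts,
    code: GeneticCode | None = None,
    alpha: float = 0.05,
    strict_alpha: float = 0.01,
    rare_threshold: float = 0.1,
    construction: str = "per_codon",
) -> pd.DataFrame:
    """Per-codon optimal/preferred/rare classification table.

    Parameters
    ----------
    high_counts, low_counts
        Pooled codon counts of the high- and low-CAI gene sets.
    genome_counts
        Pooled counts of the whole genome (defines preferred and rare flags).
    construction
        ``"per_codon"`` (default): 2x2 codon-vs-rest-of-family tables, the
        only construction under which "frequency significantly higher"
        aligns with RSCU.  ``"family"``: one k x 2 whole-family contingency
        test shared by all codons of the family.

    Returns a DataFrame indexed by the 59 informative codons with columns
    ``amino_acid, third_base, rscu_genome, rscu_high, rscu_low, chi2, p,
    preferred, optimal_class, optimal, rare, testable``.
    """
    code = code or standard_code()
    if high_counts.total() == 0 or low_counts.total() == 0:
        raise ValueError("high and low pools must both be non-empty")
    rscu_genome = rscu(genome_counts, code, include_stops=False)
    rscu_high = rscu(high_counts, code, include_stops=False)
    rscu_low = rscu(low_counts, code, include_stops=False)

    rows = []
    for aa, codons in sorted(code.degenerate_families.items()):
        fam_high = sum(high_counts[c] for c in codons)
        fam_low = sum(low_counts[c] for c in codons)
        if construction == "family":
            table = np.array(
                [[high_counts[c] for c in codons], [low_counts[c] for c in codons]],
                dtype=float,
            )
            keep = table.sum(axis=0) > 0
            if keep.sum() >= 2 and table.sum(axis=1).min() > 0:
                fam_stat, fam_p, _, _ = stats.chi2_contingency(table[:, keep])
            else:
                fam_stat = fam_p = math.nan
        for c in codons:
            if construction == "per_codon":
                stat, p = _chi2_2x2(
                    high_counts[c],
                    fam_high - high_counts[c],
                    low_counts[c],
                    fam_low - low_counts[c],
                )
            else:
                stat, p = fam_stat, fam_p
            testable = not math.isnan(p) if isinstance(p, float) else True
            higher = (
                testable
                and not math.isnan(rscu_high[c])
                and not math.isnan(rscu_low[c])
                and rscu_high[c] > rscu_low[c]
            )
            if testable and higher and p < strict_alpha:
                klass = "*"
            elif testable and higher and p < alpha:
                klass = "@"
            else:
                klass = ""
            rg = rscu_genome[c]
            rows.append(
                {
                    "codon": c,
                    "amino_acid": aa,
                    "third_base": code.third_base(c),
                    "rscu_genome": rg,
                    "rscu_high": rscu_high[c],
                    "rscu_low": rscu_low[c],
                    "chi2": stat,
                    "p": p,
                    "preferred": bool(rg > 1) if not math.isnan(rg) else False,
                    "optimal_class": klass,
                    "optimal": klass != "",
                    "rare": bool(rg < rare_threshold) if not math.isnan(rg) else False,
                    "testable": testable,
                }
            )
    df = pd.DataFrame(rows).set_index("codon")
    return df.loc[[c for c in code.informative_codons]]


def optimal_codon_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Third-base composition counts of preferred / optimal / rare codons.

    Rows: codon categories; columns: total, A/U, G/C and per-base counts —
    a per-genome summary of third-position leanings.
    """
    u = table.copy()
    u["third"] = u["third_base"].replace({"T": "U"})
    out = {}
    for kind in ("preferred", "optimal", "rare"):
        sel = u[u[kind]]
        counts = sel["third"].value_counts()
        out[kind] = {
            "total": int(len(sel)),
            "AU": int(counts.get("A", 0) + counts.get("U", 0)),
            "GC": int(counts.get("G", 0) + counts.get("C", 0)),
            "A": int(counts.get("A", 0)),
            "U": int(counts.get("U", 0)),
            "G": int(counts.get("G", 0)),
            "C": int(counts.get("C", 0)),
        }
    return pd.DataFrame(out).T


@dataclass
class NeutralityFit:
    """OLS of P12 on P3 plus the Spearman association of the two."""

    slope: float
    intercept: float
    spearman_rho: float
    spearman_p: float
    n_genes: int

    @property
    def relative_neutrality(self) -> float:
        """Slope expressed as a percentage."""
        return 100.0 * self.slope


def neutrality_fit(profiles: pd.DataFrame) -> NeutralityFit:
    """Fit the neutrality regression on complete (p3, p12) pairs.

    ``profiles`` is a per-gene composition table with ``p3`` and ``p12``
    columns.  Needs >= 3 complete pairs; a zero-variance P3 yields NaN
    slope (reported missing, not zero).
    """
    pairs = profiles[["p3", "p12"]].dropna()
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need >= 3 complete (p3, p12) pairs, got {n}")
    x = pairs["p3"].to_numpy()
    y = pairs["p12"].to_numpy()
    if np.ptp(x) == 0:
        return NeutralityFit(math.nan, math.nan, math.nan, math.nan, n)
    fit = stats.linregress(x, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant y -> undefined rho, kept NaN
        rho, p = stats.spearmanr(x, y)
    return NeutralityFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        spearman_rho=float(rho),
        spearman_p=float(p),
        n_genes=n,
    )


_CORR_COLUMNS = ["gc_cds", "p1", "p2", "p12", "p3", "enc"]


def correlation_matrix(
    per_gene: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman rho and p over composition and ENc columns.

    ``per_gene`` must carry the requested columns (default
    gc_cds/p1/p2/p12/p3/enc).  Returns ``(rho, p)`` DataFrames; the
    diagonal is 1 / 0; pairs involving a constant column are NaN.
    """
    cols = columns or _CORR_COLUMNS
    if len(per_gene) < 3:
        raise ValueError("need >= 3 genes")
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            pair = per_gene[[a, b]].dropna()
            if len(pair) < 3 or pair[a].nunique() == 1 or pair[b].nunique() == 1:
                r = p = math.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, p = stats.spearmanr(pair[a], pair[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


def group_comparison(
    per_gene_by_species: dict[str, pd.DataFrame],
    group_a: list[str],
    metrics: tuple[str, ...] = ("cai", "enc"),
) -> pd.DataFrame:
    """One-way ANOVA across species and Welch's t between two species groups.

    ``per_gene_by_species`` maps species label -> per-gene indices table;
    ``group_a`` lists the species forming one side of the t-test (the other
    side is every remaining species).  Observations are per-gene values.

    Returns a DataFrame indexed by metric with columns
    ``anova_F, anova_p, t_stat, t_p``.
    """
    if len(per_gene_by_species) < 2:
        raise ValueError("need >= 2 species")
    rows = {}
    for metric in metrics:
        samples = {
            sp: df[metric].dropna().to_numpy()
            for sp, df in per_gene_by_species.items()
        }
        if any(len(v) < 2 for v in samples.values()):
            raise ValueError(f"every species needs >= 2 defined {metric} values")
        f_stat, f_p = stats.f_oneway(*samples.values())
        a = np.concatenate([samples[sp] for sp in group_a])
        b = np.concatenate(
            [v for sp, v in samples.items() if sp not in group_a]
        )
        if len(a) == 0 or len(b) == 0:
            raise ValueError("both t-test groups must be non-empty")
        t_stat, t_p = stats.ttest_ind(a, b, equal_var=False)
        rows[metric] = {
            "anova_F": float(f_stat),
            "anova_p": float(f_p),
            "t_stat": float(t_stat),
            "t_p": float(t_p),
        }
    return pd.DataFrame(rows).T


def cluster_species(
    rscu_by_species: pd.DataFrame,
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of genomes on Euclidean RSCU distance.

    ``rscu_by_species`` is a species x codon matrix (one row per genome,
    columns the informative codons).  Rows are processed in species-name
    order so linkage tie-breaking is deterministic.  Missing entries are
    handled pairwise-complete (rescaled Euclidean) with a warning.

    Returns ``(linkage_matrix, labels)`` in scipy linkage format.
    """
    if len(rscu_by_species) < 2:
        raise ValueError("need >= 2 genomes")
    mat = rscu_by_species.sort_index()
    labels = list(mat.index)
    x = mat.to_numpy(dtype=float)
    if np.isnan(x).any():
        warnings.warn(
            "missing RSCU entries: using pairwise-complete Euclidean distances",
            stacklevel=2,
        )
        n = len(labels)
        d = np.zeros((n, n))
        p = x.shape[1]
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~np.isnan(x[i]) & ~np.isnan(x[j])
                if not ok.any():
                    raise ValueError("a genome pair shares no observed codons")
                diff = x[i, ok] - x[j, ok]
                d[i, j] = d[j, i] = math.sqrt(np.sum(diff**2) * p / ok.sum())
        condensed = squareform(d, checks=False)
    else:
        condensed = hierarchy.distance.pdist(x, metric="euclidean")
    linkage = hierarchy.linkage(condensed, method="average")
    return linkage, labels


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage, labels)
    return str(tree).strip()
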