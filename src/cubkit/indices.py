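"""Core codon-usage indices: RSCU, CAI and Wright's effective number of codons.

RSCU (relative synonymous codon usage) is the observed count of a codon
divided by the count expected if its synonymous family were used uniformly:
``RSCU_j = count_j / (N_family / k)`` for a family of size ``k``.  Values
near 1 mean no bias; within each observed family the values sum to ``k``.

CAI (codon adaptation index) is the geometric mean, over the codons of a
gene, of each codon's relative adaptiveness ``w`` in a high-expression
reference set (``w_j = RSCU_j / max RSCU in family`` on the reference).
Single-codon amino acids (Met, Trp) and stops carry no weight.

ENc (effective number of codons) summarises overall bias irrespective of
which codons are favoured, from 20 (one codon per amino acid) to 61 (all
sense codons uniform).  Per observed family the homozygosity estimate is
``F = (n * sum(p_i^2) - 1) / (n - 1)`` and

    ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

with ``Fk`` the mean F over families of degeneracy ``k``.  Finite samples
can push the raw value outside [20, 61]; the reported value is clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .cds_io import CodonCounts
from .composition import gc3s
from .genetic_code import GeneticCode, standard_code

__all__ = [
    "rscu",
    "rscu_table",
    "ReferenceWeights",
    "cai_weights",
    "load_reference_weights",
    "cai",
    "enc",
    "expected_enc",
    "CubIndices",
    "indices_table",
]

#: Pseudocount added to zero-count reference codons before computing
#: relative adaptiveness, so no weight is exactly zero (classic CAI practice).
CAI_PSEUDOCOUNT = 0.5


def rscu(
    counts: CodonCounts,
    code: GeneticCode | None = None,
    include_stops: bool = True,
) -> pd.Series:
    """RSCU per codon for one gene or a pooled genome.

    Returns a Series indexed by codon.  Degenerate families contribute
    their 59 informative codons; the stop family (treated as a three-codon
    family) is included unless ``include_stops=False``.  Single-codon amino
    acids are reported as 1.0 when observed.  Codons of families with zero
    total count are NaN (unobserved, not unbiased).
    """
    code = code or standard_code()
    values: dict[str, float] = {}
    families: list[tuple[str, ...]] = list(code.families.values())
    if include_stops:
        families.append(tuple(sorted(code.stop_codons)))
    for codons in families:
        k = len(codons)
        total = sum(counts[c] for c in codons)
        for c in codons:
            if k == 1:
                values[c] = 1.0 if total > 0 else math.nan
            elif total == 0:
                values[c] = math.nan
            else:
                values[c] = counts[c] * k / total
    order = [c for c in _codon_order(code, include_stops)]
    return pd.Series(values, name=counts.gene_id).reindex(order)


def _codon_order(code: GeneticCode, include_stops: bool) -> list[str]:
    from .genetic_code import ALL_CODONS

    keep = set(code.sense_codons)
    if include_stops:
        keep |= code.stop_codons
    return [c for c in ALL_CODONS if c in keep]


def rscu_table(
    genomes: dict[str, CodonCounts],
    code: GeneticCode | None = None,
    include_stops: bool = True,
) -> pd.DataFrame:
    """Pooled-genome RSCU, one column per genome, with amino-acid annotation."""
    code = code or standard_code()
    cols = {label: rscu(cc, code, include_stops) for label, cc in genomes.items()}
    df = pd.DataFrame(cols)
    aa = {c: code.codon_to_aa.get(c, "*") for c in df.index}
    df.insert(0, "amino_acid", pd.Series(aa))
    return df


@dataclass
class ReferenceWeights:
    """Relative adaptiveness ``w`` per codon, from a high-expression reference.

    The maximal codon of every family has ``w == 1``; Met, Trp and stop
    codons carry no weight.
    """

    weights: dict[str, float]
    provenance: str = ""

    def __getitem__(self, codon: str) -> float:
        return self.weights[codon]

    def __contains__(self, codon: str) -> bool:
        return codon in self.weights


def cai_weights(
    reference_counts: CodonCounts, code: GeneticCode | None = None
) -> ReferenceWeights:
    """Relative adaptiveness from pooled reference-set codon counts.

    Zero-count codons within an observed family receive a 0.5 pseudocount
    before RSCU so every weight is positive.  A family entirely absent from
    the reference cannot be weighted and raises a ValueError naming the
    missing families.
    """
    code = code or standard_code()
    missing = [
        aa
        for aa, codons in code.degenerate_families.items()
        if sum(reference_counts[c] for c in codons) == 0
    ]
    if missing:
        raise ValueError(
            "reference set has no codons for families: " + ", ".join(sorted(missing))
        )
    weights: dict[str, float] = {}
    for codons in code.degenerate_families.values():
        adj = {
            c: (reference_counts[c] if reference_counts[c] > 0 else CAI_PSEUDOCOUNT)
            for c in codons
        }
        total = sum(adj.values())
        k = len(codons)
        rscu_vals = {c: adj[c] * k / total for c in codons}
        top = max(rscu_vals.values())
        for c in codons:
            weights[c] = rscu_vals[c] / top
    return ReferenceWeights(
        weights=weights, provenance=f"computed from {reference_counts.gene_id!r}"
    )


def load_reference_weights(name: str = "yeast") -> ReferenceWeights:
    """Load a packaged relative-adaptiveness table.

    ``"yeast"`` is the S. cerevisiae table of Sharp & Li (1987), the
    reference distributed with CodonW (here taken from the seqinr ``caitab``
    dataset).  Met, Trp and stop codons are dropped from the weight set.
    """
    if name != "yeast":
        raise ValueError(f"unknown packaged reference {name!r}")
    code = standard_code()
    path = resources.files("cubkit.data") / "scerevisiae_cai_weights.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    informative = set(code.informative_codons)
    weights = {
        row.codon: float(row.w)
        for row in df.itertuples()
        if row.codon in informative
    }
    return ReferenceWeights(
        weights=weights,
        provenance="S. cerevisiae relative adaptiveness (Sharp & Li 1987)",
    )


def cai(counts: CodonCounts, weights: ReferenceWeights) -> float:
    """Codon adaptation index: geometric mean of ``w`` over weighted codons.

    ``CAI = exp( sum_j count_j * ln(w_j) / sum_j count_j )`` over codons
    that carry a weight (Met, Trp and stops are excluded).  NaN if the gene
    has no weighted codons.  Weights of exactly zero are floored at 0.01
    so a single absent-in-reference codon cannot annihilate the index.
    """
    log_sum = 0.0
    n = 0
    for codon, count in counts.counts.items():
        if codon in weights:
            w = max(weights[codon], 0.01)
            log_sum += count * math.log(w)
            n += count
    return math.exp(log_sum / n) if n else math.nan


def enc(counts: CodonCounts, code: GeneticCode | None = None) -> float:
    """Wright's effective number of codons, clipped to [20, 61].

    Families with ``n <= 1`` or ``F == 0`` are dropped from their
    degeneracy-class mean.  If no threefold family is measurable (Ile
    absent), its contribution ``1/F3`` is estimated as the 9:5-weighted
    mean of ``1/F2`` and ``1/F4``.  If the two-, four- or sixfold class has
    no measurable family the index is undefined (NaN).
    """
    code = code or standard_code()
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for codons in code.degenerate_families.values():
        n = sum(counts[c] for c in codons)
        if n <= 1:
            continue
        sum_p2 = sum((counts[c] / n) ** 2 for c in codons)
        f = (n * sum_p2 - 1) / (n - 1)
        if f > 0:
            f_by_class[len(codons)].append(f)
    means = {k: float(np.mean(v)) if v else math.nan for k, v in f_by_class.items()}
    if any(math.isnan(means[k]) for k in (2, 4, 6)):
        return math.nan
    inv3 = 1.0 / means[3] if not math.isnan(means[3]) else (
        (9.0 / means[2] + 5.0 / means[4]) / 14.0
    )
    raw = 2.0 + 9.0 / means[2] + inv3 + 5.0 / means[4] + 3.0 / means[6]
    return float(min(61.0, max(20.0, raw)))


def expected_enc(gc3s_value: float) -> float:
    """Expected ENc under composition alone: ``2 + s + 29/(s^2 + (1-s)^2)``."""
    s = gc3s_value
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


@dataclass
class CubIndices:
    """Per-gene index bundle: CAI, ENc and GC3s (the CodonW columns)."""

    gene_id: str
    cai: float
    enc: float
    gc3s: float
    extras: dict = field(default_factory=dict, repr=False)


def indices_table(
    counts_list: list[CodonCounts],
    weights: ReferenceWeights,
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """Per-gene CAI / ENc / GC3s table indexed by gene id."""
    code = code or standard_code()
    rows = [
        {
            "gene_id": cc.gene_id,
            "cai": cai(cc, weights),
            "enc": enc(cc, code),
            "gc3s": gc3s(cc, code),
        }
        for cc in counts_list
    ]
    return pd.DataFrame(rows).set_index("gene_id")
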