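"""Nucleotide-composition statistics per gene, with explicit exclusion rules.

The positional GC contents use different codon universes on purpose:

* ``gc_cds`` — every counted codon position, no exclusions.
* ``p1``, ``p2`` — all codons except the single-codon amino acids AUG (Met)
  and UGG (Trp), whose bases carry no synonymous signal.
* ``p3`` — additionally excludes the three stop codons and the three Ile
  codons, whose third-position substitution rates are asymmetric; this is
  the universe used for neutrality and PR2 plots.
* ``gc3s`` — third positions of degenerate sense codons only (Met, Trp and
  stops excluded, Ile INCLUDED): the synonymous-third-position GC used by
  the ENc-plot.  ``p3`` and ``gc3s`` therefore differ except on genes
  without Ile codons.

Undefined ratios (every codon excluded, or an empty denominator) propagate
as NaN, never as zero, so downstream correlations use complete pairs only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .cds_io import CodonCounts
from .genetic_code import GeneticCode, standard_code

_GC = frozenset("GC")
_ILE = frozenset({"ATT", "ATC", "ATA"})


@dataclass
class CompositionProfile:
    """Per-gene composition summary; NaN marks undefined fields."""

    gene_id: str
    gc_cds: float
    p1: float
    p2: float
    p3: float
    p12: float
    gc3s: float
    a3: float
    u3: float
    g3: float
    c3: float
    au_bias: float
    gc_bias: float

    def as_dict(self) -> dict[str, float]:
        d = self.__dict__.copy()
        return d


def _p3_universe(code: GeneticCode) -> frozenset[str]:
    """Codons whose third position enters P3 (and the PR2 base fractions)."""
    excluded = code.single_codons | code.stop_codons | _ILE
    return frozenset(c for c in code.sense_codons if c not in excluded) | frozenset()


def _fourfold_universe(code: GeneticCode) -> frozenset[str]:
    """Third positions of strictly fourfold-degenerate families."""
    out: set[str] = set()
    for codons in code.families.values():
        if len(codons) == 4:
            out.update(codons)
    return frozenset(out)


def _frac(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def positional_gc(
    counts: CodonCounts, code: GeneticCode | None = None
) -> tuple[float, float, float, float, float]:
    """GC fractions (gc_cds, p1, p2, p3, p12) under the exclusion rules above."""
    code = code or standard_code()
    if counts.total() == 0:
        raise ValueError(f"gene {counts.gene_id!r}: no codons counted")
    singles = code.single_codons
    p3_ok = _p3_universe(code)

    gc_all = n_all = 0
    gc1 = gc2 = n12 = 0
    gc3 = n3 = 0
    for codon, n in counts.counts.items():
        gc_all += n * sum(b in _GC for b in codon)
        n_all += 3 * n
        if codon not in singles:
            gc1 += n * (codon[0] in _GC)
            gc2 += n * (codon[1] in _GC)
            n12 += n
        if codon in p3_ok:
            gc3 += n * (codon[2] in _GC)
            n3 += n
    p1 = _frac(gc1, n12)
    p2 = _frac(gc2, n12)
    p3 = _frac(gc3, n3)
    p12 = (p1 + p2) / 2
    return _frac(gc_all, n_all), p1, p2, p3, p12


def gc3s(counts: CodonCounts, code: GeneticCode | None = None) -> float:
    """Third-position GC over synonymous (degenerate sense) codons."""
    code = code or standard_code()
    synonymous = frozenset(
        c for cs in code.degenerate_families.values() for c in cs
    )
    gc = n = 0
    for codon, k in counts.counts.items():
        if codon in synonymous:
            gc += k * (codon[2] in _GC)
            n += k
    return _frac(gc, n)


def base3_composition(
    counts: CodonCounts,
    code: GeneticCode | None = None,
    universe: str = "p3",
) -> tuple[float, float, float, float, float, float]:
    """Third-position base fractions (a3, u3, g3, c3) and the PR2 biases.

    Parameters
    ----------
    universe
        ``"p3"`` (default) uses the same codon set as P3 — one
        third-position universe for the neutrality and PR2 plots; or
        ``"fourfold"`` for the classic PR2 variant restricted to fourfold-
        degenerate families.

    Returns ``(a3, u3, g3, c3, au_bias, gc_bias)`` with
    ``au_bias = a3/(a3+u3)`` and ``gc_bias = g3/(g3+c3)``; a bias is NaN
    when its denominator is zero.
    """
    code = code or standard_code()
    if universe == "p3":
        ok = _p3_universe(code)
    elif universe == "fourfold":
        ok = _fourfold_universe(code)
    else:
        raise ValueError(f"unknown PR2 universe {universe!r}")
    tally = {"A": 0, "T": 0, "G": 0, "C": 0}
    for codon, n in counts.counts.items():
        if codon in ok:
            tally[codon[2]] += n
    total = sum(tally.values())
    a3 = _frac(tally["A"], total)
    u3 = _frac(tally["T"], total)
    g3 = _frac(tally["G"], total)
    c3 = _frac(tally["C"], total)
    au_bias = _frac(tally["A"], tally["A"] + tally["T"])
    gc_bias = _frac(tally["G"], tally["G"] + tally["C"])
    return a3, u3, g3, c3, au_bias, gc_bias


def composition_profile(
    counts: CodonCounts,
    code: GeneticCode | None = None,
    pr2_universe: str = "p3",
) -> CompositionProfile:
    """All composition statistics for one gene."""
    code = code or standard_code()
    gc_cds, p1, p2, p3, p12 = positional_gc(counts, code)
    a3, u3, g3, c3, au_bias, gc_bias = base3_composition(counts, code, pr2_universe)
    return CompositionProfile(
        gene_id=counts.gene_id,
        gc_cds=gc_cds,
        p1=p1,
        p2=p2,
        p3=p3,
        p12=p12,
        gc3s=gc3s(counts, code),
        a3=a3,
        u3=u3,
        g3=g3,
        c3=c3,
        au_bias=au_bias,
        gc_bias=gc_bias,
    )


def composition_table(
    counts_list: list[CodonCounts],
    code: GeneticCode | None = None,
    pr2_universe: str = "p3",
) -> pd.DataFrame:
    """Per-gene composition table (one row per gene, NaN for undefined)."""
    profiles = [composition_profile(c, code, pr2_universe) for c in counts_list]
    return pd.DataFrame([p.as_dict() for p in profiles]).set_index("gene_id")


def genome_summary(table: pd.DataFrame) -> pd.Series:
    """Genome-level means: per-gene values averaged over defined entries."""
    return table.mean(axis=0, skipna=True)
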