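"""Seeded generator of synthetic CDS sets with controllable codon-usage structure.

The generator emulates the statistical features that codon-usage analyses
assume in real genomes, so every stage of the pipeline can be exercised and
validated against planted truth without any downloads:

* multi-gene CDS sets (>= 300 bp, multiple of 3, ATG start, single terminal
  stop — generated genes pass the CDS quality filter unchanged);
* per-family codon preferences (a Dirichlet draw per genome, optionally
  tilted towards A/U- or G/C-ending codons) producing RSCU structure;
* a per-gene third-position GC drift, optionally *coupled* to first/second
  position GC so that the expected neutrality-plot slope (OLS of P12 on P3)
  equals a chosen parameter ``m``;
* an expression-tier structure: a small fraction of genes drawn from a more
  strongly biased codon distribution, making optimal-codon calling testable
  against planted truth.

Generation is codon-wise: an amino acid is drawn from the genome's
amino-acid frequency vector, then a codon from that family's preference
distribution re-weighted for the gene's third-position GC target.  Mutation
is not simulated at the nucleotide level — the analyses only see codons.

Slope coupling.  A latent drift ``delta ~ U(-w, w)`` shifts each gene's
third-position GC target.  The same delta shifts the gene's P12 target by
``c * delta`` where ``c = m * (1 + Var(e3)/Var(delta))`` and ``Var(e3)`` is
the binomial sampling variance of the realised P3 estimate; the inflation
compensates the regression-attenuation caused by sampling noise in the
regressor, so the *expected OLS slope* of P12 on P3 equals ``m``.  Both
targets are met by numerically inverting the realised-composition maps
(third-base GC as a function of the re-weighting parameter, P12 as a
function of an exponential tilt on amino-acid frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cds_io import CdsRecord
from .genetic_code import GeneticCode, standard_code

__all__ = ["SyntheticSpec", "generate_genome", "generate_biased_pair"]

# Typical eukaryotic proteome amino-acid frequencies (rounded); any vector
# may be supplied in SyntheticSpec instead.
_DEFAULT_AA_FREQS = {
    "A": 0.078, "R": 0.051, "N": 0.044, "D": 0.053, "C": 0.012,
    "Q": 0.039, "E": 0.064, "G": 0.072, "H": 0.023, "I": 0.053,
    "L": 0.096, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.068, "T": 0.056, "W": 0.011, "Y": 0.031, "V": 0.066,
}

_GC = frozenset("GC")
_ILE = frozenset({"ATT", "ATC", "ATA"})


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic genome.

    Defaults describe an AT-rich, mildly A/U-preferring genome of 2,000
    genes averaging ~1 kb — the scale and leanings of the small eukaryotic
    parasite genomes these analyses target.
    """

    n_genes: int = 2000
    seed: int = 0
    #: mean CDS length in codons (including start and stop)
    mean_codons: float = 330.0
    #: lognormal sigma of the codon-count distribution
    length_dispersion: float = 0.35
    min_length: int = 300
    aa_freqs: dict[str, float] | None = None
    #: Dirichlet concentration of per-family codon preferences (larger =
    #: closer to uniform within a family)
    family_concentration: float = 20.0
    #: direction of the genome-wide third-base preference, "AU" | "GC" | None
    base_bias: str | None = "AU"
    #: odds multiplier applied to codons ending in the favoured bases
    base_bias_odds: float = 1.5
    #: genome-wide third-position GC target (before drift)
    gc3_target: float = 0.35
    #: optional per-gene uniform gradient (lo, hi) replacing gc3_target
    gc3_gradient: tuple[float, float] | None = None
    #: expected neutrality-plot slope of P12 on P3
    m: float = 0.0
    #: half-width of the per-gene uniform third-position GC drift
    delta_half_width: float = 0.15
    #: fraction of genes in the high-expression tier (0 disables the tier)
    tier_fraction: float = 0.05
    #: third-base direction favoured by tier genes, "AU" | "GC"
    tier_bias: str = "AU"
    #: odds multiplier of the tier preference
    tier_odds: float = 4.0

    def aa_vector(self) -> dict[str, float]:
        freqs = dict(self.aa_freqs or _DEFAULT_AA_FREQS)
        total = sum(freqs.values())
        return {aa: f / total for aa, f in freqs.items()}


class _GenomeModel:
    """Precomputed arrays for fast codon-wise sampling."""

    def __init__(self, spec: SyntheticSpec, code: GeneticCode, rng: np.random.Generator):
        self.code = code
        self.aa_freqs = spec.aa_vector()
        fams = sorted(code.families.items())  # (aa, codons), name order
        self.aa_names = [aa for aa, _ in fams]
        self.q = np.array([self.aa_freqs[aa] for aa in self.aa_names])
        self.codons: list[str] = []
        self.fam_id = []
        for i, (_, codons) in enumerate(fams):
            for c in codons:
                self.codons.append(c)
                self.fam_id.append(i)
        self.fam_id = np.array(self.fam_id)
        self.n_fams = len(fams)
        self.is_gc3 = np.array([c[2] in _GC for c in self.codons], dtype=float)
        fam_sizes = np.bincount(self.fam_id, minlength=self.n_fams)
        self.n_gc = np.bincount(
            self.fam_id, weights=self.is_gc3, minlength=self.n_fams
        )
        self.n_au = fam_sizes - self.n_gc
        # mean GC fraction at codon positions 1+2, per codon
        self.gc12 = np.array(
            [((c[0] in _GC) + (c[1] in _GC)) / 2.0 for c in self.codons]
        )
        # per-genome Dirichlet preference, biased towards the chosen third base
        conc = np.full(len(self.codons), spec.family_concentration)
        self.pref = self._draw_pref(conc, spec.base_bias, spec.base_bias_odds, rng)
        if spec.tier_fraction > 0:
            self.tier_pref = self.pref * self._bias_odds(
                spec.tier_bias, spec.tier_odds
            )
        else:
            self.tier_pref = self.pref
        # membership masks for the composition universes
        self.in_p12 = np.array(
            [c not in code.single_codons for c in self.codons], dtype=float
        )
        self.in_p3 = np.array(
            [c not in code.single_codons and c not in _ILE for c in self.codons],
            dtype=float,
        )

    def _bias_odds(self, direction: str | None, odds: float) -> np.ndarray:
        w = np.ones(len(self.codons))
        if direction is None or odds == 1.0:
            return w
        if direction == "AU":
            w[self.is_gc3 == 0] = odds
        elif direction == "GC":
            w[self.is_gc3 == 1] = odds
        else:
            raise ValueError(f"unknown bias direction {direction!r}")
        return w

    def _draw_pref(
        self,
        conc: np.ndarray,
        direction: str | None,
        odds: float,
        rng: np.random.Generator,
    ) -> np.ndarray:
        alpha = conc * self._bias_odds(direction, odds)
        pref = np.empty(len(self.codons))
        for f in range(self.n_fams):
            mask = self.fam_id == f
            if mask.sum() == 1:
                pref[mask] = 1.0
            else:
                pref[mask] = rng.dirichlet(alpha[mask])
        return pref

    def codon_probs(self, s: float, pref: np.ndarray, q: np.ndarray) -> np.ndarray:
        """Per-codon sampling probabilities at third-GC weight s."""
        with np.errstate(divide="ignore", invalid="ignore"):
            w3 = np.where(
                self.is_gc3 == 1,
                s / np.maximum(self.n_gc[self.fam_id], 1e-12),
                (1.0 - s) / np.maximum(self.n_au[self.fam_id], 1e-12),
            )
        # single-codon families keep probability 1 regardless of s
        single = (self.n_gc[self.fam_id] == 0) | (self.n_au[self.fam_id] == 0)
        w = np.where(single, 1.0, pref * w3)
        z = np.bincount(self.fam_id, weights=w, minlength=self.n_fams)
        cond = w / z[self.fam_id]
        return cond * q[self.fam_id]

    # --- realised-composition maps (numerically inverted per gene) -------

    def p3_of_s(self, s_grid: np.ndarray, pref: np.ndarray) -> np.ndarray:
        """Expected P3 (GC3 over the P3 universe) as a function of s."""
        out = np.empty(len(s_grid))
        for i, s in enumerate(s_grid):
            probs = self.codon_probs(s, pref, self.q)
            w = probs * self.in_p3
            out[i] = (w * self.is_gc3).sum() / w.sum()
        return out

    def p12_of_beta(self, beta_grid: np.ndarray, s: float, pref: np.ndarray) -> np.ndarray:
        """Expected P12 as a function of the amino-acid GC12 tilt beta."""
        out = np.empty(len(beta_grid))
        base_probs = self.codon_probs(s, pref, self.q)
        # family-level mean gc12 under the within-family codon distribution
        num = np.bincount(
            self.fam_id, weights=base_probs * self.gc12, minlength=self.n_fams
        )
        den = np.bincount(self.fam_id, weights=base_probs, minlength=self.n_fams)
        fam_gc12 = num / np.maximum(den, 1e-12)
        for i, beta in enumerate(beta_grid):
            q = self.q * np.exp(beta * fam_gc12)
            q = q / q.sum()
            probs = self.codon_probs(s, pref, q)
            w = probs * self.in_p12
            out[i] = (w * self.gc12).sum() / w.sum()
        return out


def _invert_monotone(grid_x: np.ndarray, grid_y: np.ndarray, target: float) -> float:
    """x such that f(x) = target, by linear interpolation on a monotone grid."""
    if grid_y[0] > grid_y[-1]:
        grid_x, grid_y = grid_x[::-1], grid_y[::-1]
    lo, hi = grid_y[0], grid_y[-1]
    if not (lo - 1e-9 <= target <= hi + 1e-9):
        raise ValueError(
            f"composition target {target:.4f} outside feasible range "
            f"[{lo:.4f}, {hi:.4f}]"
        )
    return float(np.interp(target, grid_y, grid_x))


def generate_genome(
    spec: SyntheticSpec, code: GeneticCode | None = None
) -> tuple[list[CdsRecord], pd.DataFrame]:
    """Generate one genome and the per-gene truth table.

    Returns ``(records, truth)``; ``truth`` has one row per gene with the
    parameters actually used (tier membership, drift delta, third-GC and
    P12 targets, tilt beta, length).  Deterministic under ``spec.seed``.
    """
    code = code or standard_code()
    rng = np.random.default_rng(spec.seed)
    model = _GenomeModel(spec, code, rng)

    # gene lengths in codons (incl. start + stop), >= min_length/3
    min_codons = max(spec.min_length // 3, 3)
    mu = np.log(spec.mean_codons) - spec.length_dispersion**2 / 2
    n_codons = np.maximum(
        np.round(rng.lognormal(mu, spec.length_dispersion, spec.n_genes)).astype(int),
        min_codons,
    )

    # per-gene third-GC base target and drift
    if spec.gc3_gradient is not None:
        lo, hi = spec.gc3_gradient
        base = rng.uniform(lo, hi, spec.n_genes)
    else:
        base = np.full(spec.n_genes, spec.gc3_target)
    w = spec.delta_half_width
    delta = rng.uniform(-w, w, spec.n_genes)
    p3_targets = np.clip(base + delta, 0.05, 0.95)

    # realised-composition maps (tier genes deliberately use the base map:
    # their extra third-base odds are applied on top, giving them a
    # genuinely distinct codon distribution rather than a re-targeted one)
    s_grid = np.linspace(0.02, 0.98, 49)
    p3_map_base = model.p3_of_s(s_grid, model.pref)

    # attenuation-corrected P12 coupling (see module docstring): the OLS
    # slope of P12 on realised P3 is deflated by every source of P3
    # variance that the latent drift does not explain — binomial sampling
    # noise and the tier genes' systematic third-base offset — so the
    # coupling constant is inflated by the matching factor.
    var_delta = w**2 / 3.0
    n_internal = n_codons - 2
    p3_frac = sum(
        v for aa, v in model.aa_freqs.items()
        if aa not in ("M", "W", "I")
    )
    n3 = np.maximum(n_internal * p3_frac, 1.0)
    pbar = float(np.mean(p3_targets))
    var_noise = pbar * (1 - pbar) * float(np.mean(1.0 / n3))
    var_tier = 0.0
    if spec.tier_fraction > 0:
        p3_map_tier = model.p3_of_s(s_grid, model.tier_pref)
        mid = float(np.clip(np.mean(base), p3_map_base.min(), p3_map_base.max()))
        s_at_mid = _invert_monotone(s_grid, p3_map_base, mid)
        tier_offset = float(np.interp(s_at_mid, s_grid, p3_map_tier)) - mid
        f = spec.tier_fraction
        var_tier = f * (1 - f) * tier_offset**2
    if var_delta > 0:
        c = spec.m * (var_delta + var_noise + var_tier) / var_delta
    else:
        c = 0.0
    # the genome-wide target must be feasible; per-gene drifted targets are
    # clipped to the realisable range instead
    s_mid = _invert_monotone(s_grid, p3_map_base, spec.gc3_target)
    beta_grid = np.linspace(-4.0, 4.0, 41)
    p12_map = model.p12_of_beta(beta_grid, s_mid, model.pref)
    p12_base = float(np.interp(0.0, beta_grid, p12_map))

    # tier membership
    n_tier = int(round(spec.tier_fraction * spec.n_genes))
    tier = np.zeros(spec.n_genes, dtype=bool)
    if n_tier:
        tier[rng.choice(spec.n_genes, size=n_tier, replace=False)] = True

    codon_arr = np.array(model.codons)
    stop_codons = sorted(code.stop_codons)  # TAA, TAG, TGA
    records: list[CdsRecord] = []
    truth_rows = []
    width = len(str(spec.n_genes))
    for g in range(spec.n_genes):
        pref = model.tier_pref if tier[g] else model.pref
        p3_t = float(
            np.clip(p3_targets[g], p3_map_base.min() + 1e-6, p3_map_base.max() - 1e-6)
        )
        s_g = _invert_monotone(s_grid, p3_map_base, p3_t)
        p12_t = p12_base + c * delta[g]
        p12_t = float(np.clip(p12_t, p12_map.min() + 1e-6, p12_map.max() - 1e-6))
        beta_g = _invert_monotone(beta_grid, p12_map, p12_t)
        q_g = model.q * np.exp(
            beta_g * _family_gc12(model, s_g, pref)
        )
        q_g = q_g / q_g.sum()
        probs = model.codon_probs(s_g, pref, q_g)
        probs = probs / probs.sum()
        idx = rng.choice(len(probs), size=n_internal[g], p=probs)
        stop_w = np.array([1.0 - s_g, s_g / 2, s_g / 2])
        stop = stop_codons[rng.choice(3, p=stop_w / stop_w.sum())]
        seq = "ATG" + "".join(codon_arr[idx]) + stop
        gene_id = f"g{g:0{width}d}"
        records.append(CdsRecord(id=gene_id, sequence=seq))
        truth_rows.append(
            {
                "gene_id": gene_id,
                "n_codons": int(n_codons[g]),
                "tier": bool(tier[g]),
                "delta": float(delta[g]),
                "p3_target": p3_t,
                "p12_target": p12_t,
                "s": s_g,
                "beta": beta_g,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return records, truth


def _family_gc12(model: _GenomeModel, s: float, pref: np.ndarray) -> np.ndarray:
    """Per-amino-acid mean GC12 under the family codon distribution at s."""
    probs = model.codon_probs(s, pref, model.q)
    num = np.bincount(model.fam_id, weights=probs * model.gc12, minlength=model.n_fams)
    den = np.bincount(model.fam_id, weights=probs, minlength=model.n_fams)
    return num / np.maximum(den, 1e-12)


def generate_biased_pair(
    bias: str,
    strength: float,
    base_spec: SyntheticSpec,
    code: GeneticCode | None = None,
) -> tuple[
    tuple[list[CdsRecord], pd.DataFrame], tuple[list[CdsRecord], pd.DataFrame]
]:
    """Two genomes identical except for opposite third-base preference.

    The preference acts as an odds shift ``strength`` on the third-position
    GC composition target (towards G/C for "GC", towards A/U for "AU") and
    as the within-family preference odds, in opposite directions for the
    two genomes.  Both genomes share the base spec's seed, so at
    ``strength == 1`` they are byte-identical; at larger strengths they
    emulate the contrast between a G/C-leaning genome and an A/U-leaning
    background.
    """
    if strength < 1:
        raise ValueError("strength must be >= 1")
    if bias not in ("AU", "GC"):
        raise ValueError(f"unknown bias direction {bias!r}")
    other = {"AU": "GC", "GC": "AU"}[bias]
    s0 = base_spec.gc3_target

    def shifted(direction: str) -> float:
        if direction == "GC":
            return s0 * strength / (s0 * strength + (1 - s0))
        return s0 / (s0 + (1 - s0) * strength)

    spec_a = replace(base_spec, base_bias=bias, base_bias_odds=strength,
                     gc3_target=shifted(bias))
    spec_b = replace(base_spec, base_bias=other, base_bias_odds=strength,
                     gc3_target=shifted(other))
    return generate_genome(spec_a, code), generate_genome(spec_b, code)
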