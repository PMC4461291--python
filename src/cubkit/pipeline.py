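"""End-to-end orchestration: per-genome reports plus cross-genome comparison.

``run_pipeline`` runs every analysis stage for each input genome and then
the inter-genome layer, writing TSV tables and a machine-readable JSON
manifest of every statistic.  The rendered tables are pure views of the
manifest: every number in a table also appears in (or is derivable from)
the manifest entry for its stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cds_io, coa, composition, genome, indices
from .genetic_code import standard_code

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "validate_manifest"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and genome label."""

    def __init__(self, stage: str, label: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for genome {label!r}: {cause}")
        self.stage = stage
        self.label = label


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    genomes: dict[str, Path]  # label -> CDS FASTA
    out_dir: Path
    min_len: int = 300
    cai_reference: str | Path = "yeast"  # packaged table name or FASTA path
    tail_fraction: float = 0.05
    pr2_universe: str = "p3"
    include_stops_in_rscu: bool = True
    chi2_construction: str = "per_codon"
    coa_axes: int = 4
    #: species labels forming one side of the two-group comparison
    group_a: list[str] = field(default_factory=list)

    def validate(self) -> None:
        labels = list(self.genomes)
        if len(labels) != len(set(labels)):
            raise ValueError("genome labels must be unique")
        if not labels:
            raise ValueError("at least one genome is required")
        for label, path in self.genomes.items():
            if not Path(path).exists():
                raise ValueError(f"genome {label!r}: file not found: {path}")
        if not 0 < self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must be in (0, 0.5)")
        unknown = [g for g in self.group_a if g not in self.genomes]
        if unknown:
            raise ValueError(f"group_a labels not among genomes: {unknown}")


def _jsonable(x):
    if isinstance(x, (np.floating, float)):
        return None if math.isnan(x) else float(x)
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in x]
    return x


def _load_weights(ref: str | Path) -> indices.ReferenceWeights | None:
    """Resolve the CAI reference: packaged table, FASTA path, or ``"self"``.

    ``"self"`` returns None; each genome's weights are then derived from its
    own pooled codon usage (useful when no homologous high-expression
    reference exists for the organism).
    """
    if isinstance(ref, str) and ref == "self":
        return None
    if isinstance(ref, str) and ref == "yeast":
        return indices.load_reference_weights("yeast")
    records = cds_io.read_cds_fasta(Path(ref))
    kept, _ = cds_io.filter_cds(records, min_len=3)
    pooled = cds_io.pool_counts(
        [cds_io.count_codons(r) for r in kept], gene_id=str(ref)
    )
    return indices.cai_weights(pooled)


def _analyse_genome(label, fasta, cfg, weights, code, out):
    stage = "read"
    try:
        records = cds_io.read_cds_fasta(fasta)
        stage = "filter"
        kept, report = cds_io.filter_cds(records, min_len=cfg.min_len, code=code)
        report.to_csv(out / f"{label}.filter_report.tsv", sep="\t", index=False)
        if not kept:
            raise ValueError("no CDS passed filtering")
        counts = [cds_io.count_codons(r, code=code) for r in kept]
        pooled = cds_io.pool_counts(counts, gene_id=label)

        stage = "indices"
        genome_weights = weights or indices.cai_weights(pooled, code)
        idx = indices.indices_table(counts, genome_weights, code)
        idx.to_csv(out / f"{label}.indices.tsv", sep="\t")

        stage = "rscu"
        genome_rscu = indices.rscu(pooled, code, cfg.include_stops_in_rscu)
        genome_rscu.rename("rscu").to_csv(out / f"{label}.rscu.tsv", sep="\t")

        stage = "composition"
        comp = composition.composition_table(counts, code, cfg.pr2_universe)
        comp.to_csv(out / f"{label}.composition.tsv", sep="\t")
        summary = composition.genome_summary(comp)

        stage = "optimal"
        high_ids, low_ids = genome.select_expression_tails(idx, cfg.tail_fraction)
        by_id = {c.gene_id: c for c in counts}
        high = cds_io.pool_counts([by_id[g] for g in high_ids], "high")
        low = cds_io.pool_counts([by_id[g] for g in low_ids], "low")
        opt = genome.call_optimal_codons(
            high, low, pooled, code, construction=cfg.chi2_construction
        )
        opt.to_csv(out / f"{label}.optimal_codons.tsv", sep="\t")
        opt_summary = genome.optimal_codon_summary(opt)
        opt_summary.to_csv(out / f"{label}.optimal_summary.tsv", sep="\t")

        stage = "neutrality"
        fit = genome.neutrality_fit(comp)

        stage = "correlation"
        per_gene = comp.join(idx[["enc"]], how="inner")
        rho, pval = genome.correlation_matrix(per_gene)
        rho.to_csv(out / f"{label}.correlation_rho.tsv", sep="\t")
        pval.to_csv(out / f"{label}.correlation_p.tsv", sep="\t")

        stage = "encplot"
        encplot = idx[["gc3s", "enc"]].copy()
        encplot["expected_enc"] = encplot["gc3s"].map(
            lambda s: indices.expected_enc(s) if not math.isnan(s) else math.nan
        )
        encplot.to_csv(out / f"{label}.encplot.tsv", sep="\t")

        stage = "coa"
        mat, n_imputed = coa.rscu_matrix(counts, code)
        ca = coa.correspondence_analysis(mat, cfg.coa_axes, n_imputed)
        ax_rho, ax_p, ca = coa.axis_correlations(ca, comp.join(idx, rsuffix="_idx"))
        ca.gene_coords.to_csv(out / f"{label}.coa_genes.tsv", sep="\t")
        ca.codon_coords.to_csv(out / f"{label}.coa_codons.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001 - re-raised with context
        raise PipelineError(stage, label, exc) from exc

    manifest = {
        "n_records": len(records),
        "n_kept": len(kept),
        "drop_reasons": dict(cds_io.drop_reason_tally(report)),
        "composition_means": _jsonable(summary.to_dict()),
        "mean_cai": _jsonable(idx["cai"].mean()),
        "mean_enc": _jsonable(idx["enc"].mean()),
        "pr2": {
            "mean_au_bias": _jsonable(comp["au_bias"].mean()),
            "mean_gc_bias": _jsonable(comp["gc_bias"].mean()),
        },
        "neutrality": {
            "slope": _jsonable(fit.slope),
            "intercept": _jsonable(fit.intercept),
            "relative_neutrality_pct": _jsonable(fit.relative_neutrality),
            "spearman_rho": _jsonable(fit.spearman_rho),
            "spearman_p": _jsonable(fit.spearman_p),
            "n_genes": fit.n_genes,
        },
        "correlation_rho": _jsonable(rho.to_dict()),
        "correlation_p": _jsonable(pval.to_dict()),
        "optimal_summary": _jsonable(opt_summary.to_dict()),
        "n_optimal": int(opt["optimal"].sum()),
        "n_preferred": int(opt["preferred"].sum()),
        "n_rare": int(opt["rare"].sum()),
        "coa": {
            "inertia_fractions": _jsonable(ca.retained_inertia()),
            "axis1_pct": _jsonable(100 * ca.inertia_fractions[0])
            if len(ca.inertia_fractions)
            else None,
            "axes1_4_pct": _jsonable(100 * ca.inertia_fractions[: cfg.coa_axes].sum()),
            "n_imputed": ca.n_imputed,
            "axis_correlations_rho": _jsonable(ax_rho.to_dict()),
            "axis_correlations_p": _jsonable(ax_p.to_dict()),
        },
    }
    return manifest, genome_rscu, idx


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written as JSON)."""
    cfg.validate()
    code = standard_code()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    weights = _load_weights(cfg.cai_reference)

    manifest: dict = {"genomes": {}, "cross_genome": {}}
    rscu_rows = {}
    idx_by_species = {}
    for label, fasta in cfg.genomes.items():
        per, genome_rscu, idx = _analyse_genome(label, fasta, cfg, weights, code, out)
        manifest["genomes"][label] = per
        informative = [c for c in code.informative_codons]
        rscu_rows[label] = genome_rscu.reindex(informative)
        idx_by_species[label] = idx

    if len(cfg.genomes) >= 2:
        try:
            rscu_by_species = pd.DataFrame(rscu_rows).T
            linkage, labels = genome.cluster_species(rscu_by_species)
            newick = genome.linkage_to_newick(linkage, labels)
            (out / "species_cluster.nwk").write_text(newick + "\n")
            manifest["cross_genome"]["cluster_newick"] = newick
            manifest["cross_genome"]["cluster_labels"] = labels
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("cluster", "ALL", exc) from exc
        if cfg.group_a:
            try:
                gc = genome.group_comparison(idx_by_species, cfg.group_a)
                gc.to_csv(out / "group_comparison.tsv", sep="\t")
                manifest["cross_genome"]["group_comparison"] = _jsonable(gc.to_dict())
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("group_comparison", "ALL", exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


_GENOME_KEYS = {
    "n_records",
    "n_kept",
    "drop_reasons",
    "composition_means",
    "mean_cai",
    "mean_enc",
    "pr2",
    "neutrality",
    "correlation_rho",
    "correlation_p",
    "optimal_summary",
    "n_optimal",
    "n_preferred",
    "n_rare",
    "coa",
}


def validate_manifest(manifest: dict) -> None:
    """Structural validation of a pipeline manifest (raises on failure)."""
    if set(manifest) != {"genomes", "cross_genome"}:
        raise ValueError("manifest must have exactly 'genomes' and 'cross_genome'")
    for label, per in manifest["genomes"].items():
        missing = _GENOME_KEYS - set(per)
        if missing:
            raise ValueError(f"genome {label!r} manifest missing keys: {missing}")
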