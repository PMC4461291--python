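#!/usr/bin/env python
"""Run the full codon-usage pipeline over the synthetic cohort.

Produces, per genome: filter report, per-gene CAI/ENc/GC3s, pooled RSCU,
composition table, optimal-codon calls, neutrality fit, correlation matrix,
ENc-plot data and correspondence analysis; across genomes: RSCU clustering
and the two-group CAI/ENc comparison (G/C pair vs A/U majority).

Bulky per-gene tables land in scratch/pipeline/; the cohort-level summary
tables (composition means, optimal-codon summaries, neutrality fits, the
dendrogram and the manifest) are copied to results/.
"""

import json
import shutil
from pathlib import Path

import pandas as pd

from cubkit.pipeline import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
GENOMES = ROOT / "scratch" / "genomes"
OUT = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def main() -> None:
    fastas = sorted(GENOMES.glob("*.fasta"))
    if not fastas:
        raise SystemExit("run analysis/01_simulate_genomes.py first")
    cfg = RunConfig(
        genomes={p.stem: p for p in fastas},
        out_dir=OUT,
        cai_reference="self",
        group_a=[p.stem for p in fastas if p.stem.startswith("gc")],
    )
    manifest = run_pipeline(cfg)

    # Table-3-shaped cohort summary: per-genome composition means + ENc
    comp_rows = {}
    for label, per in manifest["genomes"].items():
        means = per["composition_means"]
        comp_rows[label] = {
            "GCcds%": 100 * means["gc_cds"], "GC3s%": 100 * means["gc3s"],
            "P1%": 100 * means["p1"], "P2%": 100 * means["p2"],
            "P12%": 100 * means["p12"], "P3%": 100 * means["p3"],
            "meanENc": per["mean_enc"], "meanCAI": per["mean_cai"],
            "neutrality_slope": per["neutrality"]["slope"],
            "AU_optimal": per["optimal_summary"]["AU"]["optimal"],
            "GC_optimal": per["optimal_summary"]["GC"]["optimal"],
            "coa_axis1%": per["coa"]["axis1_pct"],
        }
    summary = pd.DataFrame(comp_rows).T.round(2)
    summary.to_csv(RESULTS / "02_cohort_summary.tsv", sep="\t")
    print("cohort summary (per-genome means):")
    print(summary.to_string())

    shutil.copy(OUT / "manifest.json", RESULTS / "02_manifest.json")
    shutil.copy(OUT / "species_cluster.nwk", RESULTS / "02_species_cluster.nwk")
    shutil.copy(OUT / "group_comparison.tsv", RESULTS / "02_group_comparison.tsv")

    print("\ndendrogram:", (OUT / "species_cluster.nwk").read_text().strip())
    gc = manifest["cross_genome"]["group_comparison"]
    print(f"\nG/C pair vs A/U majority: CAI ANOVA p = {gc['anova_p']['cai']:.3g}, "
          f"ENc ANOVA p = {gc['anova_p']['enc']:.3g}")
    au_labels = [l for l in comp_rows if l.startswith("au")]
    au_opt = sum(comp_rows[l]["AU_optimal"] for l in au_labels)
    au_tot = au_opt + sum(comp_rows[l]["GC_optimal"] for l in au_labels)
    print(f"A/U-ending optimal codons in the A/U group: {au_opt}/{au_tot}")


if __name__ == "__main__":
    main()
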