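"""Panel statistics and fold changes on a small paired tumor cohort.

Reads a 11-gene x 6-sample expression table (3 tumor / 3 paired adjacent
normal), computes the protease panel average that serves as the
overexpression baseline, the high-expression cutoff (panel mean + 1.5 SD),
the genes called above-average in the tumor samples, and each called
gene's tumor/normal fold change.
"""

from pathlib import Path

from protfunnel import (
    DEFAULT_SURFACE_TERMS,
    call_above_average_dataset_mean,
    filter_by_localization,
    fold_change_tumor_vs_normal,
    high_expression_cutoff,
    load_protease_catalog,
    panel_stats,
    read_expression_table,
)

here = Path(__file__).parent / "data"
panel = filter_by_localization(
    load_protease_catalog(here / "catalog.tsv"), DEFAULT_SURFACE_TERMS
)
cohort = read_expression_table(
    here / "pdac_cohort_matrix.tsv",
    here / "pdac_cohort_meta.tsv",
    dataset_id="pdac_cohort",
    platform_id="GPL570",
)

stats = panel_stats(cohort, panel, cohort.sample_ids_in_groups(["tumor"]))
cutoff = high_expression_cutoff(stats, k=1.5)
print(f"panel mean over tumor samples: {stats.panel_mean:.1f} (n={stats.n_values})")
print(f"high-expression cutoff (mean + 1.5 SD): {cutoff:.1f}")

called = call_above_average_dataset_mean(cohort, panel)
print(f"above-average in tumors: {sorted(called.genes)}")
for gene in sorted(called.genes):
    fc = fold_change_tumor_vs_normal(cohort, gene)
    flag = "PASS" if fc >= 1.5 else "fail"
    print(f"  {gene:6s} tumor/normal fold change {fc:.2f}  [{flag} at 1.5]")
# Genes above the panel average AND >= 1.5-fold enriched over adjacent
# normal tissue are the cohort's candidate proteases.
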