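"""Generate a synthetic multi-sample breast-cancer cohort.

Builds the tiny stock cohort (6 samples across HR+, HER2+, TNBC and normal
tissue), prints its composition and the injected ground truth: arm-scale
copy-number segments carried by tumor cells, subtype-specific epithelial
markers, and condition-specific ligand–receptor pairs.
"""

from sctme import default_cohort, generate_cohort

cfg = default_cohort("tiny")
ds, truth = generate_cohort(cfg, seed=7)

print(f"cohort: {ds.n_cells} cells × {ds.n_genes} genes, "
      f"{ds.cells['sample_id'].nunique()} samples")
print(ds.cells.groupby(["condition", "major_type"], observed=True).size()
      .unstack(fill_value=0))
print(f"\ntumor cells (ground truth): {int(truth.tumor_labels.sum())}")
print("\ninjected CNV segments (log2 copy-number ratio; + gain, − loss):")
for s in truth.cnv_specs:
    print(f"  {s.chromosome} genes {s.start_gene_index}..."
          f"{s.start_gene_index + s.n_genes}: {s.log2_cnr:+.1f} "
          f"in {sorted(s.conditions)}")
print(f"\ninjected markers: {len(truth.marker_specs)} "
      f"(12 per tumor condition, fold change 8)")
print(f"injected ligand–receptor pairs: {len(truth.lr_specs)}")
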