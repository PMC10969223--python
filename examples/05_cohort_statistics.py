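"""Cohort-level statistics: immune proportions and CNV–immune correlation.

Computes per-sample major-type proportions, Welch t-tests (Bonferroni-
corrected) on immune fractions across conditions, and the per-window
Pearson correlation between mean tumor-cell log2(CNR) and the sample's
immune fraction.  With few samples per condition the correlations are
descriptive, not inferential.
"""

from sctme import PipelineConfig, default_cohort, generate_cohort, \
    sort_genes_genomically
from sctme.cnv import estimate_cnv, select_reference
from sctme.cohort import cell_type_proportions, cnv_immune_correlation, \
    immune_fractions, proportion_tests
from sctme.tumor import call_tumors

ds, truth = generate_cohort(default_cohort("tiny"), seed=7)
ds, _ = sort_genes_genomically(ds)
cnv = estimate_cnv(ds, select_reference(ds.cells))
calls = call_tumors(ds, cnv, PipelineConfig(), seed=7)

props = cell_type_proportions(ds)
imm = immune_fractions(props)
print("per-sample immune fractions (T + B + myeloid):")
print(imm.to_string(index=False))

tests = proportion_tests(props)
print("\npairwise Welch t-tests on immune fractions "
      "(Bonferroni-adjusted):")
if tests.empty:
    print("  (skipped: a condition has fewer than 2 samples)")
else:
    print(tests.to_string(index=False))

spots = cnv_immune_correlation(cnv, calls, props, "TNBC", ds.cells,
                               min_samples=2, r_threshold=None)
print(f"\ntop CNV–immune correlation spots for TNBC "
      f"({spots.iloc[0]['n_samples']} samples):")
print(spots.head(5).to_string(index=False))
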