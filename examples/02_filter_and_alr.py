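"""Compositional preprocessing: high-abundance filter and ALR transform.

Taxa are kept when their relative abundance reaches 0.1% in at least two
specimens of at least one clinical group; the survivors are mapped to
unconstrained real space with the additive log-ratio transform.
"""

import scfa_micromap as sm

table, meta, _ = sm.generate_cohort(sm.GeneratorConfig(seed=42))
filtered, report = sm.filter_high_abundant(table, meta, abundance_min=0.001, min_prevalent_samples=2)
print("filter:", report.counts())

alr = sm.alr_transform(filtered.to_relative())
print(f"ALR reference part: {alr.reference_id} (pseudocount {alr.pseudocount:g})")
print(alr.data.iloc[:3, :4].round(3))
# Each value is ln(taxon / reference); rows now live in R^(p-1), where
# ordinary linear models apply.
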