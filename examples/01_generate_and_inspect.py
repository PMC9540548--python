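"""Generate a synthetic ELN-like dataset and inspect its statistics.

Builds 2000 Buchwald-Hartwig coupling records with the default study
conditions (24 contexts, long-tailed popularity, mostly single-variation
records, one context-replacement event mid-range) and prints the imbalance
and multi-label statistics a modeler would check first.
"""

import rxncontext as rc

cfg = rc.GeneratorConfig(n_records=2000, seed=0)
ds = rc.generate(cfg)
print(f"records: {len(ds)}, variations: {ds.n_variations}, "
      f"years: {ds.years()[0]}-{ds.years()[-1]}")

result = rc.filter_and_label(ds, k=30, min_yield=20.0)
report = rc.dataset_report(result)
print(f"kept {report['records_kept']} records over "
      f"{report['n_labels']} contexts "
      f"(dropped {report['records_dropped_yield']} at the yield filter, "
      f"{report['records_dropped_context']} at the top-k filter, "
      f"{report['records_dropped_duplicate']} as duplicate reactions)")

summary = rc.imbalance_summary(result.multi_table, result.label_space)
print(f"mean imbalance ratio: {summary.mean_ir:.2f} "
      f"(imbalanced: {summary.imbalanced})")
print(f"label cardinality: {summary.cardinality:.3f}, "
      f"label density: {summary.density:.4f}")
# mean IR well above 1.5 marks an imbalanced label distribution; cardinality
# near 1 says most reactions have a single recorded context.

realism = rc.validate_realism(ds)
print("realism envelopes:",
      {k: v["pass"] for k, v in realism.items() if isinstance(v, dict)})
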