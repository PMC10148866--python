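"""Generate a synthetic multi-omics bundle with planted SL pairs.

The generator draws coherent cell-line, patient, drug and pathway data in
which five gene pairs are truly synthetic lethal: LoF-A cell lines are more
sensitive to knocking out B, LoF-A tumors over-express B, double-LoF
patients survive longer than epistasis-free expectation, and so on.
"""

from slidekit import GeneratorConfig, generate

config = GeneratorConfig(seed=1)
synth = generate(config)
bundle, truth = synth.bundle, synth.truth

print(f"candidate pairs : {len(bundle.pairs)}")
print(f"planted SL pairs: {truth.planted.sum()}")
print(f"cell lines      : {len(bundle.cellline_alterations.samples)}")
print(f"patients        : {len(bundle.cohort.samples)}")
print(f"screens         : {[s.dataset_name for s in bundle.screens]}")
print(f"drug screens    : {[s.dataset_name for s in bundle.drug_screens]}")
print(f"pathways        : {len(bundle.pathways.pathways)}")
print("\nplanted pairs:")
print(truth[truth.planted][["gene_a", "gene_b", "series"]].to_string(index=False))

# The truth table lets you score any downstream analysis: 'planted' marks
# the true positives, the signal_* columns say which modality carries signal.
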