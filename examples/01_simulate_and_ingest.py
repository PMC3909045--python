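"""Simulate a multi-study cytokine dataset and harmonise it.

Generates synthetic per-study measurements for glycolipid analogues in the
five test-models, normalises every response to the α-GalCer-like reference
compound within each study (at the reference-maximal dose), and averages
replicate studies into one relative response per (compound, test-model,
marker) cell.
"""

import warnings

import inktqsar as iq

warnings.simplefilter("ignore")

config = iq.GeneratorConfig(n_compounds=50, seed=1)
descriptors, records, truth = iq.generate_dataset(config)
print(f"simulated {len(records)} raw measurements for "
      f"{config.n_compounds} compounds")

parsed = iq.read_response_table(records)
normalized = iq.normalize_to_reference(parsed, "CPD-001")
matrix = iq.aggregate_replicates(normalized, "CPD-001")
n_cells = int(matrix.values.notna().sum().sum())
print(f"{len(normalized)} normalized study results -> {n_cells} aggregated "
      f"(compound, test-model, marker) cells")

# the reference is 1.0 everywhere by construction: units cancel in the ratio
ref = matrix.values.loc["CPD-001"].dropna()
print(f"reference compound relative response: min={ref.min():.3f}, "
      f"max={ref.max():.3f} (should both be 1.000)")

freq = iq.summarize_frequencies(matrix)
print("\nassay usage (share of all aggregated results):")
for system, pct in freq.attrs["test_model_percent"].items():
    print(f"  {system:<28} {pct:6.2f}%")
print("each percentage is that test-model's share of the dataset; sparse,")
print("uneven coverage is typical of literature-aggregated response data")
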