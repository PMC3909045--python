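"""Score Th1/Th2 polarization with Derringer desirability.

Each relative cytokine response is mapped linearly to d in [0.1, 0.9]
between 0 and the maximum observed response; a Th1 axis wants IFN-γ high
(d -> 0.9) and IL-4 low (d -> 0.9 on the mirrored scale).  The overall D
is the geometric mean of the component d-values, so only consistently
polarized profiles score high: d = 0.1 with d = 0.9 gives D = 0.3.
"""

import warnings

import inktqsar as iq

warnings.simplefilter("ignore")

print("worked example: one response maximal, the other minimal")
print(f"  D = geometric mean of 0.1 and 0.9 = "
      f"{iq.overall_desirability([0.1, 0.9]):.2f} -> not a useful polarizer\n")

descriptors, records, truth = iq.generate_dataset(iq.GeneratorConfig(n_compounds=50,
                                                                     seed=1))
matrix = iq.aggregate_replicates(
    iq.normalize_to_reference(iq.read_response_table(records), "CPD-001"),
    "CPD-001")
table = iq.desirability_profiles(matrix)
D = table.d_matrix()

print("per-axis desirability (number of scoreable compounds):")
for axis in D.columns:
    print(f"  {axis:<14} n={D[axis].notna().sum():2d}  "
          f"median D={D[axis].median():.3f}")

ref_D = D.loc["CPD-001"]
print("\nreference compound D per axis (all responses = 1 by definition):")
print("  " + ", ".join(f"{a}={v:.3f}" for a, v in ref_D.dropna().items()))

top = D["Th1-in-vivo"].idxmax()
print(f"\nstrongest Th1 in-vivo polarizer: {top} "
      f"(D={D.loc[top, 'Th1-in-vivo']:.3f} vs reference "
      f"{ref_D['Th1-in-vivo']:.3f})")
print("compounds with D above the reference are 'strong' candidates for a")
print("polarized (here Th1-biased) immune response")
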