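"""Map the chemical space of the compound set.

Constant descriptor columns are pruned, the matrix is autoscaled, and the
compounds are summarised by principal-component scores (for a t(1)/t(2)
score plot) and by average-linkage (UPGMA) hierarchical clustering.
"""

import inktqsar as iq

descriptors, truth = iq.generate_chemical_space(
    iq.GeneratorConfig(n_compounds=50, n_descriptors=40, n_constant=3, seed=1))

pruned, removed = iq.prune_constant_descriptors(descriptors)
print(f"descriptor matrix {descriptors.shape[0]}x{descriptors.shape[1]}: "
      f"removed {len(removed)} constant columns -> {pruned.shape[1]} retained")

pca = iq.pca_scores(pruned, n_components=2)
ev = pca.explained_variance_fraction
print(f"PCA: t(1) explains {ev[0]:.1%}, t(2) {ev[1]:.1%} of the scaled "
      f"descriptor variance")
print("compounds close together in the t(1)/t(2) plane are structurally "
      "similar;\nthe correlated informative block dominates t(1) here")

dendro = iq.hca_average_linkage(pruned)
heights = dendro.merges[:, 2]
print(f"\nUPGMA clustering: {len(heights)} merges, heights from "
      f"{heights[0]:.2f} to {heights[-1]:.2f} (monotone non-decreasing)")
print("first merged pair:",
      dendro.leaf_labels[int(dendro.merges[0, 0])],
      "+", dendro.leaf_labels[int(dendro.merges[0, 1])],
      f"at height {heights[0]:.2f}")
print("the Newick export (dendro.to_newick()) can be drawn with any tree viewer")
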