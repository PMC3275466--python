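"""How often would a sample's subtype call change if it were re-measured?

Monte Carlo answer: perturb every gene with its own Gaussian measurement
error and re-classify, many times.  An archetypal sample (on a centroid)
essentially never flips; a gray-area sample between two centroids flips
constantly — same assay, same error model, very different reproducibility.
"""

import numpy as np

import subtypesim as st

spec = st.SyntheticSpec(seed=7)
centroids = st.make_centroids(spec)

# archetype: sigma per gene straight from its own replicate measurements
_, suite = st.make_archetype_suite(spec, subtypes=["Luminal B"], centroids=centroids)
parent, subtype, rm = suite[0]
sigma = {g.gene_id: g.sigma for g in st.fit_gene_gaussians(rm)}
cfg = st.SimulationConfig(n_sims=10_000, master_seed=42)
res = st.run_reproducibility(parent, subtype, centroids, sigma, cfg)
print(f"archetypal {subtype}: prop_identical = {res.prop_identical:.4f} "
      f"over {res.n_sims:,} simulations")

# gray-area sample: exact midpoint between two centroids
a, b = centroids.subtype_names[0], centroids.subtype_names[1]
midpoint = st.ExpressionProfile(
    "midpoint", (centroids.profiles[a] + centroids.profiles[b]) / 2.0
)
assigned = st.classify_sample(midpoint, centroids).assigned_subtype
res = st.run_reproducibility(
    midpoint, assigned, centroids, np.full(spec.n_genes, 0.5), cfg
)
print(f"gray-area midpoint ({a} / {b}): prop_identical = "
      f"{res.prop_identical:.4f}")

card = st.scorecard(res)
print("\n" + card.to_markdown())
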