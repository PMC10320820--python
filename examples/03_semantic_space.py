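"""Period semantic spaces, nearest neighbors, and the ratio analysis.

Each period's cue-by-cue count matrix is row-normalized, PPMI-weighted, and
expanded with an attenuated random walk G = (I - 0.75 P)^-1; cosine
similarity between rows of G defines the space.  A cue's change is read off
the Covid/Precovid similarity ratios of its top-20 neighbors.
"""

import lexidrift as lx
from lexidrift.simulate import SimConfig, generate_dataset

ds, truth = generate_dataset(SimConfig(seed=0, shift_magnitude=0.5))
targets = sorted(
    ds.registry.loc[
        ds.registry["cue_type"].isin(
            ("control", "pandemic", "emotion", "routine")), "cue"]
)
pre_ds, cov_ds = lx.assemble_period_datasets(ds, targets)
_, sim_pre = lx.build_semantic_space(pre_ds, alpha=0.75, period="precovid")
_, sim_cov = lx.build_semantic_space(cov_ds, alpha=0.75, period="covid")

cue = truth.cues.loc[truth.cues["shifted"], "cue"].iloc[0]
print(f"top-5 neighbors of shifted cue {cue}:")
print("  precovid:", lx.top_neighbors(sim_pre, cue, k=5))
print("  covid:   ", lx.top_neighbors(sim_cov, cue, k=5))

# union of the two top-20 neighborhoods with similarity ratios
comparisons = lx.neighbor_analysis(sim_pre, sim_cov, cue, k=20)
print(f"mean |ratio - 1| = {lx.mean_ratio_deviation(comparisons):.3f}")

# all cues: gamma/inverse model of the ratios with cue-level clustering
ratios = lx.neighbor_ratio_table(sim_pre, sim_cov, ds.registry, k=20)
summary = lx.fit_ratio_model(ratios)
print(f"cue-type x neighbor-type interaction: chi2 = "
      f"{summary.statistic:.2f}, p = {summary.p_value:.3g}")

# ego network of the cue's responses, colored old / new / shared
g = lx.ego_network(ds, cue, min_occurrence=2)
new_nodes = [n for n, d in g.nodes(data=True) if d["category"] == "new"]
print(f"ego network: {g.number_of_nodes()} nodes, "
      f"{len(new_nodes)} Covid-only responses")
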