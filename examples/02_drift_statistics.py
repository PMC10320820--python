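"""Per-cue drift statistics and the group models.

Two complementary measures per cue: the proportion of Covid response tokens
whose type was never given Precovid, and the KL divergence (nats) of the
Covid response distribution from the Precovid one (Jeffreys smoothing).
Group differences across cue types are tested with a binomial-logit GLM and
a gaussian linear model, with Tukey-adjusted pairwise contrasts.
"""

import lexidrift as lx
from lexidrift.simulate import SimConfig, generate_dataset

ds, truth = generate_dataset(SimConfig(seed=0, shift_magnitude=0.5))
ft = lx.count_responses(ds)

# one shifted cue, by hand
cue = truth.cues.loc[truth.cues["shifted"], "cue"].iloc[0]
prop, n_new, n_total = lx.new_response_proportion(ft, cue)
kl = lx.kl_divergence_cue(ft, cue)  # D(covid || precovid), 0.5 pseudocount
print(f"{cue}: {n_new}/{n_total} new tokens ({prop:.1%}), KL {kl:.3f} nats")

# all analysis cues at once (fillers excluded)
table = lx.drift_table(ft, ds.registry)
print(table.groupby("cue_type")[["proportion_new", "kl_nats"]].mean()
      .round(3))

# omnibus tests and Tukey-adjusted contrasts
for response in ("proportion_new", "kl_nats"):
    summary = lx.fit_drift_models(table, response)
    print(f"\n{response}: {summary.family} {summary.statistic_name} = "
          f"{summary.statistic:.2f}, p = {summary.p_value:.3g}")
    for c in summary.contrasts:
        if "pandemic" in c.levels:
            print(f"  {c.levels[0]} vs {c.levels[1]}: "
                  f"diff {c.estimate_response:+.3f}, "
                  f"p_adj {c.p_adjusted:.3g}")
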