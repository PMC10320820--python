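"""Generate a synthetic two-period association dataset and preprocess it.

The generator produces SWOW-style free-association data for two cohorts
(precovid / covid) in which the pandemic-type cues drift toward a small
cluster of "sense" words.  Preprocessing normalizes tokens, applies the four
participant exclusion rules, and trims each (cue, period) cell to a quota.
"""

import lexidrift as lx
from lexidrift.data import SENTINELS
from lexidrift.simulate import SimConfig, generate_dataset, inject_violators

# a dataset with 100 analysis cues, 60 respondents per cue per period
ds, truth = generate_dataset(SimConfig(seed=0, shift_magnitude=0.5))
print(f"{len(ds.participants)} participants, {len(ds.trials)} responses, "
      f"{ds.registry['cue'].nunique()} cues")

# add a few participants engineered to violate each exclusion rule
lexicon = lx.Lexicon(frozenset(
    set(ds.trials.loc[~ds.trials["response"].isin(SENTINELS), "response"])
    | set(ds.registry["cue"])
))
ds, labels = inject_violators(
    ds, {"sentences": 0.01, "uniqueness": 0.01,
         "lexicon": 0.01, "unknown": 0.01}, seed=1,
)
print(f"injected {len(labels)} rule violators")

# normalization (here a no-op: the simulator emits canonical tokens)
ds = lx.normalize_tokens(ds, variant_map=None)

# the four exclusion rules: >30% sentences, <80% unique, <60% in-lexicon,
# >60% unknown cues
ds, report = lx.filter_participants(ds, lexicon)
print("excluded per rule:", report["rule_counts"])

# quota sampling: at most 60 respondents per (cue, period), preferring the
# Rioplatense native-language tiers
ds = lx.select_participant_quota(ds, quota=60, seed=0)
print(f"{len(ds.participants)} participants after preprocessing")
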