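# lexidrift

Detecting fast diachronic semantic change from two-period word-association
norms.

`lexidrift` compares free word-association responses (a cue word plus up to
three responses per participant, SWOW-style) collected in two time periods —
labeled *precovid* and *covid* — and quantifies how individual cue words
drifted between them:

1. **New-response proportion** — the share of second-period response tokens
   whose type was never given for that cue in the first period.
2. **KL divergence** — the relative entropy (nats) of the second-period
   response distribution with respect to the first, after additive
   smoothing on the union support.
3. **Semantic-space change** — each period's cue-by-cue counts are
   PPMI-weighted and expanded with an attenuated random walk
   `G = (I − αP)⁻¹` (α = 0.75); a cue's change is summarized by the
   Covid/Precovid cosine-similarity ratios of its top-20 nearest neighbors.
4. **Directional sense shifts** — a sense is anchored by two paradigm
   words; the shift in a cue's summed similarity to them is tested against
   a permutation null of random word pairs similarity-matched (±0.05) to
   the anchor pair.

Group differences across cue types (control / pandemic / emotion / routine)
are tested with a binomial-logit GLM, a gaussian linear model, and a
gamma/inverse-link model of the similarity ratios with cue-level clustering,
all with Tukey-adjusted pairwise contrasts.

The package also ships a fully seeded synthetic-data generator
(Dirichlet-multinomial responses with an injected sense shift of magnitude
δ and optional exclusion-rule violators), so the entire methodology can be
exercised and validated offline. See [docs/methods.md](docs/methods.md) for
the model and every default.

## Quickstart

```python
import lexidrift as lx
from lexidrift.simulate import SimConfig, generate_dataset

ds, truth = generate_dataset(SimConfig(seed=0, shift_magnitude=0.5))
ft = lx.count_responses(ds)
table = lx.drift_table(ft, ds.registry)
print(table.groupby("cue_type")[["proportion_new", "kl_nats"]].mean())
```

```
          proportion_new  kl_nats
cue_type
control            0.034    0.129
emotion            0.030    0.113
pandemic           0.456    1.219
routine            0.025    0.106
```

The pandemic cues — the only ones shifted by the generator — stand out on
both measures. The scripts in [examples/](examples/) walk through the full
methodology: preprocessing with the four exclusion rules, the drift models,
the semantic spaces and neighbor-ratio analysis, and the matched
permutation sense-shift test. Each runs in a few seconds:

```bash
python examples/04_sense_shift_test.py
# pan000: shift = +0.1065, one-sided p = 0.005 (199 matched permutations)
# ctl000: shift = +0.0047, one-sided p = 0.120 (199 matched permutations)
```

## Command line

A thin CLI wraps the library pipeline (preprocess → drift → semspace →
senseshift). Artifacts (TSV tables, model JSONs, a reproducibility
manifest) land in `--output-dir`.

```bash
lexidrift simulate --out sim.tsv --seed 1 --delta 0.5
lexidrift drift --data-path sim.tsv --registry-path sim.registry.tsv \
    --output-dir out/
lexidrift run-all --config my_config.yaml
```

Every analysis constant (exclusion thresholds, quota, α, k, permutation
count, tolerance, seed) can be set in a YAML config or as a CLI flag;
unknown config keys are rejected.

## Data format

Tab-separated, UTF-8. Wide dialect: one row per (participant, cue) with
columns `participant_id, period, gender, age, native_language, education,
cue, R1, R2, R3`; long dialect: one row per response with `position` /
`response` instead of R1–R3 (auto-detected). The strings
`No more responses` and `Unknown word` are sentinel responses. An optional
cue registry TSV (`cue, cue_type, presented_in`) assigns the experimental
cue types; an optional lexicon (one word per line) enables the in-lexicon
exclusion rule, and an optional variant map (`variant → canonical`)
canonicalizes spelling variants of responses.

## Testing and reproducing the results

```bash
python -m pytest -q                 # full suite, a few minutes
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` pins the package's contract: design arithmetic,
agreement of the dense walk solve with the truncated Neumann series (1e-8),
closed-form KL / inverse / cosine values (1e-10), ~5% type-I rate of the
matched permutation test under a null generator, KL-ranking AUC ≥ 0.9 at
δ = 0.5 with monotonicity in δ, exact round-trip of the exclusion rules on
injected violators, and exactly-zero drift when both periods contain
identical data.

`scripts/acceptance.py` recomputes the headline quantities end-to-end from
a seed and writes them as JSON; everything is deterministic given the seed.
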