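# Methods

This note documents the statistical model implemented by `lexidrift`, every
parameter with its default and rationale, the synthetic-data generator, and
the package's numerical and scaling choices.

## Data model

A dataset holds three tables: participants (`participant_id, period,
gender, age, native_language, education`, with `period ∈ {precovid,
covid}`), trials (one row per response: `participant_id, cue, position ∈
{R1, R2, R3}, response`), and a cue registry (`cue, cue_type ∈ {control,
pandemic, emotion, routine, filler}, presented_in`). Two sentinel responses
are first-class citizens: *No more responses* (the participant stopped
early) and *Unknown word* (the cue was not recognized; it occupies the
whole trial). Sentinels never enter response counts.

### Normalization

Tokens are normalized by stripping markup tags, iterating
quote-stripping and final-punctuation removal to a fixpoint (so forms like
`"casa".` reduce fully), collapsing whitespace and lowercasing. An optional
variant map sends spelling variants to canonical forms; it applies to
responses only (cue strings are stimulus identities) and must be
idempotent: a canonical form may not itself be mapped.

### Participant exclusion rules

All four comparisons are strict inequalities; sentinels leave the
denominators of rules 1–3, and rule 4 is computed over presented cues:

1. **sentences** — more than 30% of responses have ≥ 3 whitespace tokens;
2. **uniqueness** — fewer than 80% of response tokens are unique;
3. **lexicon** — fewer than 60% of responses are in the reference lexicon
   (rule disabled when no lexicon is supplied; an empty lexicon is a
   configuration error);
4. **unknown** — more than 60% of presented cues answered *Unknown word*.

### Quota sampling

Each (cue, period) cell is trimmed to 60 respondents. Respondents are kept
by native-language priority tier — Uruguay/Argentina Rioplatense first,
then Cordobés/Northern — and within the tier straddling the boundary a
uniform random subset is drawn from a seeded generator. Cells at or under
quota are kept whole and consume no randomness, so equal inputs yield equal
outputs.

## Drift measures

Counts aggregate over positions R1–R3 by default (configurable). For a cue
with Precovid counts `n_pre` and Covid counts `n_cov` over response types:

- **New-response proportion**: the fraction of *Covid tokens* whose type
  has zero Precovid count. Token-level (each response is one Bernoulli
  trial), matching the binomial model below.
- **KL divergence**: `D(covid ‖ precovid)` in nats over the union support
  after adding a pseudocount to every cell. Default 0.5 (Jeffreys); a
  pseudocount of 0 is allowed and yields +∞ on disjoint support.

### Group models

- `proportion_new`: binomial GLM with logit link on (new, total) per cue,
  cell-means parameterization over cue types; omnibus likelihood-ratio χ²
  against the intercept-only model.
- `kl_nats`: gaussian linear model; omnibus ANOVA F.
- Pairwise cue-type contrasts are Tukey-adjusted via the studentized range
  distribution (asymptotic df for z-based models, residual df for the
  gaussian one). Constant responses short-circuit to a null result
  (statistic 0, p 1) rather than a degenerate fit.

## Semantic space

Per period: (1) a cue-by-cue count matrix over the cues present in the
data (responses that are not cues are dropped — the space is defined on
the cue vocabulary); (2) rows normalized to probabilities; (3) PPMI,
`max(0, ln(p(j|i)/p(j)))`, with the reference marginal `p(j)` the mean of
column j over rows (uniform cue prior; a count-weighted marginal is
available), re-normalized to row-stochastic; (4) attenuated random-walk
expansion `G = (I − αP)⁻¹` with α = 0.75, computed by a dense solve up to
2000 rows and a truncated Neumann series beyond (the two agree within 1e-8;
a spectral-radius check raises before a divergent expansion); (5) cosine
similarity between rows of G, clipped to [0, 1], zero rows giving 0.

### Neighbor-ratio analysis

For each analysis cue, the union of its top-20 neighborhoods in the two
spaces (ties broken lexically) is categorized *precovid-only* /
*covid-only* / *shared*, and each neighbor contributes the ratio
covid-similarity / precovid-similarity. Zero Precovid similarity yields an
infinite ratio, flagged and excluded from means and models. Ratios are
modeled with a gamma GLM with inverse link, fit by generalized estimating
equations with an exchangeable working correlation within cue — the
clustering a random-intercept mixed model would absorb, chosen because GEE
with a full cue-type × neighbor-type cell-means design is deterministic and
dependency-light while targeting the same marginal contrasts. The omnibus
statistic is the Wald χ² for the interaction, built from double-difference
contrasts over a reference row and column.

### Ego networks

The responses given to a focal cue (≥ 2 occurrences) form a star around
it, each node labeled old / new / shared by period membership and weighted
by its percentage of the cue's responses; edges are added between nodes
that appear as cue–response pairs anywhere in the data. Exported as
node/edge TSVs and optionally GraphML.

## Sense-shift test

A sense anchor is a pair of distinct paradigm words. The sense rating of a
cue is the sum of its cosine similarities to the two words; the shift is
the Covid rating minus the Precovid rating. The null distribution
recomputes the shift for `n_perm` random word pairs whose *Precovid*
cosine lies within ±0.05 of the anchor pair's (so the null pairs are as
tight as the anchor), drawn uniformly without replacement; fewer eligible
pairs than requested is a hard `ShortfallError`. The one-sided p-value is
the add-one estimator `(1 + #{null ≥ observed}) / (1 + n_perm)`, never
exactly zero. Default `n_perm` = 1000; desk-scale vocabularies (a few
hundred words, ~10⁴–10⁵ candidate pairs) support a few hundred matched
pairs, so the tests and examples use 50–199.

## Synthetic-data generator

The generator is the package's test bed; its defaults are study
conditions, not tuning knobs:

- 100 analysis cues (25 each control / pandemic / emotion / routine), 150
  filler cues, 10 extra "sense" words registered as fillers, and 500
  response-only tokens.
- Each cue has a 40-word support set drawn with cue words weighted 1.0 and
  response-only tokens 0.18, with a Dirichlet(0.3) distribution over the
  support. Sense words are a coherent cluster: 45% of their response mass
  points at the other sense words.
- The Covid distribution of a shifted (pandemic) cue is
  `(1 − δ)·θ + δ·φ`, where φ is a geometric profile (ratio 0.6) over the
  sense words; δ defaults to 0.5. All other cues are unchanged, so any
  measured drift on them is pure sampling noise.
- Participants answer 15-cue blocks that interleave cue types (as in the
  source task, where target cues were scattered among controls and
  fillers); each (cue, period) cell receives exactly 60 respondents.
  Trials draw 3 distinct responses via Gumbel top-k; 2% of trials are
  *Unknown word* and 10% stop after R1.
- Demographics follow the modeled study's cohort marginals
  (`lexidrift.study_design`): the Precovid cohort is predominantly
  Uruguayan Rioplatense, the Covid cohort Argentinian Rioplatense.
- `inject_violators` adds participants engineered to violate exactly one
  exclusion rule each (e.g. 4/12 multi-word responses ≈ 33% > 30%),
  keeping every other rule satisfied. The clean generator itself produces
  a small share (< 0.5%) of genuine uniqueness violators — participants
  whose block is dominated by the coherent sense cluster — mirroring the
  low organic exclusion rate of real norming data.

## Scale and numerics

The modeled study had ~21k participants, 469 analysis cues and a
13k-word similarity vocabulary. This package's defaults reproduce the
design *shape* at desk scale (100 analysis cues, 60 respondents per cell,
~260-word spaces) so that the full pipeline runs in seconds on one CPU;
all sizes are parameters. Consequences of the scale-down: permutation
matching pools are smaller (hence `n_perm` ≤ 199 in tests), and the
neighbor sets of a 260-word space are denser than in a 13k-word one.
Numerical choices: dense `linalg.solve` for G below 2000 rows (Neumann
series above, tolerance 1e-10), `scipy.stats.entropy` for KL,
`scipy.stats.studentized_range` with df 1e7 as the asymptotic Tukey
reference, and seeded `numpy.random.default_rng` everywhere randomness
exists — equal seeds give byte-identical artifacts.

## Limitations

- The gamma ratio model uses GEE, not a random-intercept gamma GLMM;
  marginal rather than conditional estimates (a deliberate substitution —
  see the interaction df note: with four cue types and three neighbor
  categories the interaction has 6 df).
- The generator emulates response *distributions* and cohort composition,
  not real lexical semantics: tokens are synthetic identifiers, and the
  injected shift is a single coherent sense cluster rather than the messier
  multi-sense drift of real vocabularies.
- Sense anchors must be chosen by hand, as in the source methodology; the
  package validates them (distinct, in-vocabulary) but cannot judge their
  semantic quality.
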