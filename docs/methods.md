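# Methods

This note documents the models implemented in `synbold`, the choices made
where the design was genuinely open, and what the synthetic validation does
and does not establish.

## Node-count metrics

All metrics operate on a constituent tree whose nodes carry half-open
terminal spans `[i, j)` (0-based). The *countable* nodes are all
nonterminals except part-of-speech wrappers. A tree is treated as
POS-wrapped only when **every** terminal's immediate parent has exactly one
child — the shape of standard parser output — and only then are those
wrappers excluded (the root never is; a flag restores them). In mixed
bracketings where some word sits directly under a phrasal node, nothing is
stripped: a structural test cannot distinguish an NP directly over a word
from a POS tag, and spontaneous-speech bracketings frequently attach words
directly to phrases.

Attribution rules, per countable node with span `[i, j)`:

| strategy | counted at |
|---|---|
| top-down | word `i` (phrase opening) |
| bottom-up | word `j − 1` (phrase closing) |
| left-corner | last word of the node's first daughter |
| open nodes | level, not a count: `cumsum(TD) − cumsum(BU)` |
| early top-down | word `w`'s TD nodes counted at `w − 1`; word 0 absorbs words 0 and 1 |
| chunked | chunk-initial word / preceding dependency head |

Open nodes are measured *after* the closures at the word (final word of a
complete sentence = 0); an `open_timing="before"` flag gives the
pre-closure convention. Early top-down folds the first word's nodes into
word 0 rather than positing pre-sentence events. For the chunked strategy,
heads are the tokens with at least one dependent; nodes after the last head
are assigned to the last head so that every strategy distributes exactly the
same total (conservation is asserted, not assumed). The left-corner
announce point is the standard one (node announced when its leftmost
daughter completes). These parsers are deliberate oracles: they attribute
the nodes of the final parse and ignore ambiguity.

Each incremental traversal has a brute-force counterpart (`span_oracle`)
that attributes nodes by direct span inspection; equality on 1,000 random
trees is part of the validation suite.

## From words to scan-resolution regressors

Word-level predictors become impulses of the predictor's value at the word's
onset (boxcars over the word's duration are available behind a flag), placed
on a 0.05 s grid, convolved with the double-gamma HRF

`h(t) = g(t; 6, 1) − g(t; 16, 1) / 6`, truncated at 32 s,

and sampled at volume onsets `t_k = k · TR` (TR default 1.5 s; a reference
offset is configurable). Word-by-word predictors are mean-centered per
recall beforehand — convolution is per run, so centering pools within the
same run — except the word-rate impulse and the sentence-onset/-offset
indicators, which stay on their 0/1 scale. Temporal-derivative columns
(convolution with `dh/dt`, then orthogonalized against the parent so the
parent's beta keeps its interpretation) are optional and capture sub-TR
latency shifts. Convolution is linear and deterministic; delaying all
onsets by exactly one TR shifts the sampled regressor by one scan. The
collinearity report computes all pairwise Pearson correlations and flags
|r| > 0.7 (configurable): the structure-building regressors correlate at
0.9+ after convolution, which is why the production strategies are compared
across separate models rather than jointly.

## Encoding models

The response table stacks (participant, ROI, scan) rows. Fixed effects are
design columns plus factors: modality is deviation-coded ±½ (production
positive), so a `slope:modality` coefficient *is* the
production-minus-comprehension slope difference; ROI is Helmert-coded
((BA44+BA45) vs LpMTG, then BA44 vs BA45 — orthogonal, zero-sum).
By-participant random slopes are uncorrelated variance components (the
`(0 + x || participant)` structure); random intercepts and correlations are
excluded. ML is used whenever AIC or likelihood-ratio comparison is
requested, REML otherwise, and REML fits with different fixed structures are
refused comparison. `AIC = 2k − 2·logLik` counts fixed effects, variance
components and the residual variance. t statistics use a normal
approximation — thousands of observations per participant — and per-term
Wald chi-squares test coefficient blocks jointly (a 2-column ROI interaction
has df = 2). Pairwise cell contrasts are linear combinations of fixed
effects with Tukey (studentized-range) adjustment within a family by
default; the adjustment method is configurable, as published analyses vary.

**Prewhitening.** BOLD residuals are temporally autocorrelated, and the
HRF-convolved regressors are smooth, a combination that understates mixed-
model standard errors (we measure ~16% type-I for a null regressor at
AR(1) ρ = 0.3 without correction). Each series is therefore AR(1)
prewhitened before fitting: ρ is estimated per (participant, ROI) series by
profiling the REML criterion of `y ~ N(Xβ, σ²·AR1(ρ))` over a ρ grid (step
0.05, parabolic refinement). REML matters — plug-in residual
autocorrelation is biased low precisely because the smooth regressors absorb
autocorrelated noise — and series of ≥200 scans give a calibrated ~5% null
rejection rate. This step is standard scan-level fMRI practice and is this
package's addition on top of the bare mixed model.

**Convergence and singular fits.** On non-convergence the weakest non-focal
variance component is dropped and the drop recorded; focal components are
never dropped for convergence. Separately, a component estimated at the
zero boundary (optimizers pin it just off zero, which silently inflates
fixed-effect SEs and makes Wald tests conservative) is removed when it is
negligible (< 1% of residual variance) *and* removing it costs less than
the one-point AIC break-even; with no components left the model reduces to
exact OLS. This mirrors the common lme4 practice of simplifying singular
random structures. Quasi-Newton optimization occasionally stalls near the
variance boundary; fits fall back to a direction-set search and keep the
better likelihood.

## Speech-timing models

`pause_before(w) = onset(w) − offset(w−1)` within a recall (first word NA;
negative gaps from overlapping alignments clamp to 0 with a logged count);
`duration(w) = offset − onset`. Both are modelled on `log(x + 1 ms)` by
default to tame the right skew (raw scale available — the raw-scale
syllable coefficient of the duration model estimates the articulation rate
directly), with the six word-level predictors (syllables, log frequency,
surprisal, top-down, bottom-up, open nodes) and an uncorrelated
by-participant random slope on the focal predictor. Sentence-initial words
are excluded from the pause model by default: their silences are the very
boundaries that pause-based segmentation is built from, not planning pauses
(a flag includes them).

Sentence segmentation is disfluency-informed: a new sentence starts at any
word whose preceding silent gap is ≥ the threshold (default 1.0 s,
configurable; existing boundaries are preserved; idempotent). The only
anchor available for the threshold is that multi-second pauses mark planning
breaks, so 1.0 s is a conservative default.

## The synthetic generative model

A small English-like PCFG (S/NP/VP/PP/SBAR over a 45-word lexicon, rule
probabilities calibrated analytically so the expected sentence length is
≈9.4 words, the mean of spontaneous spoken recalls segmented at pauses;
derivations outside 2–40 words or deeper than the cap are resampled) yields
i.i.d. trees. Dependencies come from deterministic head percolation (S→VP,
VP→V, NP→N, PP→P, SBAR→S), so the sentence root is the main verb.
Timings: `duration = 0.2 s · n_syllables · lognormal`, within-sentence
`pause = 0.08 s · exp(0.1 · TD(w)) · lognormal` clipped below the
segmentation threshold, inter-sentence pauses always above it — so
segmentation recovers the generative boundaries exactly, by construction.
Covariates: Zipf-assigned log frequency per lexicon word and a toy unigram
surprisal (the real pipeline ingests transformer surprisal as a column; the
toy version exists only so synthetic tables have a realistic covariate).

BOLD truth: `y = Σ_j (β_j + b_pj) x_j + ε` per ROI with
`b_pj ~ N(0, 0.3²)` on the structure-building slopes, AR(1) ε (ρ = 0.3,
sd 1) independent across ROIs, and default betas on the scale of published
encoding-model estimates (word rate 1.0, syllables 0.3, frequency 0.3,
surprisal 0.5, open nodes 0.3, top-down 0.9, bottom-up −0.35, boundaries
∓1.4). The `timing_model` switch (`standard_td` / `early_td` / `chunked`)
selects which structure-building regressor carries the top-down beta, so
the AIC model-recovery experiment can be run in every direction. The
simulator *reuses* the analysis convolution code for its truth design —
asserted column-for-column in the tests — so recovery failures cannot hide
reimplementation drift; everything is bit-deterministic under a fixed seed.

What the generator does **not** emulate: disfluencies and parse errors,
lexical/semantic covariate structure, between-ROI signal correlations,
scanner drift and motion artifacts, and modality differences in noise.
Passing recovery tests therefore demonstrates the correctness and
calibration of the estimation machinery under the stated generative model,
not robustness to real-data pathologies.

## Validation studies and problem sizes

- Tree metrics: 1,000 random trees, exact conservation / oracle equality /
  open-nodes identity.
- Encoding recovery: 100 studies of 20 participants × 3 ROIs × 300 scans;
  coverage of truth within ±3 SE and absolute bias < 0.05.
- Type-I calibration: 500 reduced-size studies (8 participants × 1 ROI ×
  200 scans); a white-noise word-level regressor should reject at 5% ± 2.
  200-scan series are the smallest at which AR(1) estimation noise no
  longer inflates the rate.
- Model selection: 16 participants × 3 ROIs × 600 scans (the production
  sample size of the recall datasets and a ~15-minute recall), 100 seeds
  per generating direction. The TD-generated direction recovers at ~94%.
  The early-TD direction reaches ~86%: after convolution the chunked
  regressor correlates 0.985 with early-TD on this corpus, and the
  occasional losses are one-to-two-AIC-unit coin flips; pushing recovery
  above 90% would need roughly twice the scan count. This residual
  confusability is a real property of the three-way comparison at this
  scale, and is reported rather than hidden.
- Pause model: 100 studies of 10 speakers × 60 sentences for γ = 0.1
  recovery; 400 reduced studies for the γ = 0 null rate.
- Numerical tolerances: convolution linearity/superposition at 1e−10,
  TR-shift at 1e−8, design determinism bit-exact, OLS agreement of the
  zero-variance mixed model at 1e−4.

## Known limitations

- The mixed-model t/Wald inference uses a normal approximation; with few
  participants and weak within-participant information it would need
  Satterthwaite-style corrections.
- AR(1) is the only residual model; physiological noise with longer-range
  structure is out of scope.
- The chunked strategy's trailing-node attribution (to the last head) is a
  conservation-preserving convention; alternative conventions would change
  per-word values but not totals.
- The syllable counter is an orthographic heuristic; a pronunciation
  dictionary can override it per word.
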