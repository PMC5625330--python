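# Methods

## The guessing null

The quantity of interest is the number of source errors a participant
would commit **if test-phase output were generation, not retrieval**: the
participant produces plausible actions for each cue, drawn from the
population's action-frequency profile, and some of those happen to
coincide with the non-target source's actions.

Per cue, frequency norms are the empirical distribution of coded actions
over *all* generation events of the experiment. Two choices matter here:

- **Duplicated actions count toward the norms.** Partner-duplicated
  actions are removed from the pair's *encoding sets* before coding (an
  action performed by both members carries no source information), but
  each occurrence still contributes to the population frequency profile —
  the norms describe the action space, not one pair's filtered history.
  Both behaviours are independent code paths and can be changed at the
  call site.
- **Sampling is without replacement** (a participant reports an action at
  most once), realized by the exponential-race construction
  (Efraimidis–Spirakis keys `Exp(1)/p_i`, keep the k smallest), which is
  distributionally identical to successive draws with renormalization of
  the remaining mass and vectorizes across replicates. Its law is checked
  against an exact subset-recursion enumeration on supports ≤ 12.

For each participant, each cue contributes its *reported* count of
distinct actions (first report counts; re-performances are ignored; counts
are truncated to the cue's support size with a warning). Per replicate the
draws are classified against the participant's duplicate-filtered own and
partner sets; the per-replicate error ratio is
`SE / (SE + novel)`. Replicates with no simulated errors (0/0) carry no
information about the composition of errors and are **excluded** from the
mean; their count is reported (`n_degenerate_reps`). The default is 500
replicates; estimator agreement with exact enumeration is tested at
50,000.

The prediction applies the estimated error-composition odds to the
participant's observed intrusions:
`predicted = intrusions_observed × ratio / (1 − ratio)`. Two guards: if
every replicate is degenerate the prediction is 0 (with a flag); if the
ratio saturates at 1 (no novel outcome exists, e.g. the pair's actions
exhaust the support) the prediction is undefined (NaN, flagged) and the
participant is dropped from downstream contrasts. Observed intrusions
*outside* the experiment's action inventory still count toward
`intrusions_observed` even though the simulation's action space cannot
produce them; the method treats every intrusion as a popularity-driven
guess.

### Finite-sample conservativeness of self-estimated norms

The norms include the focal participant's own and partner's generation
events. In a small experiment this self-inclusion is material: with 4
pairs and 5 cues a participant's pair contributes ~25% of each cue's norm
counts, inflating the simulated probability of matching the pair's own
actions, hence the ratio, hence the prediction. The net effect under a
true null (pure guessing) is **over-prediction of source errors** —
observed-minus-predicted is biased slightly negative and the one-tailed
test is conservative (measured rejection rates 0.00–0.02 at α = .05 for
4–18 simulated pairs). Supplying norms estimated without the focal pair —
or the generator's true popularity in simulations — restores nominal α
(measured 0.040 over 500 replicate experiments). At realistic sample
sizes the pair's share of the norms (~5%) makes the bias negligible: with
200 synthetic participants the mean observed-minus-predicted difference
under pure guessing is within 2 SE of zero. The conservative direction
means the method never manufactures spurious memory-error effects.

## Inference layer

- **Paired one-tailed t** (observed > predicted), `d_av` effect size:
  mean difference over the average of the two condition SDs (switchable
  to `d_z`, the mean over the SD of differences). Degenerate inputs
  (zero-variance differences) return flagged results rather than NaNs.
- **Two-way mixed ANOVA** by the classical sums-of-squares decomposition:
  the between factor is tested against subjects-within-groups, the
  within factor and interaction against the within-error term; partial
  η² per effect. Requires complete within-subject cells (listwise
  deletion is the caller's responsibility). Verified against
  `pingouin.mixed_anova` on 50 random balanced designs to 1e-8.
- **Within-subject CIs** use the Cousineau–Morey procedure:
  subject-centring, grand-mean restoration, bias correction
  √(C/(C−1)), t-based half-widths.
- **Standardized mean change** per study: `smc = mean(d)/sd(d)` with
  change-score variance `1/n + smc²/(2n)`; pooling is inverse-variance
  fixed-effect (no heterogeneity statistics by design). Forest data (per
  study effect, 95% CI, normalized weight, summary row) are emitted as
  CSV; rendering is left to the user.
- **Bayes factors** follow the one-tailed half-normal calculator: normal
  likelihood in the effect parameter (data mean, SE), alternative prior
  half-normal with mode 0 and a scale taken from a prior study's effect;
  BF10 = marginal likelihood over likelihood at zero. Computed in closed
  form (product of normals × normal-CDF truncation factor) and by
  adaptive quadrature on a mode-shifted log-scale integrand; both values
  are stored and agree to 1e-6 in log-BF across the tested grid. All
  arithmetic is in log space, so extreme inputs (|mean|/SE ≫ 1) degrade
  to ±inf BF only at the final exponentiation.
- Against rounded published summary inputs the calculator reproduces the
  two replication Bayes factors (0.31 vs. printed 0.32, and 0.29); the
  third printed value (15) is not recoverable from its rounded inputs —
  closed form gives ≈ 12.95 — which is consistent with the original
  computation having used unrounded effect estimates. It is asserted as
  ≈ 13 in the tests and documented here rather than treated as a target.
- No multiple-testing correction is applied to the step-down paired
  tests, mirroring the analysis design the pipeline implements.

## Synthetic experiment generator

The generator emulates the paired design end to end and is the ground
truth for recovery tests. Defaults are the standard study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_shapes` | 15 | cue symbols (A, C, F, … =) |
| `support_range` | 20–40 | distinct coded actions per cue |
| popularity | zipf, s = 1 | skewed action popularity (Dirichlet optional) |
| `exemplars_per_shape` | 3 | actions per member per cue (4 in load designs) |
| `p_self_repeat` | 0.005 | self-duplication per draw (~0.5%) |
| `p_partner_duplicate` | 0.013 | partner-copy per draw (~1.3%; an order of magnitude higher in naive/load settings) |
| `p_retrieve_own` | 0.55 | per-item retrieval of own actions |
| `p_retrieve_partner` | 0.40 | per-item retrieval of observed actions |
| `p_source_confusion` | 0.15 | retrieved item attributed to the wrong source |
| `guess_rate` | 0.5 | Poisson guesses per cue at test |
| `p_guess_outside_inventory` | 0.10 | a guess is a true novel (outside the inventory) |
| `monitoring_strictness` | 0.8 | extended mode: a wrong-source candidate is caught and withheld |
| `load_encoding_penalty` | 1.0 | multiplier on partner-item retrieval for cues observed under load |

Retrieval/guessing defaults were chosen once so that default runs land in
the empirically typical ranges (roughly 20+ correct recalls, 4–8 source
errors and 5–8 intrusions per participant in the 3-exemplar design); they
are not fitted to any dataset. Generation interleaves the two members per
cue; fresh actions are drawn popularity-weighted from the pair's unused
codes, duplication branches re-draw from the own/partner used sets. At
test each encoded item is retrieved independently (no output
interference or retrieval dynamics), misattributed with
`p_source_confusion`, and reported if the attributed source matches the
task; in extended-report mode everything retrieved is performed and the
verbal source judgement is recorded, with wrong-source candidates caught
at `monitoring_strictness`. Guesses reuse the popularity distribution,
excluding codes already output for that cue.

What the generator deliberately does **not** model: action semantics or
visual similarity structure, output-order dependence, participant-level
heterogeneity in retrieval or guessing rates, and any cognitive mechanism
behind source confusion (it is a flat mislabeling probability). Passing
calibration tests therefore show that the pipeline recovers the *model's*
guessing process, not that real recall obeys it.

## Pipeline and determinism

`run_analysis` executes coding → guessing null → inference, writing
`counts.csv`, `predictions.csv`, `summary.csv` (per-task/condition
mean/SD of the three response categories), `effects.csv`, `ttests.csv`,
`duplication.csv`, `norms.json`, optional `anova.csv`, and a
`manifest.json` with the config hash, seed, package and library versions
and timing. Conditions are derived from the load labels on generation
events (per-cue schedule); per-condition cells are analyzed alongside the
pooled cell when more than one label is present. Every participant gets an
independent, stable RNG substream derived from the run seed
(`SeedSequence([seed, index])`, folded below 2³¹), so reruns are
byte-identical and participant order cannot leak randomness. Failures
abort with the stage name rather than emitting partial outputs.

Problem sizes used in the shipped tests — 200 synthetic participants for
calibration, 500 replicate experiments of 4 pairs for the α-calibration
of the end-to-end null, 50,000 replicates for estimator-vs-enumeration
agreement, 5,000 simulated nulls for the t test's type-I rate — were
chosen to give the relevant binomial/Monte-Carlo bands a few percent of
slack.
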