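# Methods

This note documents the models and procedures implemented in `edtribes`,
the assumptions behind them, the synthetic data they are validated on, and
the numerical choices that were genuinely open.

## The analysis problem

Two communities coexist on a general-purpose photo-sharing platform:
pro-ana users, who post content encouraging eating disorders, and
pro-recovery users, who frame eating disorders as diseases.  The analysis
asks three questions.  First, how separated are the communities across four
interaction channels — directed contacts, comments, favorites, and tag
vocabulary?  Second, does either community imitate the other's tagging to
gain visibility?  Third, is receiving comments from the opposite community
associated with a user stopping (or continuing) to post harmful content?

All statistics operate on five linked record tables (users, photos,
comments, contacts, favorites).  Favorites carry no timestamps, because the
platform interaction they model exposes none; no analysis requires one.
View counts are static per photo and are credited at the photo's posting
time wherever a time-resolved covariate needs them.

## Community labels and agreement

Users are labeled by averaging 1–5 Likert scores from independent raters
(5 = strongly pro-ana, 1 = strongly pro-recovery).  Mean ≥ 3.5 maps to
pro-ana, ≤ 2.5 to pro-recovery, otherwise neutral; the cut points are
configuration values because no canonical ones exist.  Agreement is
reported as mean pairwise Cohen's κ over rater pairs after discretising
each rater's scores with the same cut points — the most common reading of
"kappa" for several independent raters — with Fleiss' κ as an option.  The
p-value is a permutation test (each rater's column shuffled independently);
it is exact in distribution but Monte-Carlo in resolution (500 permutations
by default).  A single identical category across all raters leaves κ
undefined and is signalled explicitly rather than returned as a number.

## Relevant tags and photos

"ED content" is every photo owned by a community-labeled user; the neutral
baseline is photos owned by neutral-labeled users.  A tag is selected as
highly relevant iff its total occurrence count reaches `min_support`
(default 3, suppressing singleton noise in the solely-in rule) and either
it never occurs in neutral content or its photo-level occurrence rate in ED
content is at least `ratio_threshold` (default 10, inclusive) times its
neutral rate.  Indicative-tag ranking uses user-level prevalence — the
fraction of a class's users who used the tag at least once — with add-one
smoothing on user counts; user-level prevalence (rather than photo counts)
makes the ranking invariant to a single prolific user reposting a tag.
Tag "variations" (thinspiration/thinspo, pro-ana/pro-anorexia) are explicit
configuration lists; no stemming is attempted.

Monthly volume series are binned by UTC calendar month; the Spearman
correlation between the two class series uses months where either class
posted at least one relevant photo.  Rank statistics use average-rank tie
correction throughout (scipy implementations).

## TF-IDF similarity and the tags network

Documents are bags of tags — photos for photo-level comparisons, users
(concatenated photo tags) for the tags network.  Weights are
tf(t, d) · ln(N / df(t)) with natural log and no smoothing; df is computed
on the collection being vectorised.  Cosine similarity is 0 by convention
when either vector has zero norm.  Mean pairwise similarities within and
between classes are computed in closed form from sums of unit vectors
(algebraically identical to averaging all pairs); cells with more than
`max_pairs` (default 2×10⁶) pairs fall back to a seeded uniform pair
sample, and the report records which mode was used.  Rank-sum p-values
between cells are computed on seeded pair samples and are descriptive only:
pairs sharing a document are not independent.

The tags network links users whose cosine similarity reaches a threshold.
The reference analysis describes the cut as a "distance greater than 99%",
which is internally inconsistent (high distance would mean *dissimilar*);
this package reads it as cosine **similarity** > 0.99.  A `calibrated` mode
instead chooses the threshold by order statistic so the edge count matches
a target (by default the contact network's edge count) within ±5%,
signalling infeasibility when ties prevent it.

## Interaction networks and neighbor-based prediction

Comments map to commenter → photo-owner edges weighted by comment count,
favorites to favoriter → owner edges, contacts as stored; self-edges are
dropped and nodes are restricted to community-labeled users (isolates
kept).  In-class fractions are weighted: for each source class, the edge
weight landing on the same class over all its out-edge weight, with a χ²
test (1 df, no continuity correction) on the weighted 2×2 table.  The
favoriting preference ratio is the pro-ana users' share of favorites to
pro-ana photos divided by their share to pro-recovery photos, reported as
the raw share ratio.

Neighbor scores count distinct neighbors (union of in- and out-neighbors)
by default; a weighted variant counts interaction weight instead, since the
reference analysis does not say which it used.  The score
(#pro-ana − #pro-recovery neighbors) predicts pro-ana membership, assessed
by the ROC area computed with the midrank (Mann-Whitney) formulation: tied
pairs receive half credit.  Isolated users are included with score 0 and
their count reported — excluding them is a defensible alternative, and the
report makes the choice visible.

## Cessation

A community user *ceases* when at least `gap_days` (default 90, the
deterministic reading of "three months") pass after their final relevant
photo while at least one non-relevant photo is posted in that window — the
continued posting distinguishes stopping harmful content from abandoning
the platform.  Users with no posts of any kind after their final relevant
photo are classed *abandoned* and excluded from cessation rates.  Users
whose observation tail after the final relevant photo is shorter than the
gap are *censored*.

The follow-up table's unit is a relevant photo with at least one comment
from a labeled community user.  Attribution is non-exclusive by default (a
photo commented by both classes counts in both commenter columns); an
exclusive mode is provided because the underlying definition is ambiguous.
A photo counts as followed by cessation iff its poster ceased; photos of
censored posters count as not followed (the poster was still posting
relevant content at the horizon).  Days-to-cessation is measured from the
photo's posting date to the poster's final relevant photo — the leading
interpretation of an underspecified quantity, recorded here deliberately.

## Hazard models

The event is "the user posts a highly relevant photo in the next 10-day
interval".  Every community user contributes one at-risk row per interval
from their first photo to the observation end (Andersen–Gill counting
process; events recur; no frailty term).  Six covariates are computed from
data strictly before the interval start: counts of relevant photos, views,
views of relevant photos, received comments from same-class and other-class
users, and the same-class fraction of received comments (0 when none — a
convention, recorded).  Each covariate exists cumulatively and over the
preceding 30 days; the two feature sets are fitted separately per class
(four models), because the corresponding coefficient tables in the
literature are printed separately — a combined fit is a configuration away.
Covariates are log(1+x) transformed (including the fraction) and z-scored
within the fitting population; zero-variance covariates are dropped with a
recorded warning.

The partial likelihood uses Breslow tie handling by default — the standard
cheap choice when a coarse grid makes ties heavy — maximised by a Newton
solver written for this grouped structure (risk set at an event time is
exactly the rows of that interval, so per-interval sufficient statistics
S₀, S₁, S₂ give the gradient and Hessian directly).  Step-halving guards
the ascent; separation is signalled when ‖β‖ diverges.  Standard errors
come from the inverse observed information; p-values are Wald.  The solver
was verified against R's `survival::coxph(ties="breslow")` on identical
panels (agreement to 6 decimals; frozen in the test suite).  Efron tie
handling delegates to lifelines' `CoxTimeVaryingFitter`.

## The synthetic-data generator

The generator is the package's validation instrument: it emulates the study
conditions with planted parameters, so recovering them end-to-end is the
acceptance surface.

* **Users** join on a 10-day grid over a multi-year span (default
  150 pro-ana, 150 pro-recovery, 200 neutral — roughly one fifth of the
  scale of the community studies this package supports, keeping the default
  pipeline interactive).  Per-user photo volumes are lognormal with
  per-class medians (pro-recovery ≈ 1.9× pro-ana, echoing the observed
  activity asymmetry); a monthly growth multiplier (default 1.03) trends
  posting intensity upward.
* **Relevant posting** is a per-interval Bernoulli event with probability
  1 − exp(−h₀·exp(β·(x − x_ref))), where x are the log(1+x)-transformed
  hazard covariates of the user's own generated history and h₀ derives from
  the per-class baseline `relevant_fraction`.  This makes hazard-coefficient
  recovery well-posed *on the log1p scale*: recovery tests fit without
  z-scoring, because standardisation rescales Cox coefficients by each
  feature's standard deviation.  A planted fraction of users (default 0.5)
  additionally stops relevant posting at a random time while continuing
  other posting, seeding genuine cessation events.
* **Tags**: relevant photos draw from the owner class's signature + shared
  ED vocabulary; pro-recovery relevant photos additionally carry pro-ana
  signature tags with probability 0.30 (the visibility-seeking overlap the
  similarity analysis is designed to detect; 0.05 in the reverse
  direction).  Background tags are Zipf-weighted over a generic vocabulary;
  self-portrait tags are sprinkled with class-specific rates.
* **Homophily**: comments, contacts and favorites are generated
  source-first — choose the acting class, make the interaction in-class
  with exactly the planted probability, then pick a concrete target —
  so the planted parameter *is* the source-side in-class fraction the
  analysis measures.  Contacts sample targets without replacement so edge
  deduplication cannot bias the fraction.  Defaults mirror the qualitative
  pattern of interest: contact homophily (0.59, 0.72), comment homophily
  (0.74, 0.83), favorite homophily (0.89, 0.56).
* **Views** are negative-binomial with user-level lognormal multipliers; in
  the direct panel simulator an extra per-photo lognormal dispersion keeps
  the view covariates identifiable next to the photo-count covariates.
* Neutral users post background tags only and interact without homophily —
  a modelling convenience; their quantitative behaviour is not part of any
  claim.

What the generator does **not** emulate: comment text, image content,
bursty or circadian posting, users switching communities over time,
rater-specific bias structure (noise is i.i.d. uniform), and
platform-mediated feedback (e.g. recommender exposure).  Passing tests
therefore demonstrate that the estimators recover planted structure of this
kind, not that real platform data satisfies the generator's independence
assumptions.

A dedicated `simulate_hazard_panel` generates the counting-process panel
directly (no corpus materialisation) for coefficient-recovery studies, and
`sign_pattern_preset` plants opposite short-term responses to cross-class
comments (+0.8 for pro-ana, −0.8 for pro-recovery on the recent
other-class-comment covariate) so the four-model fit can be shown to
recover an entrenchment-style sign pattern.  Both presets' reference
vectors and rates were chosen once for rate stability and identifiability
and are documented as illustrative.

## Determinism and problem sizes

A single pipeline seed fans out to per-stage seeds through SHA-256 of
`"{seed}:{stage}"`, so stages are independently reproducible; the report
carries a SHA-256 hash of its results section, and two runs with the same
corpus, configuration and seed are hash-identical.  Default problem sizes —
500-user corpora for end-to-end runs, 800 users × 100 intervals for
coefficient recovery, 110 + 110 users with inflated interaction rates for
homophily recovery (≥10,000 interactions per channel) — were chosen as the
smallest sizes at which the stated tolerances are comfortably inside
sampling error for the statistics involved.

## Known limitations

* The Breslow solver assumes the grouped-interval risk structure; it is not
  a general Cox implementation with staggered entry.
* Discrete-time Bernoulli events approximate the continuous-time hazard;
  with per-interval event probabilities around 0.1–0.2 the attenuation of
  fitted coefficients is small but not zero, and it is absorbed into the
  recovery tolerance.
* Pair-similarity rank-sum p-values ignore pair dependence (flagged in the
  report); treat them as descriptive.
* The per-image follow-up table inherits every ambiguity of the cessation
  definition; both attribution modes are provided, and the per-user event
  table returned by `detect_all_cessation` supports user-level sensitivity
  re-aggregation directly.
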