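# edtribes

Analysis toolkit for antagonistic health communities on photo-sharing
platforms — specifically the "pro-ana" community (users creating and
disseminating content that encourages eating disorders) and the
"pro-recovery" community (users presenting eating disorders as diseases to
recover from).  The package is aimed at computational social scientists and
infodemiology researchers who want to quantify how two such communities
interact: who talks to whom, who imitates whose vocabulary, and whether
cross-community contact is associated with users stopping to post harmful
content.

Because platform data of this kind cannot be redistributed, the package
ships a first-class synthetic-corpus generator with planted ground truth
(community memberships, homophily levels, tag distributions, cessation
events, hazard coefficients), so every stage of the analysis can be
validated against known parameters.

## What it computes

Given a corpus of users, photos (with tag lists, timestamps and view
counts), comments, directed contacts and favorites:

* **Cohort construction** — four seed-user rules (term search in
  tags/titles/descriptions, group uploads, commenting on qualifying photos,
  favoriting specific tag combinations), aggregation of 1–5 Likert ratings
  into class labels, and a chance-corrected inter-rater agreement
  coefficient κ = (p̄ₒ − p̄ₑ)/(1 − p̄ₑ) (mean pairwise Cohen, or Fleiss)
  with a permutation p-value.
* **Relevant content** — a tag *t* is "highly relevant" iff it occurs solely
  in community-owned photos or its occurrence rate there is ≥ 10× its rate
  in neutral users' photos; photos carrying such a tag are flagged.
  Class-indicative tags are ranked by the ratio of user-level prevalences
  P(t | class), and monthly posting-volume series are compared by Spearman
  rank correlation.
* **Tag similarity** — photos or users as bags of tags under the vector
  space model with weights tf(t, d) · ln(N/df(t)); cosine similarity within
  and between communities; an undirected "tags" network linking users whose
  profiles exceed a similarity threshold (calibratable to a target edge
  count).
* **Interaction networks** — contacts, comments and favorites as weighted
  directed graphs over labeled users; weighted in-class fractions with a χ²
  test; the pro-ana favoriting preference ratio; and neighbor-based class
  prediction (score = #pro-ana neighbors − #pro-recovery neighbors) scored
  by the area under the ROC curve with midrank tie handling.
* **Posting cessation** — a user ceases when ≥ 90 days pass after their
  final relevant photo while they continue posting other photos (shorter
  observation tails are censored); per-image follow-up tables break
  cessation rates and days-to-cessation down by poster class × commenter
  class.
* **Time-varying hazards** — an Andersen–Gill counting-process panel on a
  10-day grid with six covariates (relevant-photo, view and received-comment
  histories, cumulative or 30-day-recent), log(1+x)-transformed and
  z-scored, fitted by maximizing the Cox partial likelihood
  (Breslow ties via a dedicated Newton solver; Efron via lifelines) for the
  event "posts a highly relevant photo in the next interval".

## Worked example

```python
from edtribes import GeneratorParams, generate_corpus
from edtribes.cohort import labels_from_truth
from edtribes.networks import build_network, inclass_fractions, neighbor_scores, network_auc

corpus, truth = generate_corpus(GeneratorParams(), seed=1)
labels = labels_from_truth(truth)

g = build_network(corpus, labels, "comments")
s = inclass_fractions(g, labels)
print(f"in-class comments: pro-ana {s.frac_pa:.1%}, pro-recovery {s.frac_pr:.1%}")
print(f"comments AUC: {network_auc(neighbor_scores(g, labels), labels):.2f}")
```

prints

```
in-class comments: pro-ana 73.1%, pro-recovery 82.8%
comments AUC: 1.00
```

i.e. with planted comment homophily (0.74, 0.83) the measured in-class
fractions recover the planted values to within sampling error, and the
neighbor-difference score separates the two communities essentially
perfectly on this corpus.  The full pipeline is one call (or
`edtribes all --out run/ --seed 1` from a shell):

```python
from edtribes.pipeline import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(seed=1))
print(report["results"]["cessation"]["followup"]["rates"])
```

```
{'pro_ana|pro_ana': 0.358..., 'pro_ana|pro_recovery': 0.343...,
 'pro_recovery|pro_ana': 0.369..., 'pro_recovery|pro_recovery': 0.340...}
```

— the fraction of commented relevant photos followed by the poster's
cessation, by poster class and commenter class (with the default generator
no differential comment effect is planted, so the four cells agree).

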