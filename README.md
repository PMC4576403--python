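# cytogi

Automated flow-cytometry gating, leukocyte population queries, the
**Granularity Index** biomarker, and the cutoff/stratification statistics
for biomarker-guided treatment choice — with a synthetic-data generator so
the whole pipeline is testable without access to patient-level trial data.

## The problem

In ANCA-associated vasculitis (AAV), both rituximab (RTX) and
cyclophosphamide (CYC) induce complete remission in only 50–65 % of
patients, and no routine clinical marker predicts which drug will work for
whom. Whole-blood flow cytometry measured at the screening visit carries a
candidate signal: the side-scatter (SSC) profile of the granulocyte
compartment. Granulocytes split into a *hypergranular* population (maximal
SSC) and a *hypogranular* population (intermediate SSC), and the signed
difference of their abundances,

```
GI = %hypergranular − %hypogranular      (of all white blood cells, −100 % … +100 %)
```

behaves as a treatment-selection biomarker: patients with high baseline GI
remit more often on rituximab, patients with low GI more often on
cyclophosphamide.

`cytogi` implements the full analysis chain for this kind of study:

1. **Auto-gating** (`cytogi.autogate`) — a density-based clustering stage in
   the "clustering without K" family: events are binned on an equal-width
   grid per channel (default 12 bins), bins above a density threshold
   (default 0.1 % of events) are merged by Chebyshev-adjacent connected
   components, every remaining event attaches to the nearest dense-bin
   centroid, and each cluster is summarized as per-channel ordinal levels
   1–4 (1 = negative, 2 = low, 3 = positive, 4 = high, normalized within
   each file) plus its percentage of all events.
2. **Population queries** (`cytogi.popquery`) — rule-based predicates over
   level vectors (e.g. lymphocytes: `FSC ≤ 2 AND SSC = 1`), with the ten
   standard populations built in.
3. **Granularity Index** (`cytogi.granularity`) — GI per sample and the
   baseline join to clinical records.
4. **Statistics** (`cytogi.stats`) — exact two-tailed Fisher tests (integer
   hypergeometric enumeration), positive likelihood ratios with log-method
   95 % CIs, tie-corrected Kruskal–Wallis, Pearson r², Youden-index optimal
   cutpoints (J = sensitivity + specificity − 1), three-band stratification
   with per-band between-arm tests, and a profiled-design projection of the
   overall remission rate if each outer band received its favored arm.
5. **Synthetic cohorts** (`cytogi.synth`) — Gaussian-mixture event clouds
   (lymphocytes, monocytes, two granulocyte subsets, debris) whose
   granulocyte split realizes a per-patient latent GI, with arm-specific
   logistic outcome models; plus FCS 3.1 writing (`cytogi.fcs` reads 3.0/3.1).

## Worked example

From published per-band contingency counts of a 187-patient two-arm cohort
(`python examples/04_published_counts_statistics.py`):

```
GI < -9.25 flags RTX failure  LR  4.12  95% CI  1.74- 9.72
GI < -27   flags RTX failure  LR  8.82  95% CI  2.05-37.95
GI > 47.6  flags RTX success  LR  2.83  95% CI  1.20- 6.72
GI > 47.6  flags CYC failure  LR  2.13  95% CI  1.07- 4.25

   low band  n=44   RTX  30%  CYC  67%  p=0.03286
middle band  n=86   RTX  66%  CYC  55%  p=0.3782
  high band  n=57   RTX  83%  CYC  33%  p=0.0001555

Profiled design (low band -> CYC, high band -> RTX): 108/187 observed
remissions (58%) -> 129/187 projected (69%), p = 0.0317
```

Reading: a GI below −9.25 % makes failure on rituximab 4.12× as likely
(flagging 14/34 failures vs 6/60 remitters); in the low-GI band
cyclophosphamide beats rituximab (67 % vs 30 % remission, Fisher p = 0.033)
while the high-GI band reverses (83 % vs 33 %, p = 0.0002); assigning each
outer band its favored drug projects the overall remission rate from 58 %
to 69 %.

The other examples simulate data end to end — `examples/05_full_pipeline.py`
generates a 187-patient cohort with opposed arm effects, auto-gates every
sample, recovers band cutoffs by per-arm Youden optimization and prints the
stratified report. A thin CLI wraps the same stages:

```bash
cytogi simulate --n-patients 50 --out demo_data
cytogi gate demo_data/fcs --out gating.csv
cytogi gi gating.csv --out gi.csv
cytogi analyze gi.csv demo_data/clinical.csv
cytogi run-all --seed 1 --out demo_out      # everything in one step
```

## Layout

```
src/cytogi/        library (events, fcs, synth, autogate, popquery,
                   granularity, stats, clinical, pipeline, cli)
examples/          one short narrative script per capability
tests/             pytest suite, including independent oracles
docs/methods.md    models, assumptions, parameter choices, limitations
```
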