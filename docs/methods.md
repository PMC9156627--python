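# Methods

## Data model

One observation ("unit") is a single patient-semiology: an opaque patient
identifier (unique within an article), the article it came from, the reported
free text and/or its category, a multi-one-hot allocation over brain-region
nodes, three Boolean ground truths (postsurgical seizure-freedom for ≥12
months; imaging–neurophysiology concordance; invasive SEEG/stimulation
localization), a study-design label, and age/laterality metadata. A record is
accepted only if at least one ground truth holds; rows failing this are
collected as validation errors, never silently dropped. Duplicate
(patient, semiology) rows are merged by summing allocations, with a warning —
the source literature occasionally reports the same patient twice and no
principled de-duplication exists beyond identity of the keys.

The study-design label drives bias mitigation. *Topological* units come from
articles that preselected patients by a prespecified brain region — surgical
series of a known lobe, or cortical stimulation of chosen sites — and
therefore carry prior knowledge of the seizure focus. All other units are
*non-topological* (spontaneous-semiology studies). A unit is topological iff
its label is `epilepsy_topology` or `stimulation`; `spontaneous` marks the
non-topological subset.

## Region hierarchy

Eight fixed top-level regions (temporal, frontal, parietal, occipital,
cingulate, insula, hypothalamus, cerebellum); the temporal lobe carries five
named subregions (mesial, anterior, lateral, posterior, basal); further
descendants may be added freely from a YAML definition. Interlobar junction
categories (frontotemporal, temporo-parietal, …, perisylvian) are data-entry
conveniences: before any analysis their weight is redistributed over their
constituent top-level lobes. The split is **equal** (`w/k` over `k`
constituents) — the maximum-entropy choice in the absence of any stated
proportions — and conserves total weight exactly. Perisylvian is taken as
{frontal, temporal, parietal}, the lobes bounding the Sylvian fissure. The
subcallosal cortex is standalone: never redistributed, excluded from the
seven-region forest reports, included in the normalizing denominator of the
regional prior.

Allocations are stored at the most specific node only; the weight at a lobe
is always computed by rolling up the node plus all descendants at query time.
This resolves the ambiguity of records naming both a lobe and its subregion
without ever double-counting a hierarchy path.

## Normalization

The unit of analysis is one patient-semiology summing to one: after junction
redistribution, each unit's allocation vector is divided by its total.
Consequences: (i) a semiology reported to localize to k regions contributes
1/k per region, penalizing multifocal reports; (ii) a semiology's total
weight equals its patient count, so denominators of conditional probabilities
are patient counts. Raw counts above one on a node (merged duplicates) are
handled by the same proportional division. Normalization runs *after*
junction redistribution so a junction counts as its constituents, not as one
region.

## Queries

`p(region | semiology)` is the mean over the subset's units of the unit's
rolled-up weight at the region. 95% CIs are percentile intervals (2.5/97.5)
over 10,000 bootstrap resamples of the units, drawn with replacement.
The resampling unit is the (patient, semiology) unit within the queried
subset — not the article and not the raw data point — consistent with the
normalization's unit of analysis. Internally a resample is drawn as a
multinomial over the distinct per-unit values, which is distributionally
identical to unit-level resampling at O(n_boot·k) instead of O(n_boot·n)
cost. All stochastic outputs carry their seed; per-cell seeds in tables are
derived from one master seed, making any table bit-reproducible.

Forest reports cover each eligible semiology × {seven top-level regions +
five temporal subregions} × {all data, non-topological}. Eligibility requires
at least 100 patients in **both** the topological and non-topological
subsets. Temporal-subregion probabilities are nested within the temporal
lobe, so only the 8-top-level + standalone partition sums to one.

The **EUD-Loc** prior pools all semiologies over one subset (normally
non-topological) and reports each top-level region's share of total weight,
with cerebellum + standalone folded into an `other` remainder so the output
sums to one.

## Relative odds ratios

For semiology S and region R the weighted 2×2 table over units is
`a = Σ_S rollup(unit, R)`, `b = n_S − a`, `c, d` analogously over all other
semiologies — including the infrequent ones, so the complement approximates
the regional prior. `OR = (a·d)/(b·c)`; if any cell is zero the
Haldane–Anscombe correction adds 0.5 to all four cells. CIs are percentile
intervals over pooled resamples of all units (S and non-S together, not
stratified); resamples that draw no S units (or only S units) carry no
information about the OR and are excluded. Significance means the 95% CI
excludes 1 (α = 0.05). Fully degenerate tables (everyone inside R, or no
complement) are flagged rather than suppressed. For top-level regions and
subregions alike the dichotomy is region-vs-everything-else.

## Synthetic cohorts

The generator emulates article structure and the topological selection
mechanism, not clinical free text (each category carries one template
phrase that its taxonomy rule matches) and not chronological seizure
evolution. Defaults encode the study conditions:

* semiology marginal: the published frequencies of the twelve most common
  categories (tonic 9.8% … somatosensory 2.9%; 65.5% combined), the
  remaining 34.5% split evenly over 23 rarer categories;
* true conditional matrix P(region | semiology): rows for the twelve
  categories shaped after the published non-topological forest estimates;
  the single row shared by the rarer categories is *solved* from the
  constraint that the mixture reproduce the unbiased regional marginal of
  44% temporal / 31% frontal exactly (remainder: parietal 7%, occipital 6%,
  cingulate 5%, insula 3%, hypothalamus 4% — the hypothalamus needs ≥3.5%
  for the solved row to stay non-negative, because the "other automatisms"
  row is hypothalamus-heavy). Cerebellum carries no mass, matching its
  absence from the seven-region reports;
* a topological article draws a focus region (75% temporal), samples each
  unit's category from the Bayes inversion P(s | focus) ∝ P(focus | s)·P(s)
  of the same truth, and pins the unit's localization to the focus — sharp
  preselection, since resection/stimulation studies know their region;
* 71% of articles are topological, so the pooled temporal share is
  0.29·0.44 + 0.71·0.75 ≈ 0.66 by construction;
* articles carry 5–40 patients (uniform; the literature gives no size
  distribution), patients carry 1–3 distinct semiologies, 20% of
  non-topological units localize to two regions (½/½), 60% of temporal
  allocations name a subregion (45/20/15/12/8% across
  mesial/anterior/lateral/posterior/basal — mesial-dominant, as in surgical
  practice);
* ground-truth flags are independent Bernoulli draws (0.5/0.5/0.3), redrawn
  until at least one holds; 5% of patients are children under 7 and 20%
  have unknown age; laterality is generated as unknown (lateralization
  analysis is out of scope); the stimulation / epilepsy-topology split
  within topological articles is 0.5.

Because topological units are pinned to the focus, the non-topological subset
is an unbiased sample of the conditional matrix while pooled estimates are
inflated exactly where the focus distribution exceeds the true marginal.
Passing tests therefore demonstrate correct bias *mechanics* under the
generator's assumptions; real literature data add heterogeneity the generator
does not model (correlated semiologies within patients beyond sampling
without replacement, region-dependent ground-truth quality, reporting noise
in the allocations themselves).

## Problem sizes used in the checks

The test suite and acceptance script choose cohort sizes by what each
estimate needs rather than one global size:

* bias direction, conservation and the pooled/unbiased temporal shares run
  at the default scale (222 articles, ≈5,000 patients, ≈10,000 units);
* max-cell recovery of P(region | semiology) runs at 4,000 articles
  (≈50,000 non-topological units): the smallest category holds 2.9% of
  non-topological units, and a 0.05 max-error band over 84 cells requires
  its per-cell sampling error to be ≈0.011 — roughly 1,500 units for that
  category — which a 5,000-patient cohort (≈85 such units, SE ≈ 0.05)
  cannot provide for any seed;
* the exactly-twelve eligibility check runs at 356 articles (≈16,000
  units), where the twelve common categories clear 100 patients in both
  subsets and the 23 rare ones stay below with >3σ margins on both sides;
* bootstrap calibration uses 500 replicate cohorts of 200 single-semiology
  units with 2,000 resamples; the null odds-ratio control uses 500
  replicates of 1,000 units (30% carrying the test semiology), a size at
  which the percentile bootstrap's small-sample undercoverage for ratio
  statistics has decayed.

## Numerical choices and degenerate inputs

Percentile CIs use `numpy.quantile` (linear interpolation). Normalization
tolerance is 1e-9; an all-zero allocation raises with the record identity.
A single-unit subset yields a degenerate CI equal to its point estimate; an
empty subset yields NaN cells in tables and an error in direct queries.
Probability vectors in configurations must sum to 1 within 1e-6. Seeds are
plain integers; every derived seed stays below 2^31.

## Known limitations

Pattern-based text classification covers the twelve common categories plus
postictal/asymptomatic out of the box; the full 35-category inventory is
data-driven and must be loaded from an extended taxonomy file for full
parity. Negation handling is a fixed cue list with a 3-token pre-window and
clause-punctuation barriers — sentence-level scope resolution is out of
scope. Lateralizing fields are modelled in the schema but no lateralization
statistics are computed. No multiple-testing correction is applied across
the semiology × region grid; significance flags are per-cell at α = 0.05.
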