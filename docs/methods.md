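# Methods

## Allelic-status calling

A carrier is germline-heterozygous, so the variant-allele fraction (VAF)
in normal tissue is ~0.5. In tumor DNA, loss of the wild-type (WT) allele
raises the VAF; loss of the variant allele lowers it. The caller applies
the imbalance rule with δ = VAF_tumor − VAF_reference:

* δ > t → loss of WT; δ < −t → loss of variant; otherwise balance,
  with threshold t = 0.10 by default and a **strict** inequality, so
  δ = 0.10 exactly is balance.

"Imbalance above 10%" is interpreted in absolute VAF units (not as a
ratio of allele ratios); this reproduces every call in the worked
family-1 set, including the 49%-VAF tumor called balanced. The reference
is the sample's measured germline VAF when available, else 0.5 with a
`NO_GERMLINE_REFERENCE` flag. Pyrosequencing samples are aggregated as
the mean of replicates (sample sd reported); a two-sample t-test of
replicates against a non-carrier control is computed as QC metadata but
never overrides the threshold rule, since no published interaction
between the two is defined. NGS samples use alt/total read depths, with a
`LOW_DEPTH` flag below 50× (configurable). Tumors with cellularity below
0.30 (strictly) are flagged `LOW_CELLULARITY` but still called.

## Purity model and detectability

Cellularity ρ (optionally attenuated by a multiplicative subclonal
fraction) dilutes the imbalance. Allele-copy counting over a mixture of
tumor and diploid heterozygous normal cells gives the expected VAF:

| event          | deletion          | copy-neutral LOH |
|----------------|-------------------|------------------|
| balance        | 1/2               | 1/2              |
| loss of WT     | 1/(2 − ρ)         | (1 + ρ)/2        |
| loss of variant| (1 − ρ)/(2 − ρ)   | (1 − ρ)/2        |

Under the 0.10 rule, loss of WT is detectable iff ρ > 1/3 (deletion) or
ρ > 0.2 (copy-neutral). Deletion is the default copy model: it is the
conservative choice (smaller expected imbalance at a given purity), and
it explains why a 30%-cellularity tumor with a true second hit can appear
balanced. The true copy-number state of the reference cohort's LOH events
is unknown; both models are provided, neither asserted.

## Synthetic cohorts

The simulator emulates the reference study's conditions: per variant
class a latent event is drawn (loss of WT / loss of variant / balance)
with class-conditional probabilities, then observed at a uniform random
purity through the expected-VAF model plus measurement noise —
binomial(read_depth, VAF) for NGS, Gaussian replicate noise (sd 0.02,
clipped to [0,1]) for triplicate pyrosequencing. Defaults are the
observed cohort rates (pathogenic 36/55 loss-of-WT and 3/55
loss-of-variant; benign group 6/27 and 4/27; VUS 10/15 and 1/15), purity
U(0.3, 0.9) matching the 30–90% cellularity span of the worked family,
NGS for 6/97 of samples, ovarian tissue for 7/97, read depth 1000
(typical deep amplicon sequencing; the study reports no depth), fully
clonal events. All draws flow from one `numpy` generator seeded by the
config, in a fixed order (event, purity, subclonal fraction, tissue,
method, noise), so cohorts are bit-reproducible. Clipping after Gaussian
noise (rather than truncated sampling) introduces negligible bias at
sd ≤ 0.05 away from the boundaries.

What the simulator does **not** model: FFPE artifacts, GC/mapping bias,
genome coordinates, intratumor mixtures of mechanisms, or correlated
tumors from one family. Passing recovery tests therefore show the
pipeline is self-consistent under its own generative assumptions, not
that real cohorts meet them.

## Cohort summaries

Per-variant rows carry counts (balance / loss-of-variant / loss-of-WT),
% imbalance, and % loss-of-WT among imbalanced tumors (undefined when no
tumor is imbalanced). Class totals pool pathogenic vs benign+likely-benign
vs VUS. Percentages are kept at full precision; the printed-style
rendering rounds half away from zero to integers (a one-decimal
truncating rendering is also provided, matching how 36/55 = 65.45% is
conventionally printed as 65.4%). Treating a loss-of-WT call as a
positive per-tumor prediction of pathogenicity gives the confusion matrix
(VUS excluded); breast and ovary are pooled by default, with per-tissue
options. The class association uses the 2×2 χ² test without continuity
correction (correction available). The missense-vs-truncating split
exposes its effect grouping as a parameter, because published per-effect
percentages can pool effects in more than one defensible way; only the
direction (truncating > missense) is asserted.

## Binomial evidence and decision tables

Across n independent tumors with the same variant, the loss-of-WT count
is X ~ B(n, p). The pmf is computed in log space via `gammaln` and tails
are exact pmf sums (no normal approximation — n is small by design;
stable to n ≥ 10⁴). Two tails are reported: P(X ≥ k | p_benign), the risk
that a benign variant would show the observed recurrence, and
P(X ≤ k | p_pathogenic), the risk that a pathogenic variant would show so
little. Default rates are the combined-cohort estimates p_benign = 6/27
and p_pathogenic = 36/55; breast-only alternatives (5/26, 32/51) are
provided as constants, and the strict 0.05% five-of-five result holds
under the breast-only benign rate.

Decision tables list, for each n, the smallest k whose benign tail falls
below the accepted risk (default α = 0.05; the class-2-grade strict level
is 0.05%) together with the pathogenic-side power at that k, and the
largest k whose pathogenic tail falls below 1% for excluding
pathogenicity. α = 1 is treated as the degenerate accept-everything
threshold. The qualitative suggestion (`classify_by_loh`) maps the tails
to strong (< 0.05%) or moderate (< 1%) exclusion of neutrality, exclusion
of pathogenicity (< 1%), or inconclusive; the 1% "moderate" boundary is
interpretive, chosen to mirror the ~1% zone in which a 3-of-3 or 4-of-5
recurrence falls. With the combined benign rate those two situations
evaluate to 1.10% and 1.00% — marginally above the strict 1% cut — while
under the breast-only rate both are moderate; users weighing borderline
recurrences should evaluate both rates. This framework is deliberately
**not** a hypothesis test and never returns a definitive class: tumors
are assumed independent (tumors from one family violate this mildly), p
is treated as known rather than estimated with uncertainty, and the
output is intended to prioritize variants for further evidence.

## Multifactorial combination

Component likelihood ratios multiply into odds for causality; the LR
product is accumulated as a sum of logs (`math.fsum`), so co-segregation
LRs far beyond float range are handled, and the posterior is computed
from the log-odds with the numerically stable logistic form. Default
prior 0.03 (the value used for the worked BRCT variants); priors are
variant-specific in practice and always overridable. Tier bands: 5 if
posterior > 0.99; 4 in [0.95, 0.99]; 3 in [0.05, 0.95); 2 in
[0.001, 0.05); 1 below 0.001 — band edges are inclusive on the lower
bound of each band, so 0.99 itself is class 4 and 0.05 is class 3. An
optional LOH likelihood-ratio component can be multiplied in; it is
labelled experimental because no calibration of LOH recurrence onto the
LR scale has been published. Internal computation of co-segregation,
pathology, family-history or co-occurrence LRs is out of scope: they are
inputs. Round-tripping odds → posterior → odds is exact to ~10⁻⁹
relative error while 1 − posterior is well away from machine epsilon;
at extreme odds the posterior saturates at 1.0 by design.

## Packaged reference counts

The packaged tables carry the 97-tumor reference cohort: per-variant ×
tissue call counts (conserving every row and class total), the five
family-1 tumors with cellularity and VAF, and the multifactorial inputs
for the two BRCT variants. Two published percentage cells disagree with
their own row counts (one variant's imbalance/loss-WT percentages and
another's 50% loss-WT for a 1-of-1 row); the package stores counts and
recomputes percentages, so those cells are reproduced as arithmetic
dictates, not as printed. One published multifactorial row (c.5497G>A)
is internally inconsistent — its printed odds match neither its LR
product nor its posterior — and is carried for reference but excluded
from numeric checks.

## Problem sizes in the test suite

Property tests enumerate all 2ⁿ outcome sequences up to n = 12 as the
binomial oracle; parameter-recovery runs use 500 simulated tumors (and
1,000 per class for the sensitivity/specificity recovery) at purity
≥ 0.6 and depth 500 — the regime where events are detectable by
construction, so that recovery measures the caller, not the purity
model. The full suite runs in a few seconds on one CPU.
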