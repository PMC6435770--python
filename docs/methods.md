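# Methods

## The CFDR / LAD statistic

A pedigree is a directed family graph of individuals with optional
father/mother links and a list of tumour records (site, integer age at
diagnosis, primary index). *Affected* means carrying at least one
LS-associated tumour — colorectal, rectal, endometrial, ovarian, gastric,
small bowel, or upper urinary tract cancer. Tumours at any other site are
retained in the data model but never counted: they do not confer affected
status and do not enter tumour counts or age minima. Rectal cancer is kept
distinct from colon cancer in the site enumeration because sporadic MMR
deficiency is rare in rectal tumours, making it a strong LS indicator, but
both are LS-associated for counting purposes.

**First-degree relatives** are parents, children and full siblings (both
parents shared and recorded). Half-siblings are second-degree; spouses are
never relatives.

**Branches.** Blood relationship is defined by shared ancestry (ancestor
sets inclusive of self intersect), so a spouse marrying in is unrelated
even though the parent-child graph connects them through the shared child.
A blood relative whose shared ancestors with the proband all lie on the
mother's side is *maternal*; on the father's side, *paternal*; the
proband, its descendants, and relatives anchored through both parents at
once (full siblings and their descendants) are *nuclear* and belong to
both candidate branch subgraphs. This realises "a single family branch"
while letting the proband anchor every candidate cluster.

**Candidate clusters** are, per branch, the connected components of the
first-degree-relationship graph restricted to affected individuals whose
branch is that branch or nuclear. A member set arising identically in both
branches (all-nuclear membership) is merged into a single candidate
labelled nuclear. Affected individuals with no blood path to the proband
are never clustered. An unaffected individual cannot bridge two affected
relatives into one cluster: all members are affected and connected through
affected individuals only.

**Scoring.** A cluster's tumour count is the number of LS-associated
tumour records over its members, counting metachronous and synchronous
primaries independently. Its LAD starts at the internal minimum age and is
lowered — never raised — by LS-associated tumours of affected
second-degree relatives of the proband (grandparents, grandchildren,
aunts/uncles, nieces/nephews, half-siblings) whose branch matches the
cluster's branch or is nuclear; a nuclear-labelled cluster draws on both
branches, which is equivalent to keeping one candidate per branch and
letting the lower LAD win the tie-break. The second-degree extension is
anchored on the proband rather than on arbitrary cluster members; the
anchor is a design choice where the definition is genuinely open, chosen
because referral and counselling are proband-centred.

**Selection** takes the candidate with the largest tumour count, breaking
ties deterministically by lower LAD, then fewer members, then
lexicographically smallest member-id set, then branch name. The tie-break
chain is an implementation convention for reproducibility; clinically,
ties are equivalent. The selector is validated against an exhaustive
brute-force oracle (all single-branch, first-degree-connected affected
subsets) on random pedigrees of ≤ 8 members, where at most 2^8 subsets
make enumeration cheap.

## Triage

Age boundaries are strict (`< 40`, `< 50`, `< 60`); the MMR-first band is
the closed integer range [40, 49], so LAD 49 is MMR-first and LAD 50 is no
testing. Reporting categories use exact tumour counts (1 / 2 / ≥3) so the
partition over the (count, LAD) grid is exhaustive and mutually exclusive;
panel *eligibility* is the union of the three criteria. Two tumours with
LAD in [50, 60) fall to no testing — they are not promoted into the ≥3
band. After a deficient MMR-first result, the number of genes sequenced
follows the IHC pattern: paired heterodimer loss (MLH1/PMS2 or MSH2/MSH6)
→ 2 genes, single loss → 1, MSI-only with no informative IHC → 4.

The historical step-wise work-up is a reconstruction — the cohort it
models reports analysis counts, not per-patient rules. The decision tree
is: MMR functional analysis; on deficiency with MLH1 loss (and when the
era makes it available) reflex BRAF V600E, stopping if positive (somatic
origin); otherwise germline sequencing per the IHC pattern. Probands who
went straight to germline sequencing are modelled as explicit per-proband
overrides. Cohorts with known billed counts can bypass the tree entirely
and aggregate counts directly.

## Costs

Money is whole euros (all unit prices are integers) with exact integer
arithmetic; totals are reproducible bit for bit, and per-path pricing
summed over patients equals aggregation of pooled counts. Line items
render in a fixed declared order. Any price can be overridden from a
YAML/JSON table for sensitivity analysis; currency conversion is outside
the engine. The excess of one strategy over another is reported as an
exact fraction and as an integer percent rounded half away from zero.

## Statistics

The Mann-Whitney U comparison (tumour counts and LAD between MMR-deficient
and MMR-proficient clusters) wraps `scipy.stats.mannwhitneyu`: midrank U;
exact permutation null when `n1·n2 ≤ 400` and the pooled sample is
tie-free, otherwise the normal approximation with tie and continuity
corrections, with the method recorded in the result. A U exactly at the
null mean reports p = 1 (every relabelling is at least as extreme),
matching the permutation definition rather than the continuity-shifted
approximation. The implementation is checked against a brute-force
relabelling oracle for `n1, n2 ≤ 5` and holds its nominal type-I error
within Monte-Carlo tolerance on 400 null replicates. Percent figures in
summaries display as integers (half away from zero) while exact fractions
are retained internally.

## Synthetic cohort generator

The generator emulates a clinical-genetics referral series; its defaults
are the study conditions the package models:

| parameter | default | meaning |
|---|---|---|
| `ls_fraction` | 0.13 | probands carrying an LS mutation |
| `gene_mix` | 0.31 / 0.46 / 0.21 / 0.02 | MLH1 / MSH2 / MSH6 / PMS2 |
| `onset_mean` | 37 / 39 / 42 / 44 y | per-gene mean age at diagnosis |
| `onset_range` | 23–48, 22–57, 34–51, 32–56 | truncation bounds |
| `carrier_tumor_intensity` | 4.3 / 3.4 / 3.2 / 2.0 | expected LS tumours in the carrier branch |
| `sporadic_onset_mean/sd` | 55 / 10 y | sporadic tumour onset |
| `sporadic_tumor_rate` | 0.12 | per-relative sporadic tumour probability |
| `sporadic_mmr_deficiency_rate` | 0.15 | sporadic colorectal MMR deficiency (MLH1 methylation) |
| `braf_positive_given_methylation` | 0.6 | midpoint of the reported 20–50% BRAF-negative share |
| `assay_sensitivity` | 47/48 | carrier tumours showing MMR deficiency |
| `mmr_not_done_rate` | 4/372 | probands never MMR tested |
| `msi_only_rate` | 0.10 | deficient results without informative IHC |
| `vus_rate` | 0.06 | VUS among screened non-carriers (≈ 7/114) |

Onset ages are normal, truncated to the printed per-gene range intersected
with [18, 90], with spread = range/4 — the simplest distribution
consistent with a reported mean and range. The PMS2 "range" in the source
summaries is a single observed value (one family), so the generator uses a
synthetic symmetric range (32–56, spread 6); large-sample recovery tests
compare against the closed-form truncated-normal mean, not the nominal
mean, since truncation shifts it slightly. Sporadic onset (mean 55, SD 10)
reflects the early-onset-skewed referral population rather than
population-registry CRC onset.

Pedigrees are fixed at three generations (four grandparents, the parental
couple with Poisson-distributed aunts/uncles per side, the proband with
Poisson-distributed siblings; means 1.5). In carrier pedigrees the
mutation segregates dominantly from one founder grandparent; the line down
to the proband is forced carrier — reflecting ascertainment through the
referred, mutation-positive proband — while other lines inherit with
probability 1/2. The branch tumour load is 1 + Poisson(intensity − 1), so
every carrier proband is affected; the first tumour goes to the proband
and the rest are spread over the proband-ward carriers so the affected set
tends to stay first-degree connected. Non-carrier probands receive exactly
one sporadic tumour (the referral condition); other non-carriers receive
one at `sporadic_tumor_rate`. Female-only tumour sites drawn for males
fall back to colorectal. EPCAM carriers are not generated (none in the
modelled cohort).

The assay model: carriers test MMR deficient with `assay_sensitivity` and
show the carrier gene's heterodimer IHC pattern; sporadic colorectal
probands are deficient at `sporadic_mmr_deficiency_rate` with MLH1/PMS2
loss and then BRAF positive at `braf_positive_given_methylation`;
BRAF-positive cases stop the cascade unscreened. Mutation detection given
screening of the right gene is 1.0 by default (a knob exists).

**What passing tests show — and don't.** The generator recovers its own
parameters (carrier fraction, sporadic deficiency rate, closed-form
deficient and mutation-positive fractions, per-gene onset means) within 3
Monte-Carlo standard errors at n = 5000, and the default cohort reproduces
the qualitative clinical finding that MMR-deficient clusters carry more
tumours at lower ages. It does not reproduce the historical cohort's
per-patient microdata: cohort-level means (tumour count ≈ 1.8 vs the
reported 2.5; mean LAD ≈ 48 vs 47) are only approximate because sporadic
family clustering, deeper pedigrees, era effects and referral-guideline
selection are not modelled, and the historical significance levels depend
on microdata that were never released — tests assert direction and
calibration, not those p-values. Real-data features deliberately out of
scope: variant classification, assay protocol detail, MLH1
promoter-methylation assays, consanguinity, and genotype data.

## Numerical and degenerate-input conventions

Problem sizes in the test suite (220 oracle pedigrees, 400 null
replicates, n = 5000 recovery cohorts, n = 2000 effect-direction cohorts)
were chosen so Monte-Carlo tolerances of 3 SEs are decisive at desk scale.
Parsing rejects dangling parents, parentage cycles, duplicate primary
indices and multi-proband families; unknown tumour sites map to `other`
with a warning and are excluded from LS counting. Pedigrees whose proband
is unaffected parse but are excluded from CFDR statistics. A pedigree
whose only affected members are blood-unrelated to the proband has no
CFDR. In batch runs, an MMR-first proband without a conclusive MMR result
keeps an unextended analysis path with a logged warning rather than
aborting the cohort. All randomness flows from a single seeded
`numpy.random.Generator`, and identical seeds give byte-identical report
bundles.
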