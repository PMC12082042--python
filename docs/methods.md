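# Methods

## Counting units: clones and clone–isotype records

All repertoire measures are computed on clone-collapsed units rather than
raw reads, so that an expanded clone is counted once per isotype class it
occupies. Clonal inference is the field-standard hierarchical procedure:
sequences are partitioned by (V gene, J gene, junction length) within each
participant — gene-level keys, because allele miscalls within a clone are
common — and single-linkage clustered on the junction under normalized
Hamming distance. Two sequences are linked iff their distance is at most
`distance_threshold` (default **0.15**, exposed as a parameter); connected
components become clones. Single linkage is deliberate: somatic
hypermutation produces chains of variants, and a chained pair at distance
0.20 still belongs together when each link is within threshold.
Clone labels are the lexicographically smallest member `sequence_id`,
which makes the labelling deterministic and invariant to row order.

Collapse produces one record per (participant, clone, isotype subclass):
a class-switched lineage observed as both IgM and IgA2 contributes one
unit to each class. Per unit, `mutated` is the OR of member
`mutation_count >= mutation_gate`, abundance sums member
`duplicate_count`s, the V allele is the member majority (ties
lexicographic), and the representative junction is the highest-abundance
member's (ties lexicographic).

**Mutation gate.** The somatic-hypermutation criterion is
`mutation_count >= 1` — one or more bases differing from the IMGT
germline reference. The gate is an integer parameter (default 1) so a
stricter `>= 2` reading is one flag away.

## Measures

With `N` units for a participant and `n_c` per subclass:

* usage `u_c = n_c / N`; expression `e_c = log2(n_c + 1)`. The +1
  pseudo-count (configurable) keeps the log defined when a subclass is
  absent.
* class switching `s` = (switched AND mutated units) / N. `s` is
  therefore bounded above by the total switched usage.
* V-allele usage counts **mutated** units only in the numerator (an
  unmutated sequence carries no evidence of antigen-driven engagement of
  that allele) but divides by all `N` units; allele usages consequently
  sum to at most 1. The per-allele class-switching variant additionally
  requires a switched isotype.
* CDR3 length is the arithmetic mean of junction length (nucleotides) per
  subclass (median available as an option); subclasses with no units are
  missing, never zero.
* The Hill profile is computed on **clone read abundances** with isotypes
  within a clone merged: diversity is meant to read clonal expansion from
  read support, and splitting by isotype would inflate richness.
  `D_q = (Σ p_i^q)^(1/(1−q))`; `q = 0` and `q = 1` use their closed forms
  exactly (richness and exp(Shannon)). The default grid is q = 0 to 4 in
  steps of 0.1; the measure matrix carries natural-log Hill values at
  q ∈ {0, 1, 2}.

**Prevalence filter.** A subclass or V allele enters the analysis only if
its usage strictly exceeds 1% in at least ⌈0.25 · n_participants⌉
participants, applied separately to the isotype and V-allele families.
IgE is retained unconditionally for its clinical importance. Class
switching and the diversity measures are always analyzed.

## Association models

Each retained measure is analyzed untransformed by ordinary least squares
(statsmodels OLS; standard errors from residual variance with n − k df,
two-sided t-tests). The primary family adjusts for age, sex (0=female,
1=male), self-identified race (0=AA, 1=NHW), exposure group (reference:
**former smokers** — in this population vaping nearly always follows
smoking, so former use is the natural baseline), GOLD spirometry group
(reference: normal), pack-years, and inhaled-corticosteroid use.
Participants flagged as using oral corticosteroids are excluded before
modelling. Categorical covariates are dummy-coded with deterministic
column order; levels absent from the data simply produce no column, but a
missing *reference* level or a rank-deficient design is an error.

Benjamini–Hochberg adjustment is applied within each analysis family
across all (measure × term-of-interest) p-values jointly — tables of
q-values are only interpretable if the family is explicit, so family
membership is recorded in the output. Tiers: significant q < 0.05,
suggestive 0.05 ≤ q < 0.1. The step-up `bh_adjust` is implemented
directly (it accepts a family size m larger than the supplied vector);
statsmodels' `fdr_bh` serves as an independent cross-check in the tests.

Missing covariates trigger complete-case analysis with a logged drop
count; no imputation is performed. A small complete-case subset can
accidentally alias two covariates exactly (observed for rare-isotype CDR3
measures, where the participants lacking the isotype are dropped); such a
measure is reported as skipped with a warning rather than aborting the
family, since the model is simply not estimable there.

## Synthetic cohorts

The generator emulates the cohort structure the analysis expects without
any access to real sequence data. Covariate distributions per exposure
group (ages, sex and race fractions, pack-years, GOLD mixes; group sizes
44 former / 41 never / 41 vaping / 51 cigarette / 57 dual-use = 234)
follow the published cohort's descriptive table; never-smokers have
pack-years fixed at 0 and other groups are truncated at 10 (the cohort's
enrolment floor). Inhaled-corticosteroid prevalence, income, deprivation
index, CT measures, scanner labels and genetic principal components are
plausible inventions, since only their joint role as covariates matters.

Per participant, clone count ~ Poisson(`n_clones_mean`, default **300** —
a desk-scale repertoire; the heavy acceptance simulations use 150 to keep
hundreds of replicate cohorts fast). Each clone draws an isotype from the
group mixture, a V allele from the group panel weights, a J gene, a
junction of uniform-random nucleotides with length a multiple of 3 ~
Normal(per-subclass mean, 9 nt) truncated at 9, a mutated flag by
switched status, and a read abundance from a Zipf law with exponent
`1 + 1/clone_size_shape` — one parameter controlling clonal expansion and
hence Hill diversity. Mutated multi-read clones may emit extra rows with
slightly diverged junctions (≤ 6% substitutions, well inside the 0.15
clustering threshold) whose duplicate counts sum to the clone abundance;
this gives clonal grouping genuine work to undo. Group-effect defaults
mirror the qualitative direction pattern of the study (dual > cigarette ≈
vaping > former for IgA usage and class switching; IgM reversed; dual
users have the heaviest clone-size tail and an upweighted IGHV5-51*01 /
IGHV1-18*01 / IGHV3-7*01 panel) without targeting published magnitudes.
An optional `pack_years_iga_slope` makes pack-years tilt IgA mass, which
is used to test confounding adjustment.

What the generator does **not** emulate: biological junction motifs or
germline-faithful V sequences (only length, counts and identity-based
clustering are consumed downstream), phylogenetically realistic SHM
lineages, isotype co-occurrence within a clone lineage (each simulated
clone carries one isotype), sequencing error, or primer bias. Passing
tests therefore demonstrate correctness of the counting, filtering and
inference machinery under the assumed generative structure — not that
real repertoires satisfy that structure.

Everything is driven by `numpy` SeedSequence spawning: identical configs
and seeds give byte-identical output files.

## Numerical and degenerate-input choices

* Hill numbers are evaluated in log space; q = 0 and q = 1 bypass the
  generic formula, so richness is exact and the profile is continuous
  through q = 1 (|D_{1±1e-6} − D_1| < 1e-4 is tested).
* Empty rearrangement files parse to empty tables; an empty participant
  repertoire is an error for per-repertoire measures and is skipped (and
  logged) at cohort level.
* Multi-valued gene calls resolve to the first listed call; constant-
  region calls map case-insensitively with allele suffixes tolerated.
* Ties anywhere (majority allele, representative junction, BH sort) break
  lexicographically / by stable sort, keeping every output deterministic.

## Problem sizes used in the test suite

Oracle-equivalence checks run on 100 random repertoires of up to 2,000
clones and 100 clustering instances of up to 30 sequences against
brute-force recounts and transitive-closure partitions. Error control
uses 200 null cohorts of 40 participants; parameter recovery uses 50
cohorts of 200 participants with a +0.04 dual-use IgA2-usage shift;
end-to-end determinism runs the full 234-participant default twice. These
sizes were chosen as the smallest that make the Monte-Carlo margins
meaningful.

## Known limitations

* The distance-threshold clonal clustering is a deterministic stand-in
  for likelihood- or spectral-based clonal inference; with the default
  threshold it recovers simulated clones essentially exactly, but on real
  data the threshold should be tuned (e.g. from the
  distance-to-nearest distribution).
* OLS on usage fractions ignores their compositional coupling and
  bounded support; the published analysis made the same choice, and the
  FDR machinery does not require independence, but effect sizes near the
  boundary should be read with care.
* No rarefaction or coverage correction is applied to diversity;
  repertoires of very different sequencing depth are not directly
  comparable on D_q.
* Genetic principal components are consumed as optional numeric columns;
  no population-genetic modelling is attempted.
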