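# Methods

This note records the models, default parameters, numerical choices and
known limitations of `f1binmap`, in the order the pipeline runs.

## The CP (pseudo-testcross) model

A full-sib F1 family of two outbred parents segregates, at bi-allelic
sites, in three informative configurations: lmxll (maternal parent
heterozygous; progeny lm:ll expected 1:1), nnxnp (paternal heterozygous;
nn:np 1:1) and hkxhk (both heterozygous; hh:hk:kk 1:2:1).  Each parent's
meioses form an independent two-state process over that parent's two
haplotypes; hkxhk sites observe both meioses at once, but their het class
(hk) does not reveal which parent contributed which allele.  All linkage
computations in the package are expressed in terms of the transmitted
parental-allele indicators rather than raw ref/alt genotypes.

The package follows the convention that **lmxll means the first (maternal)
parent is heterozygous** and builds the maternal map from {lmxll, hkxhk}
and the paternal map from {nnxnp, hkxhk}; `swap_parents` flips the roles
for data sets coded the other way.

## Synthetic populations (`simdata`)

The generator emulates the data a resequencing-based bin-mapping study
starts from, with defaults at study scale:

| parameter | default | rationale |
|---|---|---|
| `n_progeny` | 176 | typical retained F1 family size |
| `n_chrom` / `chrom_len_cM` | 17 / 80 cM | fruit-tree-scale karyotype (unit tests use 2–3) |
| `chrom_len_bp` | 30 Mb | ~510 Mb genome / 17 |
| `seg_type_mix` | .435/.417/.148 | observed lmxll/nnxnp/hkxhk shares in deep F1 SNP sets |
| `error_rate` | 0.01 | per-call miscall probability |
| `missing_rate` | 0.05 | per-call missing probability |
| `support_mean/shape` | 14 / 5 | negative-binomial read support at ~14× coverage |
| `map_function` | Kosambi | matches downstream distances |

Meioses are simulated as a **Markov chain without crossover interference**:
the switch probability between adjacent markers is the inverse map
function of their cM distance.  Two-point theory downstream uses pairwise
recombination fractions only, so interference would change nothing it can
see.  Parental linkage phases are drawn per marker, recorded in the truth
object, and withheld from the pipeline — phase inference is part of what
is being tested.  Traits are a sum of planted QTL class effects
(4-vector over the gamete classes AC/AD/BC/BD), an optional polygenic term
built from all markers' transmitted alleles, and Gaussian noise; each
component is rescaled by its realized standard deviation so the requested
variance fractions hold in expectation.  An error is raised only when the
total explained variance exceeds 1, so a fully deterministic trait
(PVE = 1, no noise) is allowed.

`fragment_genome` cuts chromosomes into scaffolds (optionally guaranteeing
a minimum marker count per scaffold), flips each scaffold's local
coordinate direction at random, and builds a "current reference" anchoring
in which a configurable fraction of scaffolds get a wrong chromosome
and/or orientation, plus optionally unanchored scaffolds.

**What the generator does not emulate:** read-level data (alignment or
calling artefacts), crossover interference, segregation distortion with a
biological cause, linked selection, population structure within the
family, or reference-genome sequence.  Passing tests therefore demonstrate
the correctness and calibration of the *computational chain*, not
robustness to every failure mode of real sequencing data.

## Segregation typing and filtering (`segtype`)

Support bounds are literal: calls with support < 4 or > 200 are masked,
4 and 200 are retained.  Impossible progeny genotypes (e.g. the opposite
homozygote under het × hom) are set missing and counted; a site whose
impossible-call rate exceeds 5% is rejected (the choice of a per-site
threshold rather than silent masking is ours).  The Mendelian test is the
Pearson chi-square against 1:1 (df = 1) or 1:2:1 (df = 2) on non-missing
calls, with strict rejection at P < .05 — P = .05 itself is retained.  At
n = 176 the discreteness of the counts makes the realized type-I rate
~4%, slightly under nominal.

## Bin construction (`binning`)

Window calls use fixed physical tiles `[kW+1, (k+1)W]` with W = 500 kb by
default; the per-progeny call is the majority CP code of member SNPs and
ties or all-missing cells are missing.  The correction steps are applied
in order, one pass each: (ii) a missing call takes the strict majority of
the nearest non-missing calls, two per side (configurable; step ii can be
disabled); (iii) a missing run flanked by identical calls is filled;
(iv) a call differing from both immediate neighbours, which are
non-missing and identical, is replaced.  Merging treats missing-equals-
missing as identical (required for long bins; a flag demands non-missing
equality instead).  Merged bins span their member SNPs' extreme positions
and sum their SNP counts; merging is idempotent.

Two pre-processing realities of raw CP codes deserve emphasis:

* **Polarity normalisation.**  Which allele of a heterozygous parent is
  "lm" vs "ll" depends on which haplotype carries the variant, which is
  arbitrary per SNP.  Codes are therefore phase-normalised along each
  chromosome (each SNP compared with its predecessor and flipped when they
  disagree in a majority of jointly typed progeny) before windowing —
  without this, majority voting inside a window cancels the signal.
* **hkxhk phase families.**  A double-het site carries one phase bit per
  parent.  Flipping both bits is the observable hh↔kk relabelling, but a
  single-parent flip maps hh/kk onto hk and *cannot* be undone from codes
  alone: hkxhk SNPs on a chromosome fall into exactly two mutually
  reconcilable families.  Each SNP is assigned to the family whose recent
  members it is class-compatible with (joint hh/kk occupancy dominating
  hh/kk-vs-hk crossing, pooled over the last three members); an
  undecidable SNP opens a new family rather than polluting an existing one
  — spurious families merely fragment bins, pollution corrupts them.
  Families are windowed and merged separately and recorded in the bin
  table (`family` column); the non-overlap invariant holds per
  segregation set, family and chromosome.

## Two-point analysis and maps (`linkage`)

For a marker pair, a parent is *informative* when heterozygous at both
loci; each informative parent contributes a meiosis with recombination
prior (1−r, r).  The likelihood marginalises hidden haplotype origins and
any non-informative het parent's Bernoulli(½) allele, and is maximised by
EM over the joint class table, separately for every coupling/repulsion
configuration of the informative parents (≤ 4); the best configuration is
kept and reported.  Fully informative same-parent pairs reduce to
r̂ = min(f, 1−f) with f the mismatch fraction.  `lod` is the log₁₀
likelihood ratio against r = ½; the grouping statistic is the
independence-test G² scaled to LOD units, `ind_lod = G²/(2 ln 10)` — the
threshold (9) is the conventional stringent setting, the formula is our concretisation
of a "independence LOD".  Markers with more than 9 missing calls are
excluded before grouping; a 2..30 threshold ladder is reported for
diagnostics.

Ordering minimises a LOD-weighted least-squares conflict between map
distances (positions = cumulative adjacent Kosambi two-point distances)
and all pairwise two-point distances: greedy insertion seeded from the
strongest pair, then alternating 2-opt segment reversals and or-opt
relocations of 1–3-marker blocks until no move improves (reversals alone
cannot carry a misplaced block past its neighbours).  Pairs below LOD 3
("weak linkages") get weight zero; r is capped at 0.49 before the Kosambi
transform.  On 5-marker noise-free instances the heuristic attains the
exhaustive 120-permutation optimum in ≥ 95 of 100 cases (verified against
an independent brute-force minimiser).

The consensus map pairs maternal and paternal groups by their
majority-chromosome name and aligns them through shared hkxhk bridge
markers: the paternal group is reversed if the bridge positions
anti-correlate (each group's cM direction is arbitrary), the bridge pairs
are made monotone by pool-adjacent-violators, and the consensus bridge
axis takes the **longer** parental span of each bridge interval, so
recombination events resolved in either parent are not compressed; both
maps are projected piecewise-linearly onto that axis, bridge markers
average their two projections, and position ties resolve by weighted mean
parental rank.  A group pair sharing fewer than two bridges is rebuilt by
jointly re-grouping and re-ordering the union of its markers; a group with
no counterpart is carried through with a warning.

Map summaries mirror the usual published layout: per group the average
adjacent interval is length/(n−1); the overall average is
total length/(total markers − number of groups).

## QTL scanning (`qtlscan`)

Phases along a mapped group are resolved by propagating pairwise
coupling/repulsion calls over a **maximum spanning tree** of the pairwise
LOD graph (a nearest-neighbour chain accumulates flip errors; the tree
routes every marker through its most reliable links).  Per parent, a
two-state HMM over haplotype origin runs across the group's markers
(transition = inverse map function of the inter-marker distance, emissions
from the phase-resolved codes with a miscall rate eps = 0.01, the hk class
marginalising the other parent's allele).  Posteriors at grid positions
between markers are interpolated with single transitions to the two
flanking markers — stepping through intermediate grid points would
compose Kosambi fractions into something else, whereas single-step
transitions reproduce the two-point conditional probabilities exactly and
match the simulator's crossover process.  Maternal × paternal posteriors
combine into the four gamete classes.

Interval mapping is Haley–Knott regression of the (possibly transformed)
trait on the expected class probabilities (intercept + 3 contrasts):
deterministic, fast, and adequate at the conventional LOD scale;
mixture-EM is a possible extension, not implemented.  LOD =
(n/2) log₁₀(RSS₀/RSS₁); peaks are local maxima with LOD ≥ 2.5 separated by
≥ 10 cM (the cross-season adjacency tolerance reused as the peak-merging
radius, since no within-scan rule is conventional); support intervals walk
the curve down 1 or 2 LOD; PVE is the RSS-based variance fraction —
definitions vary between implementations, this one is exact for the
fitted model.  The Kruskal–Wallis scan uses the tie-corrected statistic
per marker over its genotype classes with strict significance at
P < .005.

**Null calibration of the fixed LOD threshold.**  Conditional on the
design, the pointwise null LOD is exactly F-distributed with 3 numerator
degrees of freedom, so P(LOD ≥ 2.5) ≈ 0.01 per position — but a genome
scan over five 80-cM groups contains roughly 25 effectively independent
positions, and the null-calibration benchmark accordingly measures that
~40–55% of pure-noise genome scans reach LOD 2.5 at least once, with the
95th percentile of the genome-wide maximum near LOD 3.7–3.9.  No
correctly calibrated 4-class scan can keep the family-wise rate near 5%
at that fixed threshold; the threshold is retained as the conventional
default because single-QTL detection, interval coverage and cross-season
matching are what the pipeline optimises, and
`permutation_lod_threshold()` provides the empirically calibrated
genome-wide threshold when family-wise control matters.

Heritability uses a genomic relationship matrix from centered
parental-allele indicator columns (1:1 markers contribute the informative
parent's indicator; hkxhk markers contribute both parents' expected
dosages hh = 0, hk = ½, kk = 1), scaled to mean diagonal 1.  REML
maximises the profile restricted likelihood over h² via spectral
decomposition and a bounded 1-D search; σg² = h²σ̂², σe² = (1−h²)σ̂².

## Collinearity and anchoring (`synteny`)

Each SNP marker pairs with at most one bin sharing its scaffold:
`within_bin` when its position falls in the bin span (nearest midpoint on
ties), else `same_scaffold` (nearest bin).  Against a reference anchoring,
the LG↔chromosome correspondence is the majority reference chromosome of
each group's anchored markers, computed before classification; markers
then split into co-anchored, misaligned and new-anchored, a partition, and
collinearity = 100·co/(co+mis).

Re-anchoring uses the maps alone: a scaffold's group is the
weight-summed majority LG of its markers (per-map weights default equal);
when two runs of ≥ 2 markers support different groups the scaffold is
split midway between the runs (the ≥ 2-marker rule is ours); order within
a group is the weighted mean cM; orientation is the sign of the Spearman
correlation between cM and scaffold bp, '?' with fewer than two distinct
positions (written as '+' in AGP and flagged).  AGP v2.1 output uses fixed
100-bp gaps (`N 100 scaffold yes map`), validates structurally, and
round-trips losslessly.  Accuracy against simulation truth allows a
whole-group reversal per chromosome, because a linkage group's cM axis has
no intrinsic direction.

## Benchmark problem sizes

The acceptance benchmarks simulate 176-progeny populations on 3
chromosomes (map, power and heritability checks) or 5 chromosomes (null
calibration, Kruskal–Wallis null, anchoring) of 10 Mb / 80 cM with 250–300
SNPs per chromosome, 1% error and 5% missing calls; anchoring uses 50
scaffolds with ≥ 3 markers each and 20% reference misassignment.  These
sizes keep every stage's behaviour measurable (dozens of bins per group,
several crossovers per chromosome arm) at desk-scale runtimes.

## Known limitations

* Exact numeric compatibility with the classical interactive mapping
  tools (grouping trees, regression-mapping orders, DAG-merged consensus
  maps) is out of scope; the package reimplements the stated procedures
  with documented, testable concretisations.
* Two-point EM assumes a single r per pair shared by both informative
  meioses; sex-specific recombination rates are not modelled.
* The bin-construction correction steps assume locally dense windows;
  for very sparse marker sets they are conservative at best (the hk
  family mechanism above prevents the worst case).
* Interval mapping fits a single-QTL model per position; linked QTLs on
  one group bias each other's positions and PVE (no composite or
  multi-QTL model).
* The REML heritability treats bin markers as exact; with sparse maps the
  relationship matrix under-tags polygenic variance and h² is mildly
  attenuated.
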