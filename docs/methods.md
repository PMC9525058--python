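# Methods

## Differential hypermethylation calling

Beta values are methylated-signal fractions in [0,1] (computed upstream as
M/(M+U+100) from array intensities; this package consumes normalized betas
as-is).  For each probe, the replicate medians of the parental and
aggressive lines are compared; a probe is hypermethylated when
Δβ = medianₐ𝓰𝓰 − medianₚₐᵣ ≥ 0.2 — roughly a 20-percentage-point
methylation difference, the smallest difference detectable with 99%
confidence on Infinium arrays — and every replicate of both lines has
detection p < 0.01.  Detection filtering is probe-wise and strict: one
failing sample removes the probe from that pairwise comparison.  The
boundary comparison carries a 1e-12 slack so a difference that equals the
threshold up to float representation still qualifies.

Gene calls require ≥ 3 hypermethylated CpGs (optionally restricted to
promoter probes: TSS1500, TSS200, 5'UTR, first exon).  The common set is
the intersection of per-pair gene calls; per-pair supporting probes are
retained.  The region breakdown classifies hypermethylated CpGs of a gene
set into promoter / gene body / 3'UTR; a probe annotated to several genes
counts once per class membership.

The nearest-centroid marker classifier uses per-group mean betas as
centroids.  A probe is a marker when the centroid difference reaches a
threshold (default 0.2) and at most `m` training samples (default 0) sit
nearer the opposite centroid in absolute beta distance.  The direction
vector is a signed z-score — centroid difference over the pooled standard
deviation (sd = sqrt of the df-weighted average variance); a
zero-variance probe gets a signed-infinite sentinel.  New samples are
assigned to the phenotype whose centroid is nearest in mean absolute
distance over the marker probes, ties deterministically toward the
first-listed phenotype.  Distance metric, pooled-sd definition and the
`m = 0` default are this package's choices; only the method family is
prescribed by the upstream analysis.

## Cluster detection and the shuffle bootstrap

Gene position is the transcription start coordinate from the caller's gene
catalogue (a single well-defined measuring point, consistent with the
promoter focus).  Two hypermethylated genes are *linked* when no other
catalogued gene lies strictly between them (direct neighbours) or when
their TSSs are ≤ 3 Mb apart; linkage chains transitively, so a cluster may
span more than 3 Mb overall when each consecutive link qualifies.  Maximal
chains of ≥ 2 genes are clusters; singletons are not.  Sex chromosomes are
excluded by default (parental imprinting).  A unit oracle re-derives the
clusters as connected components of the full pairwise linkage graph, which
is equivalent because the gap rule is monotone in index distance.

The null model permutes the hypermethylation flags over the chromosome's
gene slots (positions fixed, hyper count preserved) — this keeps the
catalogue's gene-density structure, which re-drawing coordinates would
destroy.  The empirical p-value is (1 + #{null ≥ observed}) / (n_sim + 1),
never zero and super-uniform under the null; with a discrete cluster-count
statistic it is conservative (the achievable rejection levels are the null
CDF jump points), so the measured type-I rate at 0.05 sits at or below the
nominal level.  Chromosomes with < 2 hypermethylated genes are reported
with observed 0 and p = 1.  Randomness comes from NumPy's PCG64 generator
with integer seed sequences; one stream is consumed over chromosomes in
natural order, making every null count reproducible cross-platform.
Raw per-chromosome p-values are reported without multiplicity adjustment
(a Benjamini–Hochberg flag is available in the API).

## Candidate nomination

The promoter filter keeps clustered genes with ≥ 2 promoter CpGs each
showing Δβ ≥ 0.40 in the reference pair (`per-cpg` mode, the default,
reading the 40% criterion per CpG as the sentence structure suggests); a
`promoter-mean` mode instead requires the mean Δβ of the gene's
differential promoter CpGs to reach the threshold, since the percentage
could also be read against the promoter score.  The promoter methylation
score is 100 × the mean replicate-median beta over the gene's
differentially methylated promoter probes; the aggressive-minus-parental
difference ranks candidates, and an externally supplied functional gene
list (pathway analysis is proprietary and out of scope) can flag overlaps.

## The 0–4 methylation score

Pyrosequencing methylation percentages at five CpGs in four genes are
scored against per-gene medians of all primary patients (the gene's
combine rule — the mean of BCL2L10's two adjacent CpGs — is applied per
patient *before* the median).  A gene scores 1 when the patient deviates
from the median by at least 15 percentage points in its aggressive
direction: below the median for MYH1 (hypomethylation marks
aggressiveness), above it for PCDHB16, PCDHB15 and BCL2L10.  "15%" is read
as absolute percentage points (all values live on the 0–100 methylation
scale); the boundary is inclusive (≥ 15), with a strict-threshold option
(> 15) since the upstream descriptions differ.  The reference set is the
primary cohort by default, with a metastases option, as the two upstream
descriptions of the reference disagree.  The total over the four genes is
0–4; total ≥ 2 (inclusive) defines high risk.  A gene with missing CpGs
contributes 0 and flags the result incomplete; patients missing more than
one gene are excluded from survival validation by default.

Pairwise association of the per-gene sub-scores is summarised by the 2×2
chi-square statistic with a seeded Monte-Carlo permutation p-value (one
margin permuted), valid at small counts; pairs with a constant sub-score
are reported untestable.  P-values are reported without interpretation.

## Survival analysis

Kaplan–Meier estimation, the log-rank and Gehan–Breslow–Wilcoxon tests
(Gehan weights event times by the number at risk), Cox
proportional-hazards fits and Harrell's concordance over comparable pairs
are delegated to lifelines; ties use the Efron approximation.  The group
median is the first time the curve drops to ≤ 0.5 and is undefined for
curves that never do.  The event indicator is explicit in the patient
table (censoring handling upstream is unreported; an all-events reading is
available by setting every flag to 1).  Tumour depth dichotomises patients
at 2 mm — T1/T2 vs T3/T4, falling back to the numeric depth when the stage
is unknown.  The validation report fits the score group, the Breslow
group, and the interaction model (score, Breslow, score × Breslow);
perfect separation is flagged rather than raised.  Tests cross-check these
routines against hand-written oracles: a by-hand product-limit curve,
hypergeometric O−E sums for the log-rank statistic, and a brute-force
partial-likelihood maximiser on a 4-subject fixture (agreement to 1e-4).

## Synthetic data

The generator emulates the study design: 3 cell-line pairs × 3 replicates
on a 20-autosome genome of 150 genes/chromosome (~1 Mb TSS spacing,
150 Mb chromosomes) with 6 probes per gene cycling through the six region
groups promoter-first (so every gene has 4 promoter probes).  Baselines
are uniform on [0.05, 0.55] (headroom so the planted shift does not
saturate at 1); replicate noise is truncated normal with sd 0.02
(transparent, and the upstream work states no replicate-noise model);
planted genes gain Δβ = 0.35 at all promoter probes.  The standard layout
plants 50 common genes — 9 clusters on 6 chromosomes (30 genes, mirroring
the real study's cluster yield) plus 20 isolated singletons — and 25
pair-specific genes per pair that must not survive the intersection.
Detection-failure fractions are 0 by default and planted independently per
(probe, sample) when enabled.

The cohort generator defaults to 49 primary and 10 metastatic patients
(the validation cohort's size).  A latent aggressive indicator (default
prevalence 0.4 among primaries; all metastatic patients aggressive) shifts
each signature CpG by 25 percentage points in the gene's direction around
baseline means of 60% (MYH1) and 25–30% (hyper genes), with 5-point
Gaussian noise truncated to [0, 100].  Survival is exponential under
proportional hazards — baseline median 51 months (the long-survival
median), hazard × 3.4 (the reported hazard ratio) for aggressive patients
— so a Cox fit on the true labels recovers the planted ratio; censoring is
an independent uniform time whose horizon is solved numerically for the
requested overall rate (default 0.15, a plausible registry-cohort value;
the real cohort's censoring is unreported).  Breslow depth is lognormal
around 1.5 mm (indolent) or 3.5 mm (aggressive), and T stage derives from
depth.

What the generator does *not* emulate: probe-chemistry artefacts (type
I/II), batch effects, SNP-affected probes, non-exponential hazards,
informative censoring, or correlation between neighbouring CpGs beyond the
planted gene-level shifts.  Passing planted-truth tests therefore shows
the pipeline's logic is correct under its stated model, not that the
thresholds are optimal for real arrays.

## Problem sizes and numerical choices

Planted-truth recovery runs the full 18 000-probe × 3-pair design
(seconds).  Cluster-caller/oracle agreement uses 500 random chromosomes of
≤ 12 genes, where exhaustive enumeration is cheap.  Bootstrap calibration
uses 200 true-null single-chromosome genomes drawn from the study
genome's own layouts (a random autosome with its planted hyper count,
flags shuffled) at n_sim = 1000.  Survival recovery uses 200-patient
cohorts, 50 seeds per planted hazard ratio in the tests and 30 replicates
in the acceptance script.  All seeds are explicit; the acceptance script
derives every stream from its `--seed` argument.
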