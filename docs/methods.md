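# Methods

`casteseq` implements a replicate-interval differential-expression pipeline
for two-caste, three-stage larval transcriptomics in bumblebees, together
with the downstream analyses that such a study runs: taxonomic-novelty
classification, reciprocal-best-hit (RBH) orthology, cross-species gene-list
overlap statistics, and a qRT-PCR validation arm. This note documents the
models, the defaults and the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Normalization: subsampling without replacement

Raw counts are the algebraic sum of collapsed-read abundances incident to
each transcript. Libraries are equalized in depth by drawing, for each
library, `n_draws` subsamples of exactly `target_depth` reads without
replacement — a multivariate hypergeometric draw over features — and
returning the per-feature mean across draws. Defaults: `target_depth="min"`
(the smallest library total) and `n_draws=10` with an explicit seed. Each
single draw's column sum equals the target exactly, and the expectation of
the normalized count is `raw x target / library_total`. This is the
simplest faithful form of nonparametric subsampling normalization:
depth-equalizing, distribution-free, and it preserves the discreteness of
low counts. The matching is global (one target depth for all libraries);
whether per-stage matching or a single draw would change downstream calls
is an open design question — the mean-of-draws matrix is what all
downstream stages consume here.

Replicate QC computes, per library, the mean Pearson correlation of
`log2(count + 20)` with the other libraries of the same phenotype and flags
libraries below `min_corr` (default 0.9). The offset +20 is reused from the
OFC statistic so QC and effect size damp low-abundance noise identically.
QC only reports; removal is an explicit configuration action
(`excluded_samples`), never silent. Note that with two or three replicates
a single corrupted library also drags down its siblings' mean correlation —
the report is a shortlist for inspection, not an automatic verdict.

## Differential expression: the interval rule and OFC

For each feature and phenotype (stage x caste), the "maximal confidence
interval" is the [min, max] of normalized counts across biological
replicates. A feature is a DEG between castes within a stage when the two
intervals are disjoint; a shared endpoint counts as overlap (the strict
reading — ties are not evidence of separation). Effect size is the offset
fold change

    OFC = log2((min_k + 20) / (max_k' + 20)),

with `min_k` from the upregulated caste's interval and `max_k'` from the
other — a conservative bound on fold change — and 20 a base-level offset
that prevents low-abundance features from dominating the OFC ranking.
Disjointness forces `min_k > max_k'`, so every DEG has OFC > 0. HDEGs are
DEGs with OFC strictly > 1 (OFC = 1.0 exactly is not an HDEG).

The rule is distribution-free, so its null is exact: for iid continuous
replicate values the intervals separate iff one group holds the top ranks,
giving P(DEG) = 2/C(n1+n2, n1) — 0.1 for 3v3, 2/70 for 4v4, 0.2 for 3v2.
This analytic value is the calibration check used in the tests and the
acceptance script. There is no per-gene p-value and no multiple-testing
correction inside the caller: the rule is interval-based by construction.

Unannotated exon features belonging to one multi-exon transcript are merged
before HDEG counting: member counts are summed per sample, the interval
rule and OFC recomputed on the sum, and the unit counts as one HDEG.
When no unit file is supplied, `infer_transcript_units` chains unannotated
features on the same chromosome and strand within 1,000 bp whose expression
profiles correlate at Pearson >= 0.9; the rule is configurable and echoed in
the output, since exact exon-merging conventions vary between annotations.

Genes of interest are selected by five criteria: (a) top OFC in some
phenotype (ties all flagged), (b) HDEG in >= 1 stage, (c) HDEG in >= 2
stages, (d) gene family contains another HDEG, (e) literature-supported
caste link; selection requires (a) and/or at least two of (b)–(e).

## Annotation classes and novelty

Four classes: annotated; unannotated-not-novel; novel non-coding; novel
coding. Annotation membership (a GFF-derived id set) takes precedence.
Otherwise a feature is novel (taxonomically restricted) when no homology
hit outside the genus *Bombus* reaches E <= 1e-5 in either the nucleotide
or protein search. Features with no hits at all satisfy that condition and
are classified novel, flagged `no_hit_novel` for transparency. Coding
status is a deliberately simple stand-in for a full coding-potential
predictor: longest ATG→stop ORF over six frames >= 100 codons (threshold
configurable); real analyses may substitute any external predictor by
passing their own coding flags.

Novelty enrichment between caste pathways is a two-sided Fisher exact test
per stage on W-up vs Q-up HDEGs. Two table conventions are supported:
`columns="total"` uses (novel, total) columns and `columns="rest"` the
textbook (novel, not-novel) table. The default is "total", which is the
construction under which the reference late- and mid-instar comparisons of
this study design (7/14 vs 5/40 and 14/92 vs 7/54) evaluate to 0.042 and
0.813; the "rest" convention gives 0.007 and 0.810 on the same counts.
Stages where either caste has no HDEGs are reported untestable, not p = 1.

## Orthology and overlap statistics

RBH pairs (a, b) require b to be a's best hit and a to be b's best hit;
"best" is lowest E-value, then highest bitscore, then lexicographically
smallest subject id — a fixed chain chosen purely for determinism. The map
is one-to-one and symmetric under exchanging the two tables. DEG/HDEG
lists filtered to mapped features become DEO/HDEO lists.

Overlap tests build [[|a∩b|, |a\b|], [|b\a|, |bg\(a∪b)|]] over a supplied
background, with two-sided Fisher p and Bonferroni adjustment by a
per-batch family size that is always supplied, never inferred (the
reference design uses families of 36 and 18 comparisons). Comparisons with
an empty list are untestable. `exclude_and_retest` removes a gene set
(e.g. diapause-associated genes) from lists and background and recomputes.
Platform congruence is scored per gene x stage: the sequencing side is
significant when the gene is an HDEG, the qPCR side when the Mann–Whitney
p < 0.05; a match is agreement in significance and direction, or joint
non-significance. The match proportion is tested against 0.5 with an exact
binomial test, one-sided by default (`alternative` is a flag): the
reference value 38/48 gives p = 3.085e-5 one-sided, twice that two-sided.

## qRT-PCR arm

Plates are calibrated by subtracting each plate's (IPC Cq − grand IPC mean)
from all wells, which equalizes IPC across plates and preserves
within-plate differences exactly. Relative quantities use per-gene
efficiencies, RQ(g,s) = E_g^(Cq̄_g − Cq_g,s), with the per-gene mean Cq
across samples as calibrator — so RQ is invariant to a constant shift of
any one gene's Cq. Efficiency defaults to 2.0 when unknown. geNorm M is
the mean SD of pairwise log2 RQ ratios with the other candidates, with
iterative exclusion of the highest-M gene; pairwise variation V(n/n+1)
compares normalization factors (geometric means) of the best n vs n+1
genes, and the recommended reference count is the smallest n >= 2 with
V < 0.15 (the conventional cutoff), floor two references. BestKeeper SD is
the per-gene SD of calibrated Cq. Targets are normalized by the geometric
mean of the chosen references, and caste differences within a stage are
tested with two-sided Mann–Whitney U tests — exact when tie-free, normal
approximation (flagged) with ties. Sidedness of the rank tests is a
documented default, not a hidden constant.

## Synthetic-data generator

The generator emulates the study design the pipeline targets: six
phenotypes EQ/EW/MQ/MW/LQ/LW with replicate counts (3,3,3,2,3,3) — 17
libraries — library depths uniform in [0.8e6, 1.2e6], and 200 true
caste-DE features at log2-fold 4 allocated to mid (60 Q-up, 90 W-up) and
late (36 Q-up, 14 W-up) stages with none early, mirroring the stage
profile of strong caste differences in this design. Counts are negative
binomial (dispersion 0.05 by default; per-block for DE features) around a
log-normal baseline; 60% of features carry a shared log-normal stage factor
(SD 1 log2 unit) so replicates cluster by stage rather than caste. The
caste factor multiplies the up-caste mean by 2^fold within the affected
stage only. Because each library is scaled to its depth, very large DE
fractions compress apparent fold changes compositionally — with DE
features ~1% of the transcriptome the effect is negligible.

Homology hit tables, cross-species hit-table pairs and Cq plates are
generated consistently with the recorded truth, so the classifiers and the
RBH mapper can be scored for exact recovery. Cq plates contain eight
candidate references of graded stability (gene noise 0.03–0.65 cycles; the
first two form the stable pair), fold-change targets (defaults: 4-fold
Q-up at mid, 2-fold W-up at late), six biological replicates per phenotype,
per-gene efficiencies in [1.8, 2.1], plate offsets and an IPC well per
plate; `noise_scale=0` collapses all stochastic components except plate
offsets.

What the generator does **not** emulate: nucleotide-level reads and
alignment artifacts, GC/length biases, correlated gene modules, batch or
colony effects beyond the stage factor, partial or ambiguous homology
evidence, and qPCR non-linearities (primer-dimer, inhibition). Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the declared noise model, not robustness to every artifact
of real libraries.

## Problem sizes and numerical choices

The test suite runs most checks on reduced designs (hundreds of features)
and the headline recovery check on the full default design (15,000 features
x 17 libraries); null-rate calibration uses 1e5–2e5 simulated features.
Determinism: every stochastic step takes an explicit seed; there is no
global random state. Degenerate inputs are errors, not silent defaults:
zero-depth libraries, single-replicate phenotypes, missing castes, missing
IPC wells, lists outside the background. Ties: touching intervals are not
DEGs; OFC exactly 1 is not an HDEG; equal top OFC flags all tied features;
RBH ties resolve by the fixed chain above.

## Known limitations

The interval rule's sensitivity depends strongly on replicate number (its
null rate is 0.2 at 3v2 vs 0.1 at 3v3), and it has no notion of
within-group variance beyond the range. The coding-status ORF rule is a
heuristic. The "total" Fisher table convention double-counts the novel
genes in the margin; it is retained as the default for comparability, with
the textbook convention one flag away. Cross-species overlap p-values
depend on list sizes in the partner species, which must be supplied by the
user; none are hard-coded.
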