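# Methods

This note documents the models and numerical choices behind each stage,
what the synthetic-data generator does and does not emulate, and the
design decisions taken where the problem was genuinely open.

## Synthetic cohort generator

The generator is the testing substrate for every stage: it produces a
multi-patient cohort with known cell types, EMP states, copy-number
blocks, doublets and mixing fractions.

**Generative model.** Counts are gene-wise negative binomial:

    count(c, g) ~ NB(mean = b(g) · e(type(c), g) · r(c, g) · β(p(c), g) · ℓ(c),
                     size = θ)

with log-normal baseline means `b(g)` (default ln-mean 0, ln-sd 1, giving
cells of roughly 3,000–4,000 total UMIs — a typical droplet depth; at
substantially shallower depth the scale-factor-10,000 normalization
amplifies low-expression noise beyond what real data shows), program
effects `e` (default: 60 genes per program at fold 3; the pEMT and
epithelial programs are both active in the mixed tumor state), block
copy-ratios `r` acting multiplicatively on the mean (the signal model that
relative-expression CNV inference reads out; default one clonal
copy-ratio-2 gain of 150 genes per patient), per-(patient, gene) batch
factors `β = exp(N(0, 0.15))`, and per-cell library factors
`ℓ = LogNormal(0, 0.35)`.

The dispersion default is `θ = 10` (biological CV ≈ 0.32), the
conventional value for UMI-count simulators; gene-level UMI data is far
less dispersed than bulk tissue. Mitochondrial gene means are scaled so
the expected mitochondrial fraction is 5%; 50 housekeeper genes get a
fixed mean of 3 so nearly all intact cells detect well over 30 of them.

**Doublets** are sums of two independently drawn cells (5% of barcodes by
default). Each patient has two hashed samples; doublets carry the HTOs of
both parents, so roughly half (same-sample pairs) are invisible to
hashing — as in real hashed libraries. **HTO counts** are Poisson with
signal mean 200 on the cell's own HTO(s) and background mean 5 elsewhere;
no dispersion parameter is modeled, so demultiplexing difficulty is
governed entirely by the signal/background separation.

**Pseudo-bulk mixtures** draw cell-type fractions from a Dirichlet
(α = 1), form the fraction-weighted sum of mean count profiles of
resampled singlets per type, and rescale to a fixed library size
(10⁶). Because the generator's library-size distribution is independent
of cell type, count-mass fractions and cell-number fractions coincide up
to program-driven differences of a few percent — real tissues can violate
this (mRNA content differs by type), which is a known limitation of
signature-based deconvolution generally.

**What the generator does not emulate:** gene–gene correlation modules
beyond the discrete programs, ambient RNA, empty droplets (cell calling
is threshold QC, not knee-point detection), splicing, spatial structure,
and real genome annotation (chromosomes are synthetic rank positions).
Passing tests therefore demonstrate contract correctness and statistical
calibration under a clean NB world, not robustness to every artifact of
real tissue dissociation.

**Determinism.** One global seed forked via `SeedSequence.spawn` into
independent streams (gene table, type assignment, counts, HTOs); every
output is byte-identical under a repeated seed.

## QC and demultiplexing

All thresholds are strict inequalities, following the usual "more
than / less than" phrasing of cell-calling rules; a cell with exactly 500
UMIs or exactly 10% mitochondrial content fails. Detection for QC counts
(genes, housekeepers) means count > 0. Named profiles: `default`
(UMIs > 500, mito < 10%), `hk30` (adds > 30 housekeepers), `kurten`
(> 175 genes, mito < 10%, > 60 housekeepers, no UMI rule).

QC runs on raw counts before demultiplexing; the order is a pipeline
convention, not a constraint of the functions. HTO thresholds are
required configuration — they encode a per-library manual judgment.
`suggest_hto_thresholds` proposes the midpoint of a two-component split
of log1p counts but is never applied silently. Cells positive for no HTO
(negatives) are excluded together with doublets by default
(`keep_negatives=True` retains them): an unidentifiable cell cannot be
assigned a sample.

## Normalization and differential expression

`log_normalize` is the standard `ln(1 + c/Σc · s)` with `s = 10,000`.
Fold changes are computed on de-normalized group means with pseudocount
1 inside the log2 — the convention of current single-cell toolkits; the
pseudocount and detection threshold (count ≥ 1 by default; a "more than
one UMI" mode, `detection_min_umis=2`, exists because display statistics
sometimes use it) are exposed as parameters since toolkit versions
differ. No DE p-values are computed: downstream stages consume fold
changes and percentage filters only.

Program scores control for expression level by binning all genes into 24
equal-size mean-expression bins and sampling 100 control genes per
program gene from the program gene's bin (with replacement); the score is
mean(program) − mean(control). Phases: G1 iff both S and G2M scores are
≤ 0, otherwise the larger score wins, ties toward G2M (documented
tie-break; ties are measure-zero on real data). Cell-cycle *regression*
is deliberately out of scope — scores and phases are reported only.

## Heterogeneity

Cosine similarity is uncentered (not Pearson) on *unfiltered* log2FC
vectors — the pseudocount guarantees finiteness. The default gene
universe is the intersection across profiles; `union` zero-fills. The
patient inclusion cut (> 50 tumor cells) is strict and applied before
profiling. Cluster labels are inputs; this package does not re-implement
graph clustering.

Ward ordering uses `scipy`'s Ward linkage on the chosen distance
(Euclidean, or 1 − Spearman correlation), which follows the same
Lance–Williams recursion as the ward.D2 convention; rows are id-sorted
before clustering so tie-breaking is deterministic.

## CNV inference

A transparent simplification of reference-based relative-expression CNV
callers: per cell, (1) drop mitochondrial genes and order by (chromosome,
position); (2) `log2(1 + c/Σc · 10⁴)` from raw counts (log2 scale so the
output values are log2 ratios); (3) subtract the reference-cell mean per
gene; (4) clip at ±3 × the mean per-gene reference SD; (5) moving average
of width 101 within each chromosome, with the symmetric window shrinking
near chromosome edges (half-width = distance to the nearer edge; windows
never cross chromosomes); (6) center each cell at its median; (7) flatten
noise — values within 1.5 reference SDs of the per-gene reference mean
are set to 0 (`denoise_sd=None` disables).

Step (7) deserves justification: even a 101-gene average of
droplet-depth counts leaves per-cell noise of ~0.1 on the log2 scale
(per-gene log2 noise is ~1 at these depths regardless of biological
dispersion — it is dropout/Poisson noise), so without flattening every
cell shows spurious wiggles and the per-cell deviation score loses its
null calibration. Full-featured callers apply an equivalent denoising
step by default for the same reason.

The malignancy score is the root-mean-square deviation of a cell's
smoothed profile from the reference mean profile; a constant offset δ
scores exactly |δ|. The contract of this module is sign/segment recovery
of implanted blocks and null calibration on synthetic cohorts — not
numeric parity with any HMM-based caller, and no genotype calling or
clone trees. Per-block gene lists are exposed so users can audit whether
an apparent gain coincides with a cluster of co-regulated highly
expressed genes (a known failure mode of expression-based CNV
inference).

## TF activity

For each cell, genes are rank-transformed (average ranks on ties) to
centered quantile scores `q` with exact zero mean. The raw activity of a
regulon is `Σ mode·weight·q(target)`; it is divided by the exact standard
deviation of that sum under random placement of the targets — a weighted
sum of draws *without replacement* from the cell's finite rank
population:

    Var = var(q) · [Σa² − ((Σa)² − Σa²)/(G−1)],   a = mode·weight

which makes the null analytic (mean 0, variance 1) and the sign-flip
invariant exact. `var(q)` is the cell's empirical rank variance, so ties
(zeros) are handled correctly. This is one defensible per-cell reading of
regulon enrichment; the published two-tailed enrichment algorithm with
pleiotropy correction is intentionally not reproduced, and the contracts
are sign/ordering properties, not parity.

Repressor/activator classification is strict: a TF is a repressor iff
*more than* 90% of targets have mode −1 (18/20 = 90% exactly is
ambiguous). "Active in a cell" means activity > 0, strict. Regulon
confidence filtering (A–E letters) is the caller's choice via
`min_confidence`.

## Deconvolution

The signature matrix subsamples the phenotypes named in `subsample`
(default 75% of "T cells"/"B cells", seeded) — these populations
otherwise dominate the least-squares fit; removes a gene iff its
detection fraction is below 5% in *every* phenotype (`filter_scope="all"`,
the reading that keeps phenotype-specific markers; `"any"` is the
stricter alternative); and scales each phenotype's mean count profile to
CPM. Bulk profiles are CPM-normalized without batch or quantile
correction. NNLS (`min ‖Sf − b‖², f ≥ 0`) runs on the shared-gene
intersection; fractions are reported as `f/Σf` (uniform with a warning in
the degenerate all-zero case). No permutation significance machinery is
attached.

## Pipeline

Stages run in dependency order from a YAML config with one section per
stage; config validation is fail-fast (every enabled stage's inputs must
exist before anything runs), and the manifest records parameters and a
SHA-256 checksum of every output, so a rerun under the same seed is
verifiable byte-for-byte. Exit codes: 0 success, 2 validation error,
1 stage failure.

## Problem sizes

The test suite and acceptance script run on cohorts of 300–1,000 cells ×
2,000 genes (20 replicates for the null-calibration checks, 50 small
cohorts for the QC oracle) — sizes at which every asserted statistical
bound has comfortable margin under the generator's defaults while the
whole suite stays interactive (< 1 minute).
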