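# Methods

This note documents the models and procedures egrnkit implements, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical conventions that matter for reproducing its
output.

## Pipeline model

The pipeline assumes preprocessing is done elsewhere: counts are quantified,
peaks called, a shared cross-modality latent embedding computed (iNMF, GLUE
or similar), and cluster labels assigned. egrnkit consumes those artifacts.

**Pairing and imputation.** ATAC→RNA nucleus pairing is exact 1-nearest
neighbor under Euclidean distance in the shared latent space; ties break to
the lowest RNA index so results are deterministic. Imputation is a pure
column copy — no k>1 averaging or smoothing — so imputed values are a subset
of observed values and downstream correlations are not artificially inflated
by neighborhood averaging. The alignment diagnostic samples 50 ATAC nuclei
without replacement (seeded) and reports the fraction whose nearest RNA
nucleus carries the same label.

**Peak-to-gene linkage.** The candidate window is symmetric around the TSS
with total width 500 kb (half-width 250 kb, a first-class knob since "a
window of 500 kb" is ambiguous between width and half-width). Window
membership uses the peak midpoint, `floor((start+end)/2)`, under half-open
`[TSS−w, TSS+w)` semantics — a single unambiguous distance per pair.
Expression and accessibility are depth-normalized (counts per 10⁴, log1p)
before correlating; raw-count mode is available. The p-value uses the exact
t transform of the sample correlation on n−2 df, two-sided; BH runs over the
whole candidate table at once (not per gene), and acceptance is one-sided
(r ≥ 0.45) because the biological hypothesis is activating enhancers;
`signed=False` accepts |r|. Constant rows are dropped with a logged count
rather than propagating NaNs.

**Differential testing.** One Wilcoxon implementation (normal approximation
with tie correction, or exact enumeration for small groups) stands in for the
Seurat and Scanpy variants; the consensus operation intersects the top-N
(default 200) of any number of ranked tables, so the original three-method
design is preserved by passing three tables. log2 fold changes for
normalized data are computed on the expm1 scale with ε = 10⁻⁹. ANOVA's
"FC > 0.5" filter is read as |log2FC| > 0.5 — a linear fold-change threshold
of 0.5 would keep almost everything. DARs use Welch's t on the raw peak
count matrix (the unequal-variance form is the safer default when cluster
sizes differ), thresholds p < 10⁻³ and log2FC ≥ 1 on raw means, ranked by
(p asc, |log2FC| desc, id) and truncated to 5000 per group. Fisher
enrichment is the hypergeometric upper tail with BH across terms.

**TF mining.** Motif rankings order all peaks per motif by descending score
with coordinate-then-id tie-breaks; absent hits score 0. The recovery AUC is
the mean of the cumulative-recovery curve over the top
`max(ceil(0.001·N), 20)` ranks: the 0.1 % fraction follows the cisTarget
convention and the floor of 20 ranks keeps the statistic meaningful on
desk-scale peak sets where 0.1 % would be under five ranks. NES is the
z-score of a motif's AUC against all motifs in the same (cluster, source)
table, sample sd (ddof = 1); a cluster whose AUC vector is constant (no
motif recovers its DARs) carries no signal and is skipped. When several
enrichment sources are merged the maximum NES per (cluster, motif) wins and
a floor of 3.0 is applied at merge time. Regulator selection requires a
positive Pearson correlation between the TF's NES profile and its gene's
mean-expression profile across clusters — the only axis on which both
quantities are tabulated per TF — implementing the rule that an activator's
motif accessibility should track its own expression.

**eGRN assembly.** For each selected TF in a cluster, element nodes are the
peaks satisfying all three conditions (cluster DAR ∧ TF motif hit ∧ accepted
link); gene nodes are the genes those elements link to. Every element node
therefore lies on a complete TF→element→gene path by construction. Export is
SIF plus node/edge TSVs and round-trips exactly.

**Supervised pseudotime.** Waypoints are per-cluster coordinate medians
(robust to outliers) in a stated order, or explicit coordinates; the path is
piecewise-linear with an optional endpoint-preserving moving average
(unsmoothed by default). Nuclei project to the globally nearest segment —
not sequentially — because that is well-defined for noisy nuclei; t is arc
length at the projection normalized per trajectory, with raw arc length and
perpendicular distance also reported. Branches must share the root's
terminal waypoint; a nucleus goes to the branch whose concatenated path is
nearest, ties to the first branch and flagged.

**Cluster evaluation.** Partition equivalence is ARI = 1 exactly (identical
up to label renaming); a configurable tolerance exists but defaults to
exact, since "stable" is otherwise undefined. Ties between equally frequent
classes go to the class containing the lowest resolution. The silhouette
scores singleton clusters 0 by convention (hand-implemented for that
reason; it matches sklearn when no singleton exists), and the Dunn index
returns +inf when every cluster is a singleton.

**Gene activity.** Each fragment contributes its two Tn5 cut sites, at
positions `start` and `end−1`, counted independently in the strand-aware
window (gene body plus 2 kb upstream of the TSS side); a per-fragment mode
counts a fragment at most once. Cut-site counting is the default because
fragment files record exactly the two insertions.

**Pseudobulk.** Counts are summed per group, scaled to CPM, and
log2(CPM + 1); the +1 pseudocount is configurable and exists because
log2(CPM) is undefined at zero. Second-level averaging (e.g. donors within
stage) is a plain mean of log values, left to the caller.

## The synthetic generator

The generator emulates the *structure* of a paired single-nucleus multiome
experiment on a bifurcating differentiation system, not any particular
tissue's measured distributions:

- **Trajectory.** Nuclei sit on a piecewise-linear path in latent space — a
  root segment splitting into two branches at ±60°, total arc length 6 —
  plus isotropic Gaussian noise (default sd 0.1, "moderate"). True
  pseudotime is normalized arc position; clusters tile the (branch, t)
  space. Both modalities are independent draws from the same process, so a
  shared latent space exists by construction.
- **Counts.** RNA is negative-binomial via a gamma–Poisson mixture with
  size parameter θ (default 2; a flag gives the θ→∞ Poisson limit). ATAC is
  Poisson with per-peak lognormal baseline rates, mostly 0/1/2 counts at the
  default depth of 1500 per nucleus. Baseline RNA rates are
  softplus(loadings·latent), scaled so mean depth is 5000.
- **Programs.** Each planted TF has a home cluster; its activity is a
  Gaussian bump over that cluster's pseudotime range, with other-branch
  nuclei evaluated at their pseudotime reflected through the branch point so
  programs are branch-specific yet smooth. TF expression, target expression
  and enhancer accessibility are all multiplied by (1 + effect·activity),
  effect 16 by default — "strong" in the sense that every planted pair
  clears the r = 0.45 acceptance threshold in the zero-noise limit. Program
  genes carry a flat latent baseline (their only trajectory dependence is
  the planted activity) and planted enhancer baselines are floored at the
  lognormal median: enhancers are by construction real accessible elements,
  and without the floor the lognormal low tail can silence a planted program
  regardless of effect size.
- **Geometry.** One synthetic chromosome, 0-based half-open coordinates.
  Genes are spaced at least 2.2× the linkage half-width apart, so every peak
  falls in at most one gene's window and planted enhancers only in their own
  target's; placement infeasibility raises rather than silently overlapping.
  Decoy peaks are placed both inside and outside windows and have
  nucleus-constant rates — independent of every TF's expression by
  construction, which makes the false-link rate of the linkage step a pure
  FDR property.
- **Motifs.** Each planted motif hits its TF's enhancers with a high score
  over a low-score random background; decoy motifs have background hits only
  and are annotated to background genes, so they compete in the NES and
  correlation rankings like real motifs would.

What it does **not** emulate: sequence content, read-level artifacts,
batch/donor effects (beyond a label column), doublets, trans-chromosomal
structure, or empirically calibrated depth/dispersion distributions. Tests
that pass on this generator demonstrate that the pipeline's statistics are
correctly implemented and that its thresholds behave as designed under a
known truth — not that any particular biological dataset will yield similar
recovery.

## Problem sizes and determinism

Default study conditions are 400 nuclei per modality, 300 genes, 1200 peaks,
3 TF programs × 8 targets × 2 enhancers, 50 decoy motifs — sizes chosen so a
full pipeline run takes under a second and the whole validation suite runs
in seconds on one CPU while keeping per-test statistical power (400 nuclei
put the null sd of r near 0.05, far from the 0.45 threshold). All
randomness flows from a single root seed through named substreams
(`SeedSequence(seed, spawn_key)`), so each stage can be re-run independently
and identical configurations produce byte-identical output files; the
pipeline writes a provenance log with every threshold used and SHA-256
hashes of its outputs.

## Known limitations

- The linkage step tests positive correlations by default; repressive
  elements require `signed=False` and their FDR behaviour is not separately
  validated here.
- NES-vs-expression correlation needs ≥ 3 clusters with non-degenerate DAR
  sets; sparse designs fall back to an empty regulator list rather than a
  partial ranking.
- The stability selector treats near-identical partitions (ARI just below 1)
  as distinct classes unless a tolerance is set.
- Gene-activity scoring loops over genes; it is comfortable at 10⁴ genes ×
  10⁶ fragments but is not engineered for whole-genome fragment files.
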