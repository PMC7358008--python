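# Methods

## Scope and data model

`lungatlas` implements the analysis pipeline of a Smart-seq2 single-cell
atlas of immune cells in the developing mouse lung: eight mice, one
female and one male at each of four perinatal stages (E18.5, P1, P7,
P21), with roughly fifteen immune populations of which five are
macrophage/monocyte states. The root object is a cells × genes matrix
of non-negative integer read counts with per-cell metadata (mouse,
sex, timepoint, uniquely mapped reads, detected genes). On disk the
matrix is matrix-market, genes × cells (the community convention for
expression matrices); in memory it is cells × genes so per-cell
operations are row-wise.

## Quality control

Cells with fewer than 50,000 uniquely mapped reads **or** fewer than
400 detected genes are discarded; equality retains (the filters are
strict "less than" rules). A cell failing both rules increments both
failure counters but is removed once, and every input cell receives
exactly one disposition label (`kept`, `fail_reads`, `fail_genes`,
`fail_both`, `doublet`), so the accounting chain
`n_input → n_after_filters → n_final = n_after_filters − n_doublets`
is fully auditable.

Doublets are removed at the cluster level, replacing manual curation
with a reproducible rule. After a provisional clustering, a cluster is
flagged when (a) at least half of its cells co-express (raw count > 0)
the pan-immune marker *Ptprc*/Cd45 together with at least one
mutually exclusive non-immune lineage marker (*Epcam*, *Cdh5*,
*Col6a2* and relatives), or (b) the cluster's mean CPM of any
contaminant marker exceeds that of the immune marker. The provisional
pass runs at three times the final Leiden resolution: doublet
communities are small, and a finer partition prevents a rare genuine
population from being merged into — and removed with — a doublet
community. Flagged clusters are dropped and the cleaned matrix is
re-normalized and re-clustered from scratch. The co-expression
fraction (0.5) is a package default, not a literature value.

## Normalization and feature selection

Counts are normalized per cell to counts per million (CPM); all log
transforms are `log10(cpm + 0.1)`, so a zero count maps to exactly −1.
Feature selection is per-replicate: within each mouse (at least five
cells; smaller mice are skipped with a warning) every gene's Fano
factor Var/Mean of CPM is ranked, a gene counts as "high Fano" in that
mouse when its rank is within 1000, and genes are ordered by (number
of supporting mice descending, mean within-mouse rank ascending,
symbol ascending). The top 500 genes are kept. Both knobs
(`high_rank_cutoff`, `n_features`) are exposed; the Fano factor is
computed on CPM rather than raw counts or log values — the three
scales give different rankings and CPM matches the position of
selection after normalization in the workflow. The selected log-CPM
submatrix, gene-centered but not unit-scaled, is projected onto the
top 25 principal components with a deterministic full-SVD solver; each
component's sign is fixed so its largest-magnitude loading is
positive.

## Graph, communities, embedding, annotation

The cell graph is a Euclidean k-nearest-neighbor graph in PC space
(k = 15 by default), symmetrized by edge union with unit weights;
neighbor ties break by ascending cell index, making the graph exactly
reproducible. Communities come from Leiden modularity optimization
(RB-configuration objective) at a configured resolution, relabeled by
decreasing size. The default resolution (0.2) was calibrated once on
the default synthetic design so the cleaned atlas resolves its fifteen
designed populations, and stored as the package default. t-SNE is
initialized from the first two principal components (scaled to small
variance) rather than randomly, which stabilizes the embedding
geometry across runs — important because the batch-variation test
measures distances in this embedding.

Annotation scores each cluster against a marker panel (cell type →
signed gene rules, e.g. Mac III: *Car4*+ and *Itgax*+; Mac II:
*Itgax*+ and *Car4*−). A rule's score is the mean over its genes of
the fraction of cluster cells expressing the gene (count > 0; negative
rules contribute one minus the fraction). The best-scoring type wins;
below a floor of 0.25 the cluster is "unassigned", and exact ties go
to the earlier panel entry. "Expressing" is raw count > 0, the
simplest rule consistent with dot-plot semantics, and is exposed in
the dot-plot summary as `frac_expressing` alongside the mean log
expression.

## Replicate batch-variation test

For every (cell type, timepoint) stratum, 100 cell pairs within one
mouse and 100 pairs spanning two mice of the same timepoint are drawn
(distinct cells; sampled with replacement over pairs so the count is
attainable in small strata), and their Euclidean distances in the 2-D
embedding are compared by a two-sample Kolmogorov–Smirnov test. The
verdict is `batch_effect` only when p < α (default 0.05) **and** the
cross-mouse median distance exceeds the same-mouse median: different
animals must be farther apart, not merely differently distributed.
Strata lacking two mice with two cells each return
`insufficient_cells`. Because pairs drawn from a small stratum reuse
cells, the KS independence assumption erodes as strata shrink and the
test becomes anti-conservative; the calibration experiment shipped in
the test suite therefore uses strata of ~100 cells per mouse — the
scale of the real atlas's larger strata — where the null rejection
rate sits inside the 95% binomial band around α.

## Differential expression

Marker ranking is one-vs-rest per gene: a two-sample KS statistic
between the cluster's CPM values and all remaining cells (or a second
cluster in cluster-vs-cluster mode). The statistic is invariant under
any strictly monotone transform, so CPM and log-CPM give identical
ranks. P-values use the exact method when the smaller group has at
most 25 cells (small-cluster tables) and the asymptotic formula
otherwise; with heavily tied data (zeros) the exact routine is
approximate, and published p-values are not expected to match
bit-for-bit. The log2 fold change is
`log2((mean_in + 0.1) / (mean_out + 0.1))`, re-using the global 0.1
pseudocount. Tables sort by statistic descending, then p ascending,
|lfc| descending, symbol; one-vs-rest tables keep only upregulated
(lfc > 0) genes before truncation.

## Graph smoothing

For visualizing low or noisy genes only, the CPM matrix is smoothed
over the cell graph: one round multiplies by the row-normalized
(A + I) operator — each cell becomes the mean of itself and its
neighbors — and the default two rounds reach exactly second-order
neighbors. Unit edge weights with a self-loop are the simplest
operator with that reach; a Gaussian-kernel variant would change
weights, not reach. Per-gene variance is non-increasing per round, a
constant gene is a fixed point, and an isolated cell keeps its value.
Clustering and differential expression always use unsmoothed values.

## Pseudotime and attractor states

Pseudotime over selected clusters uses diffusion pseudotime (scanpy's
implementation) from a root cell, min-max scaled to [0, 1]. The root
is the subset cell scoring highest on an early-program marker set —
the study marks the start cell graphically, so an explicit rule is
substituted. The subset's representation is recomputed: the
atlas-level feature set is kept but PCA is rerun on the subset's cells
alone, because the global components encode between-population
separation and bury the within-population program; with the
between-population axes gone, the developmental program dominates the
leading components. Five components and a 30-neighbor graph are the
defaults — a trajectory is intrinsically low-dimensional, and extra
noise dimensions degrade the diffusion distances.

The scalar-potential analysis interpolates pseudotime on a regular
grid (default 50 × 50) over the embedding's bounding box, restricted
to nodes with at least one cell within 1.5 grid spacings. Node
potential is the inverse-distance-weighted mean of pseudotimes of
cells within the radius (an exact hit contributes its own value).
A node is a local maximum — an attractor state — when its potential is
at least that of every populated 8-neighbor and strictly greater than
at least one; a connected equal-potential plateau counts once (its
lowest row-major node) iff all its populated border is strictly lower,
so a constant field has no maxima. The 2-D gradient uses central
differences where both axis neighbors are populated, one-sided
differences otherwise, and is flagged undefined where neither exists;
it is exact on affine potentials at interior nodes. Arrows point
toward increasing pseudotime, so attractors are sinks of the reversed
field. A scalar potential has zero curl by construction: rotational
flows (e.g. a self-renewing population) cannot be represented, which
is a limitation of the method, not of the implementation.

## Abundance, proliferation, repertoire

Composition over development reports counts and percentages per
(timepoint, cell type), with the denominator either all typed cells at
the timepoint or a restricted compartment (e.g. macrophage/monocyte
states only). A cell is proliferating when at least one (configurable)
of *Mki67*, *Mcm5* has count > 0 — a detection-based stand-in for a
visual definition, invariant to normalization. B-cell germline
identity tables (per-cell V and J similarity to the germline
reference, produced upstream by contig assembly tools) are summarized
as per-locus empirical CDFs; the somatic-hypermutation flag trips when
either locus's median identity falls below 0.98.

## The synthetic generator

`generate_atlas` draws negative-binomial (gamma-Poisson) counts,
`counts[i, g] ~ NB(mean = lib_i · p[pop(i), g], dispersion 0.15)`,
with log-normal library sizes (median 3 × 10⁵, σ = 0.35 on the log
scale) emulating Smart-seq2 depth. Each of the 15 populations has a
profile over 2000 genes summing to 10⁶ CPM: 20 markers per population
elevated 500-fold over a 0.5 CPM baseline (matching the enormous log2
fold changes of real lineage markers such as granule proteases), a
shared macrophage marker (Cd68-like) across the five m/m states, a
pan-immune Cd45-like gene, and background genes with shared log-normal
means absorbing the rest of the library. Composition per timepoint
follows the study narrative — the fetal macrophage state dominates the
m/m compartment before birth and nearly vanishes by P7; lymphocytes
rise to the majority by P21 (B ≈ 30%, T ≈ 15% of immune cells) — with
rare populations floored at ~2–3% so each remains clusterable at the
simulated scale of 2000 cells. One population (Mac II by default)
carries a latent time t ∈ [0, 1] driving a 30-gene program: 15 early
genes decline linearly with t and 15 late genes rise, i.e. its profile
linearly interpolates two endpoint states, at an amplitude (10³ CPM)
large enough for per-mouse Fano selection to retain the program.
Doublets (3%) are the average of two different populations' profiles
plus a strongly expressed non-immune block (epithelial/endothelial/
mesenchymal structural genes, 2 × 10³ CPM each, as contaminating cells
contribute a large read share); low-depth failures (5%) have libraries
drawn uniformly from 5–40k reads, below the QC threshold. Optional
per-mouse effects multiply each gene by a log-normal factor of
configurable σ. Macrophage/monocyte cells are proliferating
(Mki67/Mcm5 at 100 CPM) with per-timepoint fractions 0.6/0.4/0.2/0.1
from E18.5 to P21, declining as in the real tissue.

What the generator does **not** emulate: gene-length and GC biases,
ambient RNA, batch chemistry effects, gene–gene correlation beyond
population structure, zero inflation beyond NB sampling, and realistic
gene counts (2000 genes rather than ~20k; detected genes per cell are
correspondingly fewer than the ~4000 of the real data). Passing tests
demonstrate that the pipeline recovers structure a well-specified
overdispersed model plants — not that it is robust to every artifact
of real libraries.

## Problem sizes and determinism

Tests and examples run the default 2000-cell, 2000-gene design; the
batch-calibration experiment uses 50 replicates of a two-population,
800-cell design with two timepoints (strata of ~100 cells per mouse),
and trajectory recovery is checked on seeds 0–4. All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); identical
design and seed give bit-identical matrices, and clustering, t-SNE and
pseudotime are seed-deterministic.

## Known limitations

- The doublet rule needs contaminant markers present in the gene list;
  panels for other tissues must be supplied by the user.
- The exact KS p-value with heavy ties is approximate (conservative);
  ranking is unaffected.
- The potential-field construction assumes a curl-free flow; see above.
- Composition percentages from a ~2000-cell simulation carry binomial
  noise of a few percentage points; tests compare against designed
  frequencies within that error, not against point values.
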