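# Methods

`chloronet` couples two analyses that are usually run separately: comparative
characterization of chloroplast genomes across populations of one species,
and inference of a regulatory network linking chloroplast-related regulators
to genome-wide target genes from expression data. This note records the
models, the parameters that matter, and the design choices made where the
procedure was genuinely open.

## Genome features and the quadripartite partition

A chloroplast genome is treated as a circular sequence with the quadripartite
layout LSC + IRa + SSC + IRb, where IRb is the reverse complement of IRa.
All coordinates are 0-based half-open internally; GenBank I/O converts from
the 1-based inclusive flat-file convention, and compound (`join`) feature
locations are flattened to their outer span. Gene symbols are normalized
through a small synonym table (ycf3 ≡ pafI, ycf4 ≡ pafII, psbN ≡ pbf1) and
tRNA names are unified to the `trnX-NNN` form with the anticodon written in
RNA alphabet, because records annotated a decade apart use different
conventions for the same genes; unknown symbols pass through with copy
suffixes stripped.

Inverted repeats are located by exact seed-and-extend: every k-mer match
(k = 21) between the sequence and its reverse complement seeds an ungapped
extension, and the longest non-overlapping reverse-complement pair of length
at least `min_len` (default 100 bp) is reported, ties broken by leftmost
start. This is adequate because conifer-type IRs of the kind targeted here
are short (~850 bp) exact-scale repeats; the long, slightly diverged IRs of
typical angiosperm plastomes would want an alignment-based detector.
Circular topology is handled by searching the doubled sequence on request.
The two arcs between the IRs become LSC (longer) and SSC (shorter); the
partition always tiles the circle, so `len(LSC) + len(SSC) + 2·len(IR) =
genome length` is enforced as an invariant.

GC content is `100·(G+C)/(A+C+G+T)` with `N` excluded from the denominator;
region summaries round to integer percent while the underlying function
keeps full precision. Gene counts are reported both per annotated occurrence
(an IR-duplicated gene counts twice) and collapsed to distinct symbols,
since published tallies are ambiguous between the two conventions;
presence/absence analysis always uses the collapsed form.

## Gene composition

The presence matrix is boolean samples × normalized gene symbols. Genes
unique to a focal sample set are those present in *every* focal sample and
absent from *every* other sample. Samples are clustered by average-linkage
hierarchical clustering on the Jaccard distance of their presence rows; the
linkage method is a package choice (no published method to follow) and is
recorded in the output metadata. The flat grouping is the 2-cluster cut, and
a "discriminating genes" report lists genes whose presence perfectly
separates the flat clusters — this is how single-gene differences such as a
psbM presence split surface.

## Polymorphism patterns

For each per-gene alignment, polymorphic sites are columns with ≥ 2 distinct
symbols over `{A, C, G, T, -}` after uppercasing: gaps count as alleles
(single-base indels between closely related plastomes are real signal), and
any column containing `N` or another ambiguity code is skipped entirely
because ambiguity calls are unreliable. Two samples share a partition class
iff they agree at every polymorphic site of the gene, so the partition is
invariant under row reordering and under adding monomorphic columns.

Partitions are classified against a focal layout (defaults: focal single
sample `TW`, focal pair `{JPL, SMP}`) in this order:

1. one class → `MONOMORPHIC`;
2. focal single isolated, all others one class → `TW`;
3. focal pair exactly one class, focal single not isolated → `CZ`;
4. focal single isolated, remainder split further → `TW2`;
5. otherwise `ELSE`.

Rule 2/4 are skipped when the focal single is absent from the gene's sample
set (a gene may be missing or unusable in one sample). The precedence of the
isolation rules over the pair rule resolves patterns such as
`TW | JPL,SMP | rest` (classified `TW2`) that never occur in the motivating
data; the choice is recorded here because the data cannot decide it. The
classifier reproduces all 19 published partition rows, giving group sizes
CZ = 2, TW = 10, TW2 = 2, ELSE = 4 once ycf2 (a suspected assembly artifact
in the oldest record) is excluded.

Supergene concatenation joins per-gene alignments end-to-end over a common
sample set and emits FASTA plus NEXUS with a `charset` block per gene, ready
for external tree software; tree inference itself is out of scope.

## Network inference

Targets (non-regulator genes) are modelled as sparse linear-Gaussian
functions of regulator expression on zero-mean rows. Preprocessing is:
(1) subtract each gene's mean; (2) keep genes with |centered value| ≥ 1 in
at least 5 samples. Regulators are exempt from the variability filter by
default so a fixed factor panel survives; a strict mode filters them too.

Targets are first clustered into co-expression modules (average linkage,
correlation distance `1 − r`, cut at height `h = 0.6`; zero-variance rows
become singleton modules). Regulator selection is greedy forward selection
per target: adding candidate `c` to predictor set `P` scores

    gain = (n/2)·ln(RSS(P)/RSS(P ∪ {c})) − λ + β·support

where `support` is the fraction of the target's module co-members that
already have `c` as a regulator (0 for singleton modules). Selection stops
when no gain is positive or `max_regulators_per_target` (default 5) is
reached; after each sweep the support terms are recomputed from the full
edge set and selection repeats, for `n_iterations = 3` sweeps or until the
edge set stabilises. The module assignment stays fixed after initialisation.
With `β = 0` the algorithm reduces exactly to independent per-target forward
selection. This is a deliberately transparent variant of modular per-gene
network learning in the MERLIN tradition — Gaussian likelihood, OLS, greedy
search, module-consistency prior — not a reimplementation of the original
probabilistic graphical-model code, and it is not expected to reproduce that
program's outputs edge-for-edge.

The per-edge cost λ defaults to an extended-BIC value resolved from the
problem size, `λ = ln(n)/2 + γ·ln(p)` with `γ = 0.5`, for `n` samples and
`p` candidate regulators. A fixed small constant (e.g. the AIC cost of one
parameter) admits a spurious regressor with probability ≈ 5% per candidate
trial, which across thousands of target × candidate trials floods the
network with false edges; the `ln(p)` term prices exactly that selection
multiplicity (the extended-BIC argument of Chen & Chen). An explicit numeric
`sparsity_penalty` overrides the automatic value, and the edge count is
monotone non-increasing in λ. Ties between equal gains are broken by a
seeded shuffle of the regulator order, then lexicographically; the seed has
no other role, so inference is deterministic given its configuration and
invariant under sample-column permutation.

Numerical notes: OLS uses `lstsq` without an intercept (rows are centered);
a candidate collinear with the current predictors is skipped with a warning;
a numerically exact fit (RSS ratio below 1e−12) caps the log-likelihood term
at a large finite ceiling rather than +∞.

## Consensus networks

Stability selection re-infers the network on `k = 6` subsamples, each
holding `⌊f·n⌋` sample columns drawn without replacement (`f = 0.5`, so 268
samples give 134-column subsets), and keeps edges recurring in at least
`m = 5` runs; confidence is `occurrence/k` (5 of 6 → 83.3%). Subset draws
are seeded by `(seed, index)` and per-subset engine seeds are `seed + index`,
so subsets are independent but the whole procedure is reproducible; retained
edge sets are nested in `m` by construction. Edge weight is the mean OLS
coefficient over the runs containing the edge.

## Summaries and enrichment

Network summaries count distinct edge sources (regulators), sinks (targets)
and edges. "Hub" has no canonical definition; here hubs are the top-N
regulators by out-degree (default N = 10), ties broken by ID, with the
definition echoed in output. Group edge fractions report, per polymorphism
group, the percentage of edges whose regulator is linked to that group; a
multi-label regulator's edges count once per label but once in the "any"
total, so the total can be below the per-label sum. Venn region counts are
exclusive-region tallies over arbitrary named gene sets.

Enrichment uses the two-tailed Fisher exact test per term — p is the sum of
hypergeometric probabilities of all tables as or less probable than the
observed one, the convention of mainstream statistics tools (delegated to
`scipy.stats.fisher_exact` and cross-checked against full enumeration in the
tests) — with Benjamini–Hochberg FDR across all terms tested in one run
(via `statsmodels`), significance at q < 0.05. The 2×2 table splits the
target set by term membership against the rest of the background; terms with
no background overlap are skipped.

## Synthetic data

The generators are pure functions of their configuration, seed included, and
every generated artifact round-trips through the package's readers.

* **Genomes** — six samples named after the motivating populations. Each
  genome is random sequence assembled as LSC + IRa + SSC + revcomp(IRa)
  (defaults 20 kb / 850 bp / 12 kb; flank bases are adjusted so the planted
  IR is exactly maximal), with a shared core of 70 CDS + 20 tRNA + 4 rRNA
  and planted presence structure: 22 genes private to the island sample
  (21 tRNAs + clpP), 32 genes shared by the five hinterland samples only
  (31 tRNAs + rps7), and psbM present in exactly two hinterland samples.
  Genes tile the single-copy regions at non-overlapping positions.
* **Alignments** — one reference class keeps a random base sequence; every
  other partition class gets private substitutions at dedicated columns, so
  the planted partition is recovered exactly. The default plan is the
  published 19-gene partition table plus a few monomorphic genes.
* **Expression** — regulator rows iid N(0, 1); module `m`'s targets are
  `w·Σ(module regulators) + N(0, σ²)` with defaults 10 regulators, 5 modules
  of 40 targets, 2 regulators per module, w = 1, σ = 0.1, n = 200 samples.
  This is desk-scale rather than atlas-scale (the motivating data had 121
  factors × 21,638 targets × 268 samples); the planted signal-to-noise is
  strong by design, so recovery tests validate the machinery, not
  performance on weakly coupled real transcriptomes.
* **Term sets** — one planted term sampling the target set at rate 0.8 and
  the remaining background at 0.1, plus 20 uniform decoy terms.

What the synthetic data does *not* emulate: codon structure, IR-internal
genes, alignment error, heteroscedastic or non-Gaussian expression noise,
correlated regulators, and batch structure across experiments. Passing
recovery tests therefore demonstrates correctness of the algorithms under
their stated model, not robustness to those real-data features.

## Known limitations

* The IR detector assumes exact repeats; diverged IRs are reported only up
  to their longest exact block.
* Forward selection is greedy: strongly correlated regulators can shadow
  each other, and the module prior can propagate a co-member's false edge.
* Fisher enrichment treats genes as exchangeable; no gene-length or
  expression-level bias correction is applied.
* The polymorphism classifier's rule precedence is a convention for patterns
  the motivating data never exhibits (see above).
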