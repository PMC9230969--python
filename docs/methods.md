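# Methods

This note documents the models, algorithms, numerical choices and known
limitations of the `structphylo` pipeline, in the order data flows through
it.

## Structural data model

Every computation is CA-level: a model is an ordered chain of CA
coordinates plus a one-letter sequence. Residue indexing is 0-based and
positional (file order); author residue numbers are parsed but used only
for output, because models from different sources number inconsistently.
Only `ATOM` CA records are read (first chain by default), altlocs collapse
to the first seen, and multi-MODEL files use MODEL 1 with a warning.

## Pairwise structural alignment

The aligner is an independent implementation of the classic iterative
superposition/realignment scheme used by the TM-align family:

* **Initial candidates** (all deterministic): gapless threadings of the
  shorter chain onto the longer at offsets sampled every ⌈L/20⌉ residues;
  a sequence-identity alignment (+1 match / 0 mismatch, linear gap −0.6 —
  linear, not open/extend, because free gap extension would reduce a
  sequence seed to a longest-common-subsequence match); and diagonal
  threadings through the best-superposing 20-residue window pairs.
* **Iteration**: superpose on the current pairing, rescore every residue
  pair as 1/(1+(d_ij/d₀)²) with d₀ from the shorter chain, realign by
  global dynamic programming, repeat to convergence (pairing unchanged or
  TM change < 1e-5; cap 20 iterations, best iterate kept).
* **Gap model**: three-state (Gotoh) DP; each maximal gap run costs −0.6
  once and extends free, terminal runs included. A per-column linear
  penalty was rejected during design: it makes one near-zero-score junk
  match cheaper than two gap columns, so insertions are never gapped out
  and the core register is lost. Traceback tie-breaks prefer match, then a
  gap in the second model, making the aligner bitwise deterministic.
* **Focused superposition**: rigid transforms are fitted by Kabsch (SVD,
  reflections excluded), but on a subset of pairs annealed from wide to
  tight distance cuts (8·d₀ → d₀), seeded by whichever of the all-pairs
  fit or contiguous-window fits scores best on full-pairing TM. This lets
  a rigid conserved core dominate the frame even when much of the pairing
  crosses inserted or divergent regions.
* **Sharpening**: after the best candidate converges, a few extra
  iterations at d₀/2 snap near-register solutions (e.g. one-residue
  shifts in helices) to the exact register; kept only if the standard TM
  improves.

Scores are reported under both normalisations (each chain's length);
`tm_avg` — their mean — fills the symmetric TM matrix (diagonal 1,
computed once per unordered pair). RMSD is the least-squares value over
the full final pairing; an opt-in outlier-trim mode (drop pairs beyond a
cut, re-fit, ≤ 5 cycles) mimics the RMSDs printed by interactive
superposition tools and never affects TM.

## Multiple structure alignment and the conserved core

Progressive merge along an NJ guide tree built on 1 − TM. Sub-alignments
enter pairwise alignment as pseudo-structures: per-column mean CA
coordinates over present members, with a majority-consensus sequence so
the sequence seed also works at internal nodes; d₀ uses the mean of the
two sub-alignment lengths. Column merging preserves the order invariant
(each model's residue indices strictly increase down the columns; asserted
after the merge).

After the root merge every model is superposed into a common frame
(reference = lexicographically first model id) by fitting each model onto
the mean of the others over fully occupied columns, iterated ≤ 10 rounds
or until the mean column max-distance changes by < 0.01 Å.

The conserved core is read per column in that final frame: a column is
core when (i) all models are present (configurable) and (ii) the maximum
pairwise CA distance among its members is < 4 Å. The threshold is strict
(< 4, so 3.9 passes and 4.1 does not), monotone (raising it never removes
a core column), and the per-column distances are stored for inspection.
Core-trimmed sequence alignments contain exactly the core columns.

## Distance trees

* **NJ** is Saitou–Nei: join the pair minimising
  Q(i,j) = (n−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k), two-point branch-length
  formulas, negative estimates clamped to zero (logged).
* **BioNJ** uses the same join criterion with Gascuel's variance-weighted
  reduction: d(u,k) = λ(d(i,k)−ℓᵢ) + (1−λ)(d(j,k)−ℓⱼ), λ minimising the
  reduced-matrix variance, variances initialised to the distances. On an
  exactly additive matrix the weighting is inert and BioNJ equals NJ.
* Ties on Q break by the lexicographically smallest label pair (clusters
  labelled by their smallest leaf), so both builders are bitwise
  deterministic.
* **Score→distance**: d = 1 − TM, the minimal monotone transform with
  d(x,x) = 0; −ln TM available behind a flag.
* **Midpoint rooting** walks the longest leaf-to-leaf path explicitly and
  inserts the root at its midpoint (handled in-package: the off-the-shelf
  rerooting misplaces the root when a degree-2 root splits the central
  edge). All-zero trees root arbitrarily with a warning.
* **Bootstrap**: resample columns with replacement (seeded NumPy
  generator), p-distance per replicate (sites with a gap in either member
  skipped), NJ per replicate, Felsenstein bipartition proportions on the
  reference tree's internal edges. Rows are sorted by id first, so
  supports are row-order invariant. The classical proportion is used;
  transfer bootstrap is out of scope.
* **Robinson–Foulds**: splits encoded as the side not containing the
  lexicographically smallest leaf; RF = symmetric difference count,
  normalised by 2(n−3). Newick I/O and tree containers use dendropy.

## Domain segmentation and architecture

A domain is a compact sub-structure: dense internal CA contacts, sparse
contacts outward. The weighted contact graph (edge when CA distance
< 8 Å, weight 1, +2 for chain neighbours) is partitioned by recursive
two-way spectral bisection — by connected components when the graph is
disconnected (the Laplacian null space is degenerate there), otherwise by
the Fiedler vector's sign. A split is accepted only when both parts hold
≥ 40 residues and the interface weight per residue of the smaller part is
below 0.02 of the mean intra-part weighted degree. The 0.02 value was
tuned only on the synthetic generator: planted, spatially separate domains
have interface ratios near zero while the best spectral cuts of compact
single-lobe cores measure 0.04–0.06, so 0.02 separates the regimes with a
factor-2 margin on both sides. The bias this buys — preferring to fuse
borderline cases — matches the convention of counting only clearly
distinguishable domains.

Domains may be sequence-discontinuous, which is essential: the conserved
core itself comprises N- and C-terminal segments that pack together and
must come out as one domain. The main domain is the one scoring the
highest tm_avg against a supplied one-domain reference (minimum 0.3, else
"unassigned"). Architecture types: 1 domain → type 1, 2 → type 2,
≥ 3 → type 3.

## Synthetic structure-evolution generator

The generator emulates what matters about a sheath-protein family while
staying fully controlled:

* **Core scaffold**: an idealised CA trace with exact 3.8 Å consecutive
  spacing (waypoint polylines resampled at 3.8 Å chords) and > 3 Å
  self-avoidance. The N-terminal third is a serpentine slab of extended
  strands, the C-terminal third the matching slab stacked 5.5 Å above it
  — so the core is one compact block whose termini pack together, and is
  spatially interleaved rather than sequence-contiguous — and the middle
  third is a layer of short ideal helices (2.28 Å radius, 1.5 Å rise,
  100°/residue) resting on the sandwich. Slab strand length scales as
  √(n·3.8·5.5) so small cores stay compact. Deterministic per seed.
* **Evolution**: leaves of a ladder (default), Yule, or user-supplied
  tree. Along each branch, i.i.d. Gaussian jitter of σ = 0.5 Å per
  coordinate per unit branch length, followed by five sweeps of symmetric
  (Jacobi) bond-length relaxation back to 3.8 Å. The relaxation splits
  each bond correction equally between its endpoints: a one-directional
  renormalisation was measured to slide the chain ~1 residue within its
  own path over deep branches, silently divorcing geometric from label
  homology. Sequences mutate at 0.1 substitutions/site per unit branch.
* **Accessory ("decoy") domains**: compact two-layer slabs of short
  paired strands — geometric stand-ins for Ig-like β-sandwiches — spliced
  into the chain at planned insertion points and displaced 60 Å in a
  random direction (re-offset until ≥ 12 Å from everything else; < 4 Å
  after ten tries is an error). By default taxon i carries i mod 4
  decoys, so a family spans architecture types 1–3. The truth object
  records the tree, the core homology map and all domain intervals.

**Default study conditions** (frozen before the acceptance suite was
written): 6 taxa, 300-residue core, branch length 1.4, σ = 0.5 Å,
55-residue decoys. The branch length balances two opposing pressures:
longer branches strengthen the tree signal in the TM matrix against the
incidental TM contributions of non-homologous decoys (~0.005 per entry),
while shorter branches keep the accumulated core drift inside the 4 Å
column rule. At 1.2 the topology is lost in ~15% of replicates; at 1.6
core recall falls below 0.9; 1.4 gives exact topology in ≥ 90% of
replicates with mean recall ≈ 0.95. The 60 Å decoy displacement ensures a
planted domain can never masquerade as alignable structure (at 35 Å its
incidental TM-score contributions are of the same order as the internal
branch signal).

### What the generator does and does not emulate

It reproduces: a rigid discontinuous core, divergence scaling with branch
length, lineage-specific compact insertions, and sequence divergence
correlated with structural divergence. It does not reproduce: real
secondary-structure packing or side chains, structured loop divergence
(jitter is isotropic, whereas real cores diverge less than loops),
accessory domains that genuinely resemble each other across lineages (real
Ig-like domains do, and would partially align), or modelling error of
predicted structures. Passing the benchmark therefore demonstrates the
machinery is correct and well-calibrated on families with a clean rigid
core; it does not bound performance on predicted models of real proteins,
where alignability of accessory domains and non-isotropic divergence blur
both the core boundary and the TM matrix.

## Numerical and degenerate-input choices

* d₀ clamps at 0.5 Å below L ≈ 21; TM of an empty pairing is undefined
  (alignments need ≥ 3 pairs; Kabsch needs ≥ 3 non-collinear pairs and
  raises on rank-deficient covariance).
* The DP is exact and deterministic; all tie-breaks are fixed and
  documented above.
* Identical-model inputs produce star-like trees with ~0 branch lengths
  and a zero-signal flag in the pipeline report rather than an error.
* Bootstrap requires ≥ 4 rows, ≥ 2 columns and ≥ 2 distinct sequences.
* Problem sizes used by the test suite and the benchmark (6 taxa,
  300-residue cores, 20 replicates, 50–1000 bootstrap replicates) were
  chosen so the full analysis of one family takes seconds and the whole
  benchmark a few minutes on one CPU.

## Known limitations

* Alignment is sequential (order-preserving): circular permutations and
  topology-independent similarity are invisible.
* Progressive merging cannot revise early column decisions (no iterative
  tree/alignment re-estimation loops).
* The sequence phylogeny is distance-based (p-distance + NJ) by design;
  likelihood-based inference is out of scope.
* Architecture typing reports domain counts only; it does not classify
  folds, so "Ig-like" is an interpretation left to the user.
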