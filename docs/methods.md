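# Methods

## Background and model

B cells diversify their receptors (BCRs) by somatic hypermutation (SHM)
during affinity maturation, producing clones of cells related by point
mutations to a common V(D)J ancestor. Because B cells divide clonally, the
heavy chain (IGH) and the light chain (IGK/IGL) of one cell share a single
evolutionary history, so a clone's paired chains can be concatenated into
one alignment and analyzed under a single tree topology. The two loci do
not, however, mutate at the same rate: light chains accumulate roughly half
the SHM of their paired heavy chains. `bcrtrees` therefore supports three
inference paradigms over the concatenated alignment:

* **maximum parsimony** — Fitch small parsimony with an NNI hill-climb and a
  random-restart ratchet; branch lengths from most-parsimonious change
  assignments, in changes per site;
* **single-partition maximum likelihood** — one GTR model over the whole
  concatenation, Felsenstein pruning, per-branch 1-D likelihood
  optimization, NNI search from a neighbor-joining start tree;
* **scaled multi-partition maximum likelihood** — heavy and light intervals
  form separate partitions with their own GTR parameters; all partitions
  share one topology and branch-length set, and each partition multiplies
  the branch lengths by a scalar `c_p` estimated by maximum likelihood. The
  heavy scalar is pinned to 1: a joint rescaling of all scalars is absorbed
  by the branch lengths, so only ratios are identifiable.

Missing light chains (single-cell dropout, or bulk heavy-only reads mixed
into single-cell data) are encoded as runs of N and enter the likelihood as
all-ones conditional vectors — missing at random *within a partition*. This
is the crux of the branch-length story the package quantifies: parsimony
treats missing sites as change-free and underestimates lengths;
single-partition ML implicitly assumes missing light sites mutated at the
shared (mostly heavy) rate and overestimates; the scaled model learns the
light/heavy rate ratio from cells that have both chains and stays unbiased.

## Clone preparation

Input is an AIRR Rearrangement table with IMGT-gapped `sequence_alignment`
and `germline_alignment` (heavy D segment and N/P junction regions masked
as N), `locus`, `v_call`/`j_call`, `junction_length`, `clone_id`, and
optionally `cell_id`. Clone identification itself is out of scope; the
pipeline starts from assigned clones:

1. cells with more than one heavy chain are removed; light chains with no
   same-cell heavy chain are rejected; bulk reads become light-less cells
   keyed by a cell id synthesized from the sequence id;
2. within each clone, cells are grouped into subgroups by light-chain
   (V gene, J gene, junction length) — gene-level names, allele suffixes
   stripped. Ambiguous or multiple light rearrangements contribute every
   candidate (V, J) combination and the cell joins the largest compatible
   group (ties: lowest subgroup index). Grouping is greedy from the largest
   candidate group downward, with cells canonically sorted so the procedure
   is order-independent;
3. light-less cells join the subgroup of the heavy chain at minimum Hamming
   distance (N/gap positions skipped; ties: largest subgroup, then lowest
   index);
4. each (clone, subgroup) is treated as a separate clone downstream;
5. per-chain clonal germlines are position-wise consensus sequences of the
   members' germline alignments; ties and uninformative columns are masked
   to N;
6. heavy+light rows are concatenated (missing light = N-fill), and rows that
   are identical or differ only by ambiguous characters are collapsed into
   one tip, with informative characters filling ambiguous positions and a
   collapse map recording members.

Heavy-only datasets are produced by *matched filtering*: the heavy interval
of the collapsed paired alignment, keeping exactly the paired dataset's tip
set without re-collapsing, so paired and heavy-only trees are comparable
tip-for-tip.

## Numerical choices

* Coordinates are 0-based half-open internally; IMGT positions (e.g. the
  V region 1–312 used for SHM frequencies) convert at the boundary.
* GTR: frequencies are empirical counts from each partition's non-N sites
  (pseudocount 1); exchangeabilities are ML-estimated by L-BFGS-B on
  log-rates with GT pinned to 1 and bounds [0.02, 50]. Q is normalized to
  mean rate 1 under pi so branch lengths are substitutions/site. P(t) comes
  from the pi^(1/2)-symmetrized eigendecomposition, clipped at 0 and
  row-renormalized against round-off.
* Branch lengths live in [1e-9, 10] substitutions/site, optimized by
  bounded Brent (tolerance 1e-7) in repeated sweeps until the sweep gain is
  < 1e-6; each 1-D step is accepted only if it does not decrease the
  likelihood, so sweeps are monotone. After the first sweep the search uses
  a multiplicative window around the current value, falling back to the full
  interval whenever the local optimum presses against the window edge.
* The light scalar is optimized on [1e-3, 100] (tolerance 1e-6), in
  coordinate ascent with branch-length sweeps until the joint gain is
  < 1e-5. An all-N light partition makes the scalar unidentifiable; it is
  fixed at 1 with a warning.
* Tree search: neighbor-joining start (JC-corrected distances, pairwise
  deletion of N/gap, negative branch lengths clipped to 0), then NNI
  hill-climbing; each candidate swap is scored after re-optimizing the three
  local branch lengths and accepted if it improves the likelihood by more
  than 1e-6; a full sweep follows each accepted swap. Clones with fewer
  than 3 taxa return a star tree with a warning.
* Per-site likelihood work is compressed to unique column patterns per
  partition, with per-node scaling factors against underflow, and caches
  (partials, per-edge messages, transition matrices) invalidated along the
  path to the root when a branch changes.
* Scaled-model trees are reported in alignment-wide substitutions/site by
  multiplying the reference-unit branch lengths by the partition-length
  weighted mean scalar (sum_p |p| c_p / L). This makes tree lengths directly
  comparable across methods and against simulation truth; the fitted light
  scalar is reported separately.
* Parsimony branch lengths average the ACCTRAN-like and DELTRAN-like change
  assignments 0.5/0.5 (Sankoff traceback with deterministic tie-breaking:
  prefer placing the change on the current branch vs delaying it). Pure
  ACCTRAN alone is known to produce multi-modal length estimates in the
  3-taxon missing-light setting; the average damps that artifact, and both
  pure modes remain available via `assignment=`.

## Evaluation metrics

* **RF cluster distance**: both trees are rooted on the germline tip,
  internal branches shorter than a threshold (defaults 0.001 mutations per
  nucleotide / 0.003 per codon; tip branches never collapsed) are contracted
  into polytomies, and the distance is the number of rooted clades
  (tip-label sets of internal nodes) unique to each tree. Trivial clusters
  (singletons, the all-tip set) are excluded. Lower is more accurate when
  compared against a true tree.
* **Codon bootstrap**: codon columns are resampled with replacement within
  each partition (partition intervals padded down to codon boundaries so
  sampled codons never straddle partitions; trailing sites dropped with a
  warning). Support of a full-tree internal branch is the number of
  replicate trees containing the same tip-set cluster after identical
  collapsing; the mean is taken over the full tree's internal branches.
* **Tree length** is the sum of branch lengths; **divergence** of a tip is
  the branch-length path sum from the germline; **percent tree-length
  error** is (true − estimated)/true, positive for underestimates.

## Synthetic data

The simulator is the package's ground-truth source and emulates paired SHM
at clone scale:

* **Targeting.** Mutations are applied one event at a time: a position is
  drawn proportionally to the current 5-mer mutability of its context
  (contexts recomputed after every event, so positions can be hit more than
  once), and the replacement base follows the context's substitution
  distribution. The built-in table raises classic WRC/GYW hotspots to 4.0
  and lowers SYC/GRS coldspots to 0.3 relative mutability with uniform
  substitution; published 5-mer tables (S5F-style TSV: fivemer, mutability,
  A/C/G/T substitution probabilities) can be loaded for both chains.
  Contexts containing N fall back to mutability 1; N/gap positions are never
  mutated.
* **Triplets**: germline + two tips, three branches, a fixed 25 heavy and
  12 light mutation events per branch; the SC+bulk variant erases tip B's
  light chain. True branch length is (25+12)/690 events per site.
* **Clone-scale**: a uniform random coalescent-join topology with the
  germline at the root; per branch, heavy events ~ Poisson(mean) and light
  events ~ Poisson(mean x rate_ratio), rate_ratio 0.5 by default. The
  default branch mean of 4.0 heavy events puts simulated heavy V-region SHM
  near 6% (with light/heavy SHM ratio ~0.5), mid-range of what paired
  single-cell studies of expanded clones report; defaults Lh=360, Ll=330
  with uniform base composition stand in for empirical naive starting pairs.
  True branch lengths are realized events per concatenated site.
* **Masking** removes light chains from a per-clone share of cells as close
  as possible to the requested fraction while always keeping at least one
  paired cell per clone.
* The benchmark harness sweeps (replicate, clone, masking fraction, method,
  chain mode), scoring RF distance to the pruned true tree, percent
  tree-length error (heavy-only trees are scored against heavy-event truth),
  and optionally mean bootstrap; every run derives child seeds from one root
  seed and can write a metrics TSV plus a manifest.

What the generator does **not** emulate: affinity selection (topologies are
neutral random joins rather than selection-shaped genealogies),
insertion/deletion SHM, empirical V/J sequence composition and repertoire
structure, codon structure, or clone-size heterogeneity. Passing benchmarks
therefore demonstrate correct handling of missing data, partitioned rates
and topology search at realistic SHM loads — not robustness to selection or
annotation artifacts in real repertoires.

A consequence of simulating *events* (with repeat hits) as the truth: at 25
heavy + 12 light events per branch roughly 4% of events overwrite earlier
ones within a branch and a further ~2% are homoplasic across branches, so
minimal-change (parsimony) reconstructions are bounded ~6% below event-count
truth even with complete data, while likelihood methods recover multiple
hits through the substitution model. The package reports this honestly
rather than redefining truth as observed differences.

## Scale of the shipped benchmarks

The acceptance script simulates 40 clones of 20 tips (test suite: 20
clones), sweeps masking fractions {0, 0.25, 0.5, 0.75, 0.95}, and fits
single-partition and scaled ML per clone; triplet comparisons use 200
replicates. At 95% masking a 20-tip clone retains a single paired cell, so
the per-clone light scalar rests on ~10–20 light-chain events: its sampling
distribution is right-skewed (a mild upward mean bias in the scalar, hence a
~1–2% upward pull on mean tree length in that cell), and scaled tree-length
errors have a per-clone spread of ~10%. Means over the clone set are the
meaningful quantity; their Monte-Carlo standard error (~1.7% at 40 clones)
plus the single-paired-cell skew set the resolution limit of the shipped
configuration — per-fraction mean errors in the high-masking cells are
reproducible to a couple of percentage points, not to fractions of one.

## Known limitations

* NNI-only topology search (no SPR/TBR); hard polytomies are produced only
  by collapsing, not inferred directly.
* No rate heterogeneity across sites (no Gamma), no codon or hotspot-aware
  likelihood model (e.g. HLP-family models), and no repertoire-wide
  parameter sharing across clones; all parameters are per clone.
* "Unlinked" per-partition branch lengths are deliberately not offered.
* The scaled model assumes one light/heavy rate ratio per clone; real clones
  may vary.
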