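# Methods

`its2sim` is a simulation study in a package: it asks whether adding each
sequence's own RNA secondary structure to a fast-evolving marker (an
ITS2-like spacer, ~250 nt with a conserved four-helix fold) improves
distance-based phylogenetic reconstruction, compared to using the plain
sequence or a doubled-length sequence. This note records the models, the
design decisions that were genuinely open, the numerical choices, and what
the synthetic data can and cannot show.

## Substitution models

All models are general time-reversible (GTR): off-diagonal rates
`Q[i,j] = s[i,j] * pi[j]` with symmetric exchangeabilities `s` and
stationary frequencies `pi`, which gives detailed balance
`pi_i Q_ij = pi_j Q_ji` and makes `pi` a left null vector of `Q`.

Three alphabets are used:

* **4-state** nucleotides `(A, C, G, U)` — unpaired (loop) positions;
* **16-state** doublets, lexicographic over (5' base, 3' base) — a stem
  base pair evolves as one unit, so compensatory substitutions
  (`AU -> GC` via `GU`) are first-class events rather than two independent
  coincidences;
* **12-state** pseudoproteins, base x role (unpaired / opening / closing),
  base-major order — the alphabet in which sequence and structure are
  analysed jointly.

**Branch-length units.** Every branch length in the package is expected
substitutions per *site*. A 4- or 12-state matrix is normalized to mean
rate 1 per state; a doublet covers two sites, so the 16-state matrix is
normalized to mean rate 2 per doublet (`RateMatrix.sites_per_state = 2`).
With neutral stem parameters the doublet model is then *exactly* the
Kronecker sum of two copies of the 4-state model, and the marginal process
of each pair member reproduces the 4-state transition probabilities at the
same `t` — the independence limit that anchors the tests. This requires
dividing the doublet exchangeabilities by the shared base's frequency (a
no-op for uniform frequencies).

**Default parameter values.** No rate matrices estimated from biological
ITS2 alignments are bundled; the package ships structurally faithful
defaults, all replaceable from plain-text files (estimated matrices, where
available, drop in via `read_rate_matrix`):

* 4-state: uniform exchangeabilities and frequencies (Jukes-Cantor). Every
  closed-form oracle (transition probabilities, expected divergence,
  distance corrections) is exact under this choice.
* 16-state: Kronecker-sum construction plus two stem parameters —
  `stem_bonus = 2.0` multiplies exchangeabilities between two pairable
  doublets (WC or G·U), speeding compensatory change, and
  `pair_bias = 15.0` upweights the stationary frequencies of the six
  pairable doublets to 90% total mass. The bias is what makes stems behave
  like real ITS2 stems, which remain almost fully paired at any divergence;
  without it the stationary chance that a doublet can pair is 6/16, and the
  75% helix-transfer filter (below) would reject essentially every set at
  the upper half of the branch-length grid, making those study conditions
  unreachable. Setting both parameters to 1 recovers exactly two
  independent 4-state processes.
* 12-state: uniform-exchangeability GTR over the pseudoprotein states,
  used only for distance estimation on sequence-structure data.

Matrix exponentials go through `scipy.linalg.expm` (Padé +
scaling-and-squaring); rows are clamped at -1e-12 and renormalized.

## Synthetic ancestors

`AncestorSpec` lays out a 250-nt sequence as four hairpin helices (default
stems 8/10/16/11 bp, third strictly longest, as in real ITS2) separated by
single-stranded spacers. Stem pairs are sampled G·C vs A·U with
probability `gc_bias` (default 0.5, matching the uniform stationary
composition so simulations start at equilibrium); orientation is random;
loops are drawn from the 4-state stationary frequencies. The experiment
uses five ancestors with independent seeds, emulating template sequences
drawn from different eukaryote lineages; per-lineage length or composition
differences are not modeled — ancestors differ only through their seeds.

## Simulation and the ITS2-likeness filter

Sequences evolve root-to-tip along a reference tree; each branch draws
child states directly from transition-probability rows (exact for a
time-homogeneous chain — no event-by-event simulation). Unpaired sites use
the 4-state model, template base pairs jointly use the 16-state model. The
pairing pattern is fixed along the tree and there are no indels, so leaf
sequences are columnwise homologous and the identity alignment is the true
alignment. Random streams split per attempt as
`SeedSequence(scenario_seed, spawn_key=(attempt,))`, making runs
reproducible and order-independent.

Reference trees: `equidistant` (every edge the nominal length) and
`variable` (edges alternately 1.5x / 0.5x along a preorder enumeration);
shapes `balanced` (default) and `caterpillar`, or any Newick file — the
shape is configurable because no single canonical topology exists for this
kind of benchmark. The branch-length grid is
{0.025, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45} and is itself
configurable.

A simulated set is *accepted* as ITS2-like if every leaf's structure is
recoverable from the ancestral template by homology modeling: a template
pair is kept iff the target bases can pair (WC + G·U by default), and the
transfer score is 100 x kept/total over the whole structure, accepted at
>= 75% (inclusive). Per-helix accounting and a WC-only rule are switches;
the global fraction is the default, matching how template-transfer scores
are usually computed over a whole structure. Sets failing the filter are
re-simulated (rejection sampling, capped at 100x the requested count).

## Data sets and reconstruction

Per scenario the accepted sets are shuffled; the first half is the
**sequence** data set; the same sequences with homology-modeled individual
structures, encoded as pseudoproteins, form the **sequence-structure**
data set (the paired design: within a replicate both kinds contain
identical nucleotides); the second half is concatenated taxon-wise with
the first to make the **doubled** data set (k-th remaining set with k-th
selected set — any fixed bijection is statistically equivalent).

Distances: two estimators.

* `gtr_distance` — the matrix-free logdet-style GTR estimator
  `d = -tr(Pi log(Pi^-1 F))` with `F` the symmetrized relative pair-count
  matrix and `Pi` the mean observed frequencies. Consistent for any
  stationary reversible process, but it must resolve a K x K divergence
  matrix from the data: at 250 columns and K = 12 the log is undefined
  (non-positive eigenvalues) for most taxon pairs at the study's central
  divergences, i.e. it saturates long before the process does.
* `ModelDistance` — ML branch length under a *given* rate matrix (the
  distance correction used when the substitution model is fixed, as in
  ProfDist-style tools with their built-in 4x4 and 12x12 ITS2 matrices).
  Solved by safeguarded bisection on the likelihood score,
  batched over all pairs; equals the closed-form JC correction for 4-state
  JC data. This is the pipeline default (`estimator="model"`); the logdet
  estimator remains available (`estimator="logdet"`).

Saturated cells (likelihood increasing at the cap, or undefined log) are
flagged and capped at 10 substitutions/site. Identical rows give exactly 0.

Trees: Saitou-Nei Neighbor Joining with the Q-criterion; ties broken to
the lexicographically smallest index pair; negative branch-length
estimates clamped to 0. NJ is the default engine for the experiment so the
reconstruction method is held constant. A simplified Profile NJ is
provided for completeness: iteratively bootstrap, condense the
best-supported clade (threshold 0.95) into a per-column frequency profile,
recompute distances over profiles, repeat, and expand profiles at the end.
The exact profile heuristics of existing PNJ implementations are not
documented anywhere usable; this variant is specified behavior, not an
emulation of any particular tool.

Robustness: 100 nonparametric bootstrap pseudo-replicates over alignment
columns; a 12-state column carries base and role together, so pairing
information travels with the resampled site. Support is the percentage of
replicate NJ trees containing each internal bipartition of the
point-estimate tree. Accuracy: Robinson-Foulds (raw symmetric difference
of nontrivial bipartition sets, the PHYLIP treedist convention; normalized
variant divides by 2(n-3)) and quartet distance (explicit enumeration over
all C(n,4) subsets — exact and fast at n <= 18; normalized by C(n,4)).

## Experiment grid and problem sizes

The full design is 10 branch lengths x 5 ancestors x 6 reference trees
(10/14/18 taxa, equidistant/variable) = 300 scenarios x 2,000 accepted
sets = 600,000 sets — a cluster-scale computation. The package's default
`ExperimentPlan` keeps the same design at desk scale: 200 accepted sets
and 100 replicates per data-set kind per scenario, which runs one scenario
in minutes on one CPU. The acceptance script and the heavyweight tests use
50-100 replicates per condition with 100 bootstraps — sizes chosen so the
pooled means are stable (binomial error on a pooled support mean at
50 x 11 values is well under one support point) while a full grid sweep
stays in the minutes range. Full-scale numbers are one config edit away
(`ExperimentPlan.full_scale()`).

## What the synthetic data shows — and what it cannot

Reproduced at scaled settings with the default models:

* the support optimum for sequence-only data at branch length 0.05-0.1,
  with the 0.025 point penalized by lack of signal;
* declining robustness and accuracy with increasing branch length and
  taxon count;
* the robustness ordering doubled >= sequence-structure > sequence-only —
  structure adds support *without* adding columns (more states per
  column), marker doubling adds more still;
* a small accuracy edge of sequence-structure over sequence-only at equal
  length.

Not reproduced: sequence-structure being more accurate than *doubled*
sequences. In this pipeline the true alignment is known (no indels are
simulated and realignment is outside scope), and under an error-free
alignment two independent 250-column replicates simply halve the distance
variance — the doubled set approaches perfect topology recovery at
moderate divergence, which individual structures on 250 columns cannot
beat. In pipelines that *realign* every data set, structure has a second
pathway to accuracy: the 12-letter encoding improves the alignment itself,
and misalignment noise grows with marker length. With realignment excluded
by design, this package can test the robustness claims and the
within-length accuracy claim, but not a structure-beats-elongation
accuracy claim; its acceptance test states the full ordering and is
expected to fail on exactly that comparison.

## Numerical choices and degenerate inputs

* Eigen-decompositions are batched; pairs are grouped by their observed
  state support, and states unseen in a pair are dropped from that pair's
  computation. Defective matrices fall back to per-matrix handling and are
  flagged saturated.
* Bisection for ML distances: 30 iterations on [1e-9, 10], precision
  ~1e-8 substitutions/site.
* All-equal distance matrices (zero signal) run to completion through the
  deterministic tie-break; the pipeline flags such scenarios `degenerate`.
* Positions are 0-based internally, 1-based in diagnostics.
* Seeds: every scenario derives a 31-bit seed from the master seed via
  `SeedSequence(master, spawn_key=(index,))`; per-attempt and
  per-replicate streams spawn from it. Results are independent of
  execution order.

## Known limitations

* Substitution-model defaults are structurally faithful stand-ins, not
  estimates from biological alignments; quantities that depend on the
  precise rate values (e.g. exact support levels) should be read as
  qualitative.
* No indels, no site-rate heterogeneity, no structure evolution (the
  pairing pattern is inherited unchanged; only pairability is re-assessed
  by homology modeling).
* Quartet distance is O(n^4) by design — fine for n <= 18, not for large
  trees.
* The Profile NJ variant is a documented simplification; the experiment
  defaults to plain NJ.
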