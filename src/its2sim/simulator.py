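"""Simulate ITS2-like sequence evolution along reference trees.

Two substitution processes act on an annotated ancestor: unpaired sites
evolve independently under the 4-state nucleotide model, while the two
members of each stem base pair evolve *jointly* as one 16-state doublet, so
compensatory (pairing-preserving) change is possible.  The pairing pattern
itself is fixed along the tree and no indels occur, so leaf sequences are
columnwise homologous and the true alignment is the identity.

Sequence sets are accepted as ITS2-like when every leaf's structure is
recoverable from the ancestral template by homology modeling with at least
75% helix transfer; sets failing the filter are discarded and re-simulated.

Sampling draws each child state directly from the parent state's
transition-probability row at the branch length (exact for a
time-homogeneous Markov chain; no event-by-event simulation).  Per-set
random streams are split from the scenario seed with
``np.random.SeedSequence(scenario_seed, spawn_key=(set_index,))`` so runs
are reproducible and parallelizable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import RateMatrix, transition_matrix
from .structures import AnnotatedSequence, homology_model
from .synthetic_data import AncestorSpec, ModelBundle, default_substitution_models, generate_ancestor
from .trees import PhyloTree, TreeNode

BRANCH_LENGTH_GRID: tuple[float, ...] = (
    0.025, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45,
)

TRANSFER_THRESHOLD: float = 75.0


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation grid."""

    branch_length: float
    n_taxa: int = 14
    tree_class: str = "equidistant"  # or "variable"
    topology_shape: str = "balanced"  # or "caterpillar"
    ancestor: AncestorSpec = AncestorSpec()
    n_sets: int = 2000
    models: ModelBundle | None = None
    seed: int = 0
    transfer_threshold: float = TRANSFER_THRESHOLD

    def __post_init__(self):
        if self.branch_length <= 0:
            raise ValueError("branch_length must be > 0")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")

    def get_models(self) -> ModelBundle:
        return self.models if self.models is not None else default_substitution_models()


# ---------------------------------------------------------------------------
# reference trees


def generate_reference_tree(
    n_taxa: int,
    branch_length: float,
    tree_class: str = "equidistant",
    topology_shape: str = "balanced",
) -> PhyloTree:
    """Deterministic reference topology with the study's branch-length classes.

    ``equidistant`` gives every edge the nominal length; ``variable``
    alternates 1.5x / 0.5x of it along a preorder enumeration of edges, so
    the mean edge length stays at the nominal value.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if tree_class not in ("equidistant", "variable"):
        raise ValueError(f"unknown tree class {tree_class!r}")
    if topology_shape == "balanced":
        root = _balanced_topology(n_taxa)
    elif topology_shape == "caterpillar":
        root = _caterpillar_topology(n_taxa)
    else:
        raise ValueError(f"unknown topology shape {topology_shape!r}")

    tree = PhyloTree(root)
    factors = iter([1.5, 0.5] * (2 * n_taxa))
    for node in tree.preorder():
        for child in node.children:
            child.length = branch_length * (
                next(factors) if tree_class == "variable" else 1.0
            )
    return tree


def _leaf(i: int) -> TreeNode:
    return TreeNode(label=f"t{i + 1}")


def _balanced_topology(n: int) -> TreeNode:
    """As-balanced-as-possible unrooted binary topology (root trifurcation)."""

    def build(lo: int, hi: int) -> TreeNode:
        if hi - lo == 1:
            return _leaf(lo)
        mid = (lo + hi + 1) // 2
        return TreeNode(children=[build(lo, mid), build(mid, hi)])

    third = n // 3
    a, b = third, 2 * third
    return TreeNode(children=[build(0, a), build(a, b), build(b, n)])


def _caterpillar_topology(n: int) -> TreeNode:
    node = TreeNode(children=[_leaf(n - 2), _leaf(n - 1)])
    for i in range(n - 3, 0, -1):
        node = TreeNode(children=[_leaf(i), node])
    return TreeNode(children=[_leaf(0), node.children[0], node.children[1]])


# ---------------------------------------------------------------------------
# evolution along branches


def _site_partition(ancestor: AnnotatedSequence):
    """Indices of unpaired sites and (i, j) stem pairs of the template."""
    pairs = ancestor.structure.pairs
    paired = {p for ij in pairs for p in ij}
    unpaired = np.array(
        [i for i in range(len(ancestor)) if i not in paired], dtype=np.intp
    )
    pi = np.array([i for i, _ in pairs], dtype=np.intp)
    pj = np.array([j for _, j in pairs], dtype=np.intp)
    return unpaired, pi, pj


_BASE_INDEX = {b: i for i, b in enumerate("ACGU")}


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX[b] for b in seq], dtype=np.int8)


def _decode(codes: np.ndarray) -> str:
    return "".join("ACGU"[c] for c in codes)


def _sample_rows(P: np.ndarray, states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one categorical sample from each row P[states[k], :]."""
    cum = np.cumsum(P[states], axis=1)
    u = rng.random(len(states))[:, None]
    return (u > cum[:, :-1]).sum(axis=1)


def simulate_branch(
    parent: AnnotatedSequence,
    t: float,
    models: ModelBundle,
    rng: np.random.Generator,
    label: str = "",
) -> AnnotatedSequence:
    """Evolve one sequence along one branch of length ``t`` (subs/site)."""
    codes = _encode(parent.seq)
    unpaired, pi_idx, pj_idx = _site_partition(parent)
    p4 = transition_matrix(models.nucleotide, t)
    p16 = transition_matrix(models.doublet, t)
    child = codes.copy()
    if len(unpaired):
        child[unpaired] = _sample_rows(p4, codes[unpaired], rng)
    if len(pi_idx):
        doublet_states = 4 * codes[pi_idx] + codes[pj_idx]
        new = _sample_rows(p16, doublet_states, rng)
        child[pi_idx] = new // 4
        child[pj_idx] = new % 4
    return AnnotatedSequence(label or parent.label, _decode(child), parent.structure)


def simulate_set(
    tree: PhyloTree,
    ancestor: AnnotatedSequence,
    models: ModelBundle,
    seed: int | np.random.SeedSequence,
) -> list[AnnotatedSequence]:
    """Place the ancestor at the root and evolve it branch by branch.

    Returns leaf sequences only (the ancestor is not part of the data);
    every leaf keeps the ancestral structure annotation — the *observed*
    structure of a leaf is re-derived downstream by homology modeling.
    """
    rng = np.random.default_rng(seed)
    leaves: list[AnnotatedSequence] = []

    def walk(node: TreeNode, seq: AnnotatedSequence):
        for child in node.children:
            child_seq = simulate_branch(
                seq, child.length, models, rng, label=child.label or seq.label
            )
            if child.is_leaf:
                leaves.append(child_seq)
            else:
                walk(child, child_seq)

    walk(tree.root, ancestor)
    order = {lab: k for k, lab in enumerate(tree.leaf_labels())}
    leaves.sort(key=lambda s: order[s.label])
    return leaves


@dataclass
class AcceptanceLog:
    attempts: int = 0
    accepted: int = 0

    @property
    def rejection_rate(self) -> float:
        return 1.0 - self.accepted / self.attempts if self.attempts else 0.0

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.attempts if self.attempts else 0.0


def set_accepted(
    leaves: list[AnnotatedSequence],
    template: AnnotatedSequence,
    threshold: float = TRANSFER_THRESHOLD,
) -> bool:
    """ITS2-likeness filter: every sequence must reach the helix-transfer
    threshold against the ancestral template (inclusive)."""
    for leaf in leaves:
        _, percent = homology_model(template, leaf.seq)
        if percent < threshold:
            return False
    return True


def simulate_accepted_sets(
    cfg: ScenarioConfig,
    tree: PhyloTree | None = None,
    ancestor: AnnotatedSequence | None = None,
    max_attempts_factor: int = 100,
) -> tuple[list[list[AnnotatedSequence]], AcceptanceLog]:
    """Rejection-resample until ``cfg.n_sets`` sets pass the 75% filter."""
    if tree is None:
        tree = generate_reference_tree(
            cfg.n_taxa, cfg.branch_length, cfg.tree_class, cfg.topology_shape
        )
    if ancestor is None:
        ancestor = generate_ancestor(cfg.ancestor)
    models = cfg.get_models()
    cap = max_attempts_factor * cfg.n_sets
    log = AcceptanceLog()
    sets: list[list[AnnotatedSequence]] = []
    attempt = 0
    while len(sets) < cfg.n_sets:
        if attempt >= cap:
            raise RuntimeError(
                f"scenario (bl={cfg.branch_length}, n_taxa={cfg.n_taxa}, "
                f"{cfg.tree_class}/{cfg.topology_shape}, seed={cfg.seed}): "
                f"attempt cap {cap} reached with only {len(sets)} accepted sets"
            )
        ss = np.random.SeedSequence(cfg.seed, spawn_key=(attempt,))
        leaves = simulate_set(tree, ancestor, models, ss)
        attempt += 1
        log.attempts += 1
        if set_accepted(leaves, ancestor, cfg.transfer_threshold):
            sets.append(leaves)
            log.accepted += 1
    return sets, log
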