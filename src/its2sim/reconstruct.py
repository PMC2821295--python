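"""Distance-based tree reconstruction for the three data-set kinds.

From each accepted simulation replicate three character data sets are
built: the plain *sequence* set (4-state), the *sequence-structure* set
(the same sequences encoded over the 12-state pseudoprotein alphabet using
homology-modeled individual structures), and the *doubled* set (each
sequence concatenated with the same taxon's sequence from an independent
replicate — marker elongation without structure).

Pairwise distances use the general K-state GTR estimator

    d(a, b) = -tr( Pi * log( Pi^-1 F ) )

where ``F`` is the symmetrized relative-frequency matrix of aligned state
pairs and ``Pi`` the diagonal of the mean observed frequencies.  The
estimator is consistent for any stationary reversible process and needs no
externally estimated rate matrix; saturated cells (log undefined) are
flagged and capped.  Trees come from Neighbor Joining with the standard
Q-criterion (deterministic lowest-index tie-break, negative branch lengths
clamped to zero) or from a simplified Profile NJ variant, and robustness
from 100 nonparametric bootstrap pseudo-replicates over alignment columns
(12-state columns resample base and structural role together).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import NT_ALPHABET, PSEUDO_ALPHABET, RateMatrix, StateAlphabet
from .structures import (
    AnnotatedSequence,
    PSEUDO_LETTERS,
    encode_pseudoprotein,
    homology_model,
)
from .trees import PhyloTree, TreeNode

DEFAULT_SATURATION_CAP = 10.0
_EIG_FLOOR = 1e-9


# ---------------------------------------------------------------------------
# character alignments


@dataclass(frozen=True)
class CharacterAlignment:
    """Equal-length rows over a state alphabet, as integer codes."""

    labels: tuple[str, ...]
    data: np.ndarray  # (n_taxa, n_columns) integer state codes
    alphabet: StateAlphabet

    def __post_init__(self):
        if self.data.ndim != 2:
            raise ValueError("alignment data must be 2-D")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per row required")
        if self.data.size and (
            self.data.min() < 0 or self.data.max() >= self.alphabet.size
        ):
            raise ValueError("state codes outside alphabet")

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_sequences(cls, seqs: list[AnnotatedSequence]) -> "CharacterAlignment":
        """4-state alignment from equal-length sequences (identity alignment)."""
        lut = {b: i for i, b in enumerate(NT_ALPHABET.symbols)}
        data = np.array([[lut[b] for b in s.seq] for s in seqs], dtype=np.int8)
        return cls(tuple(s.label for s in seqs), data, NT_ALPHABET)

    @classmethod
    def from_pseudoproteins(cls, seqs: list[AnnotatedSequence]) -> "CharacterAlignment":
        """12-state alignment from sequences with (individual) structures."""
        lut = {c: i for i, c in enumerate(PSEUDO_LETTERS)}
        data = np.array(
            [[lut[c] for c in encode_pseudoprotein(s)] for s in seqs], dtype=np.int8
        )
        return cls(tuple(s.label for s in seqs), data, PSEUDO_ALPHABET)


def build_structure_set(
    seqs: list[AnnotatedSequence], template: AnnotatedSequence
) -> list[AnnotatedSequence]:
    """Attach homology-modeled individual structures to each sequence."""
    out = []
    for s in seqs:
        struct, _ = homology_model(template, s.seq)
        out.append(AnnotatedSequence(s.label, s.seq, struct))
    return out


def build_doubled_set(
    set_a: list[AnnotatedSequence], set_b: list[AnnotatedSequence]
) -> CharacterAlignment:
    """Concatenate two replicate sets taxon-wise (marker doubling)."""
    by_label = {s.label: s for s in set_b}
    if set(by_label) != {s.label for s in set_a}:
        raise ValueError("taxon labels of the two sets do not match")
    lut = {b: i for i, b in enumerate(NT_ALPHABET.symbols)}
    rows = [
        [lut[b] for b in s.seq + by_label[s.label].seq] for s in set_a
    ]
    return CharacterAlignment(
        tuple(s.label for s in set_a), np.array(rows, dtype=np.int8), NT_ALPHABET
    )


# ---------------------------------------------------------------------------
# GTR distances


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # (n, n) symmetric, zero diagonal
    saturated: np.ndarray  # (n, n) bool

    def __post_init__(self):
        v = self.values
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(v)).max() > 0:
            raise ValueError("distance matrix diagonal must be zero")


def _distances_from_counts(
    counts: np.ndarray, cap: float = DEFAULT_SATURATION_CAP
) -> tuple[np.ndarray, np.ndarray]:
    """GTR distances for a batch of K x K pair-count matrices.

    Returns ``(d, saturated)``; entries whose log is undefined (zero or
    negative eigenvalues, non-finite result) are flagged and set to ``cap``.
    States unobserved in a given pair of rows are dropped from that pair's
    computation.
    """
    C = np.asarray(counts, dtype=float)
    squeeze = C.ndim == 2
    if squeeze:
        C = C[None]
    total = C.sum(axis=(1, 2), keepdims=True)
    if (total == 0).any():
        raise ValueError("empty (zero-length) rows")
    F = (C + C.transpose(0, 2, 1)) / (2.0 * total)
    pi = F.sum(axis=2)  # symmetric F: row sums = mean frequencies
    P = C.shape[0]
    d = np.full(P, cap)
    sat = np.ones(P, dtype=bool)

    masks = pi > 0
    packed = np.packbits(masks, axis=1)
    _, inverse = np.unique(packed, axis=0, return_inverse=True)
    for g in range(inverse.max() + 1):
        idx = np.where(inverse == g)[0]
        mask = masks[idx[0]]
        sub = F[np.ix_(idx, np.where(mask)[0], np.where(mask)[0])]
        spi = pi[np.ix_(idx, np.where(mask)[0])]
        M = sub / spi[:, :, None]
        dg, sg = _trace_log_batch(M, spi)
        d[idx] = np.where(sg, cap, np.maximum(dg, 0.0))
        sat[idx] = sg
    if squeeze:
        return d[0], sat[0]
    return d, sat


def _trace_log_batch(M: np.ndarray, pi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """-sum_i pi_i [log M]_ii for a stack of matrices, with failure flags."""
    P = M.shape[0]
    d = np.zeros(P)
    sat = np.zeros(P, dtype=bool)
    try:
        w, V = np.linalg.eig(M)
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        # defective matrix somewhere in the stack: fall back per matrix
        for p in range(P):
            try:
                dp, sp = _trace_log_batch(M[p : p + 1], pi[p : p + 1])
                d[p], sat[p] = dp[0], sp[0]
            except np.linalg.LinAlgError:
                sat[p] = True
        return d, sat
    bad = (w.real <= _EIG_FLOOR) & (np.abs(w.imag) < _EIG_FLOOR)
    sat |= bad.any(axis=1)
    logw = np.log(np.where(bad, 1.0, w))
    diag = np.einsum("pik,pk,pki->pi", V, logw, Vinv).real
    d = -(pi * diag).sum(axis=1)
    sat |= ~np.isfinite(d)
    return d, sat


class ModelDistance:
    """ML branch-length estimator under a fixed reversible rate matrix.

    This is the distance correction applied when the substitution matrix is
    *given* (the ProfDist family): for each pair of rows the branch length
    maximizes the likelihood ``prod_xy (pi_x P(t)_xy)^C_xy`` of the observed
    state-pair counts ``C`` under ``P(t) = exp(Q t)``.  The score equation
    is solved by safeguarded bisection, batched over all pairs.  Pairs whose
    likelihood keeps increasing at the cap (data at or beyond stationarity)
    are flagged saturated and capped, identical rows give 0.

    For 4-state data under the Jukes-Cantor matrix the estimate equals the
    closed-form JC correction; unlike the logdet estimator it stays usable
    for 12-state data at a few hundred columns, where a 12 x 12 divergence
    matrix cannot be resolved.
    """

    def __init__(self, model: RateMatrix, cap: float = DEFAULT_SATURATION_CAP):
        self.model = model
        self.cap = cap
        pi = model.frequencies
        sq = np.sqrt(pi)
        sym = model.Q * (sq[:, None] / sq[None, :])
        lam, V = np.linalg.eigh((sym + sym.T) / 2.0)
        self._lam = lam
        self._A = V / sq[:, None]  # Pi^{-1/2} V
        self._B = V.T * sq[None, :]  # V^T Pi^{1/2}

    def _score(self, counts: np.ndarray, t: np.ndarray) -> np.ndarray:
        """d/dt log-likelihood for each pair at its own t."""
        E = np.exp(self._lam[None, :] * t[:, None])  # (P, K)
        Pt = (self._A[None, :, :] * E[:, None, :]) @ self._B
        dPt = (self._A[None, :, :] * (E * self._lam[None, :])[:, None, :]) @ self._B
        Pt = np.clip(Pt, 1e-300, None)
        return (counts * (dPt / Pt)).sum(axis=(1, 2))

    def distances(
        self, counts: np.ndarray, iterations: int = 30
    ) -> tuple[np.ndarray, np.ndarray]:
        C = np.asarray(counts, dtype=float)
        squeeze = C.ndim == 2
        if squeeze:
            C = C[None]
        C = (C + C.transpose(0, 2, 1)) / 2.0
        P, k = C.shape[0], C.shape[1]
        off = C.sum(axis=(1, 2)) - np.einsum("pii->p", C)
        d = np.zeros(P)
        sat = np.zeros(P, dtype=bool)
        active = off > 0  # identical rows stay at d = 0
        if active.any():
            idx = np.where(active)[0]
            hi_score = self._score(C[idx], np.full(len(idx), self.cap))
            still_up = hi_score > 0
            sat[idx[still_up]] = True
            d[idx[still_up]] = self.cap
            idx = idx[~still_up]
            lo = np.full(len(idx), 1e-9)
            hi = np.full(len(idx), self.cap)
            Ci = C[idx]
            for _ in range(iterations):
                mid = (lo + hi) / 2.0
                up = self._score(Ci, mid) > 0
                lo = np.where(up, mid, lo)
                hi = np.where(up, hi, mid)
            d[idx] = (lo + hi) / 2.0
        if squeeze:
            return d[0], sat[0]
        return d, sat


def model_distance(
    row_a: np.ndarray | str,
    row_b: np.ndarray | str,
    model: RateMatrix,
    cap: float = DEFAULT_SATURATION_CAP,
) -> float:
    """Pairwise ML distance between two rows under a given rate matrix."""
    a, b = (_coerce_row(r) for r in (row_a, row_b))
    if len(a) != len(b):
        raise ValueError("rows must have equal length")
    if len(a) == 0:
        raise ValueError("zero-length rows")
    k = model.size
    counts = np.zeros((k, k))
    np.add.at(counts, (a, b), 1.0)
    d, _ = ModelDistance(model, cap).distances(counts)
    return float(d)


def gtr_distance(
    row_a: np.ndarray | str,
    row_b: np.ndarray | str,
    k: int | None = None,
    cap: float = DEFAULT_SATURATION_CAP,
) -> float:
    """Pairwise GTR distance (substitutions per site) between two rows.

    Rows may be integer code arrays or nucleotide strings.  Saturated
    pairs return ``cap``.
    """
    a, b = (_coerce_row(r) for r in (row_a, row_b))
    if len(a) != len(b):
        raise ValueError("rows must have equal length")
    if len(a) == 0:
        raise ValueError("zero-length rows")
    if k is None:
        k = int(max(a.max(), b.max())) + 1
    counts = np.zeros((k, k))
    np.add.at(counts, (a, b), 1.0)
    d, _ = _distances_from_counts(counts, cap)
    return float(d)


def _coerce_row(row) -> np.ndarray:
    if isinstance(row, str):
        lut = {b: i for i, b in enumerate(NT_ALPHABET.symbols)}
        return np.array([lut[b] for b in row], dtype=np.intp)
    return np.asarray(row, dtype=np.intp)


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def _pair_counts(data: np.ndarray, k: int, columns: np.ndarray | None = None) -> np.ndarray:
    """(n_pairs, K, K) state-pair counts for all row pairs of an alignment."""
    I, J = _pair_indices(data.shape[0])
    X = data if columns is None else data[:, columns]
    codes = k * X[I].astype(np.int32) + X[J]
    P = len(I)
    offsets = (np.arange(P, dtype=np.int32) * (k * k))[:, None]
    flat = np.bincount((codes + offsets).ravel(), minlength=P * k * k)
    return flat.reshape(P, k, k).astype(float)


def distance_matrix(
    aln: CharacterAlignment,
    cap: float = DEFAULT_SATURATION_CAP,
    columns: np.ndarray | None = None,
    model: RateMatrix | None = None,
) -> DistanceMatrix:
    """All pairwise distances of an alignment (optionally on a column
    resample), with saturation flags.

    Uses the logdet-style GTR estimator by default, or the fixed-model ML
    estimator when ``model`` is given.
    """
    n, k = aln.n_taxa, aln.alphabet.size
    counts = _pair_counts(aln.data, k, columns)
    if model is not None:
        d, sat = ModelDistance(model, cap).distances(counts)
    else:
        d, sat = _distances_from_counts(counts, cap)
    I, J = _pair_indices(n)
    values = np.zeros((n, n))
    values[I, J] = values[J, I] = d
    flags = np.zeros((n, n), dtype=bool)
    flags[I, J] = flags[J, I] = sat
    return DistanceMatrix(aln.labels, values, flags)


# ---------------------------------------------------------------------------
# Neighbor Joining


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei NJ with deterministic tie-breaking.

    The minimal Q-criterion cell is chosen as the lexicographically
    smallest (i, j) pair among ties; estimated negative branch lengths are
    clamped to zero.  Returns an unrooted tree (trifurcating root) for
    n >= 4, or the 3-taxon star for n = 3.
    """
    d = D.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in D.labels]
    n = len(nodes)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    while n > 3:
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        q[np.tril_indices(n)] = np.inf
        i, j = np.unravel_index(np.argmin(q), q.shape)  # row-major: lowest (i, j)
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        new = TreeNode(children=[child_i, child_j])
        dk = (d[i] + d[j] - d[i, j]) / 2
        keep = [x for x in range(n) if x not in (i, j)]
        d_new = np.empty((n - 1, n - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        d_new[-1, -1] = 0.0
        nodes = [nodes[x] for x in keep] + [new]
        d = d_new
        n -= 1
    a, b, c = nodes
    a.length = max((d[0, 1] + d[0, 2] - d[1, 2]) / 2, 0.0)
    b.length = max((d[0, 1] + d[1, 2] - d[0, 2]) / 2, 0.0)
    c.length = max((d[0, 2] + d[1, 2] - d[0, 1]) / 2, 0.0)
    return PhyloTree(TreeNode(children=[a, b, c]))


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    aln: CharacterAlignment,
    n_replicates: int = 100,
    seed: int | np.random.SeedSequence = 0,
    cap: float = DEFAULT_SATURATION_CAP,
    model: RateMatrix | None = None,
    return_replicates: bool = False,
):
    """Nonparametric bootstrap over alignment columns.

    Builds the point-estimate NJ tree, then ``n_replicates`` trees from
    column resamples (a 12-state column carries base and role together by
    construction), and reports for each internal bipartition of the point
    tree the percentage of replicate trees containing it.

    Returns ``(tree, supports)`` where ``supports`` maps each canonical
    bipartition (frozenset of labels) to a value in [0, 100]; with
    ``return_replicates`` the list of replicate bipartition sets is
    appended.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n, k, L = aln.n_taxa, aln.alphabet.size, aln.n_columns
    calc = None if model is None else ModelDistance(model, cap)
    point = neighbor_joining(distance_matrix(aln, cap, model=model))
    point_bips = point.bipartitions()
    hits = {bp: 0 for bp in point_bips}
    replicate_sets = []
    I, J = _pair_indices(n)
    base_codes = (k * aln.data[I].astype(np.int32) + aln.data[J])
    offsets = (np.arange(len(I), dtype=np.int32) * (k * k))[:, None]
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        counts = np.bincount(
            (base_codes[:, cols] + offsets).ravel(), minlength=len(I) * k * k
        ).reshape(len(I), k, k).astype(float)
        if calc is not None:
            d, sat = calc.distances(counts)
        else:
            d, sat = _distances_from_counts(counts, cap)
        values = np.zeros((n, n))
        values[I, J] = values[J, I] = d
        tree = neighbor_joining(
            DistanceMatrix(aln.labels, values, np.zeros((n, n), dtype=bool))
        )
        bips = tree.bipartitions()
        for bp in point_bips:
            if bp in bips:
                hits[bp] += 1
        if return_replicates:
            replicate_sets.append(bips)
    supports = {bp: 100.0 * c / n_replicates for bp, c in hits.items()}
    if return_replicates:
        return point, supports, replicate_sets
    return point, supports


# ---------------------------------------------------------------------------
# simplified Profile Neighbor Joining


def _freq_rows(aln: CharacterAlignment) -> np.ndarray:
    n, L, k = aln.n_taxa, aln.n_columns, aln.alphabet.size
    R = np.zeros((n, L, k))
    R[np.arange(n)[:, None], np.arange(L)[None, :], aln.data] = 1.0
    return R


def _profile_distances(R: np.ndarray, cap: float) -> np.ndarray:
    """GTR distances between rows of expected state frequencies."""
    n = R.shape[0]
    I, J = _pair_indices(n)
    counts = np.einsum("plk,plm->pkm", R[I], R[J])
    d, _ = _distances_from_counts(counts, cap)
    values = np.zeros((n, n))
    values[I, J] = values[J, I] = d
    return values


def profile_neighbor_joining(
    aln: CharacterAlignment,
    support_threshold: float = 0.95,
    n_replicates: int = 100,
    seed: int | np.random.SeedSequence = 0,
    cap: float = DEFAULT_SATURATION_CAP,
) -> PhyloTree:
    """Simplified Profile NJ.

    Iteratively: build the NJ tree and bootstrap it; condense the best
    clade whose support reaches ``support_threshold`` into a frequency
    profile (columnwise mean of its members' state frequencies); recompute
    distances treating profiles as rows of expected frequencies; repeat
    until no clade qualifies.  The final tree re-expands every profile to
    the subtree it condensed.
    """
    if not (0.5 < support_threshold <= 1.0):
        raise ValueError("support threshold must lie in (0.5, 1.0]")
    rng = np.random.default_rng(seed)
    R = _freq_rows(aln)
    labels = list(aln.labels)
    subtrees: dict[str, TreeNode] = {}
    profile_count = 0

    while True:
        n, L = R.shape[0], R.shape[1]
        if n < 4:
            break
        values = _profile_distances(R, cap)
        dm = DistanceMatrix(tuple(labels), values, np.zeros((n, n), dtype=bool))
        tree = neighbor_joining(dm)
        hits: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
        for _ in range(n_replicates):
            cols = rng.integers(0, L, size=L)
            v = _profile_distances(R[:, cols, :], cap)
            bips = neighbor_joining(
                DistanceMatrix(tuple(labels), v, np.zeros((n, n), dtype=bool))
            ).bipartitions()
            for bp in hits:
                if bp in bips:
                    hits[bp] += 1
        candidates = []
        clade_nodes = _clade_map(tree)
        for bp, c in hits.items():
            frac = c / n_replicates
            if frac < support_threshold or bp not in clade_nodes:
                continue
            candidates.append((-frac, len(bp), tuple(sorted(bp)), bp))
        if not candidates:
            break
        *_, bp_chosen = min(candidates)
        node, members = clade_nodes[bp_chosen]
        member_set = set(members)
        name = f"@profile{profile_count}"
        profile_count += 1
        subtrees[name] = node
        idx = [i for i, lab in enumerate(labels) if lab in member_set]
        rest = [i for i in range(len(labels)) if i not in idx]
        profile_row = R[idx].mean(axis=0, keepdims=True)
        R = np.concatenate([R[rest], profile_row], axis=0)
        labels = [labels[i] for i in rest] + [name]

    values = _profile_distances(R, cap)
    tree = neighbor_joining(
        DistanceMatrix(tuple(labels), values, np.zeros((len(labels),) * 2, dtype=bool))
    )
    _expand_profiles(tree.root, subtrees)
    return PhyloTree(tree.root)


def _clade_map(tree: PhyloTree) -> dict[frozenset, tuple[TreeNode, frozenset]]:
    """Canonical bipartition -> (node, leaf set below it) realizing one side."""
    out: dict[frozenset, tuple[TreeNode, frozenset]] = {}
    all_labels = frozenset(tree.leaf_labels())
    anchor = min(all_labels)
    nlv = len(all_labels)

    def below(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.label])
        s = frozenset().union(*(below(c) for c in node.children))
        if 2 <= len(s) <= nlv - 2:
            key = s if anchor not in s else all_labels - s
            out.setdefault(key, (node, s))
        return s

    below(tree.root)
    return out


def _expand_profiles(node: TreeNode, subtrees: dict[str, TreeNode]) -> None:
    for i, child in enumerate(node.children):
        if child.is_leaf and child.label in subtrees:
            sub = subtrees[child.label]
            sub.length = child.length
            node.children[i] = sub
            _expand_profiles(sub, subtrees)
        else:
            _expand_profiles(child, subtrees)
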