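"""K-state general time-reversible (GTR) substitution models.

Three alphabets are used throughout the package:

* the 4-state nucleotide alphabet ``(A, C, G, U)``,
* the 16-state doublet alphabet of ordered base pairs, lexicographic over
  (5' base, 3' base) — the coevolving unit of a stem position,
* the 12-state pseudoprotein alphabet combining each nucleotide with its
  structural role (unpaired / opening / closing), base-major order.

A GTR model is parameterized by symmetric exchangeabilities ``s`` and
stationary frequencies ``pi``; the instantaneous rates are
``Q[i, j] = s[i, j] * pi[j]`` (i != j) with rows summing to zero.  Branch
lengths are expected substitutions per *site*: a 4- or 12-state model is
scaled to mean rate 1 per state, a doublet model to mean rate 2 per doublet
(one doublet covers two sites), recorded in ``RateMatrix.sites_per_state``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "U")

#: the 16 ordered pairs, lexicographic over (5' base, 3' base)
DOUBLETS: tuple[str, ...] = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)

#: structural roles of a position, in fixed order
ROLES: tuple[str, ...] = ("unpaired", "opening", "closing")

#: 12 pseudoprotein states, base-major: A., A(, A), C., C(, C), ...
PSEUDO_STATES: tuple[str, ...] = tuple(
    f"{b}{m}" for b in NUCLEOTIDES for m in (".", "(", ")")
)

#: base pairs treated as formable in a stem: Watson-Crick plus G·U wobble
PAIRABLE: frozenset[str] = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})


@dataclass(frozen=True)
class StateAlphabet:
    """Ordered set of substitution-model states."""

    symbols: tuple[str, ...]
    name: str = ""

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.symbols)


NT_ALPHABET = StateAlphabet(NUCLEOTIDES, name="nucleotide")
DOUBLET_ALPHABET = StateAlphabet(DOUBLETS, name="doublet")
PSEUDO_ALPHABET = StateAlphabet(PSEUDO_STATES, name="pseudoprotein")


@dataclass(frozen=True)
class RateMatrix:
    """A normalized GTR rate matrix over a :class:`StateAlphabet`.

    ``Q`` satisfies detailed balance ``pi_i Q_ij = pi_j Q_ji`` and is scaled
    so that the mean rate ``-sum_i pi_i Q_ii`` equals ``sites_per_state``
    (1 for single-site alphabets, 2 for doublets), making branch lengths
    expected substitutions per site for every model.
    """

    alphabet: StateAlphabet
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    Q: np.ndarray
    sites_per_state: int = 1

    @property
    def size(self) -> int:
        return self.alphabet.size

    def mean_rate(self) -> float:
        return float(-np.sum(self.frequencies * np.diag(self.Q)))


def build_gtr_rate_matrix(
    exchangeabilities: np.ndarray,
    frequencies: np.ndarray,
    alphabet: StateAlphabet | None = None,
    sites_per_state: int = 1,
) -> RateMatrix:
    """Assemble and normalize a GTR rate matrix.

    Parameters
    ----------
    exchangeabilities
        Symmetric non-negative K x K array; the diagonal is ignored.
    frequencies
        Strictly positive stationary frequencies summing to 1.
    alphabet
        Optional state labels; defaults to the standard alphabet of size K
        (4, 12 or 16) or anonymous numbered states otherwise.
    sites_per_state
        Number of alignment sites one state covers (2 for doublet models);
        the mean rate is normalized to this value.
    """
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(frequencies, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError(f"exchangeabilities must be square, got shape {s.shape}")
    k = s.shape[0]
    if pi.shape != (k,):
        raise ValueError(f"frequencies have shape {pi.shape}, expected ({k},)")
    asym = np.abs(s - s.T)
    if asym.max() > 1e-9:
        i, j = np.unravel_index(np.argmax(asym), s.shape)
        raise ValueError(
            f"exchangeabilities not symmetric: s[{i},{j}]={s[i, j]} != s[{j},{i}]={s[j, i]}"
        )
    off = ~np.eye(k, dtype=bool)
    if (s[off] < 0).any():
        i, j = [int(x[0]) for x in np.where((s < 0) & off)]
        raise ValueError(f"negative exchangeability at s[{i},{j}]={s[i, j]}")
    if (pi <= 0).any():
        i = int(np.argmin(pi))
        raise ValueError(f"frequency pi[{i}]={pi[i]} must be strictly positive")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {pi.sum():.12f}, expected 1")
    if not (s[off] > 0).any():
        raise ValueError("all exchangeabilities are zero")
    if alphabet is None:
        alphabet = _default_alphabet(k)

    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -np.sum(pi * np.diag(q))
    q = q * (sites_per_state / mean_rate)
    s_scaled = s * (sites_per_state / mean_rate)
    return RateMatrix(alphabet, s_scaled, pi, q, sites_per_state=sites_per_state)


def _default_alphabet(k: int) -> StateAlphabet:
    if k == 4:
        return NT_ALPHABET
    if k == 16:
        return DOUBLET_ALPHABET
    if k == 12:
        return PSEUDO_ALPHABET
    return StateAlphabet(tuple(f"S{i}" for i in range(k)), name=f"{k}-state")


def transition_matrix(model: RateMatrix, t: float) -> np.ndarray:
    """Transition probabilities ``P = exp(Q t)`` for branch length ``t``.

    ``t`` is in expected substitutions per site; the doublet model's rate
    normalization (2 per doublet) makes the same ``t`` usable for paired and
    unpaired positions.  Rows are renormalized after clamping roundoff
    negatives below 1e-12.
    """
    if not np.isfinite(t) or t < 0:
        raise ValueError(f"branch length must be finite and >= 0, got {t}")
    p = expm(model.Q * t)
    if (p < -1e-12).any():
        raise ValueError("matrix exponential produced substantially negative entries")
    p = np.clip(p, 0.0, None)
    return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# doublet-model construction


def doublet_model(
    base: RateMatrix, stem_bonus: float = 2.0, pair_bias: float = 1.0
) -> RateMatrix:
    """Build a 16-state doublet model from a 4-state nucleotide model.

    The exchangeabilities are the Kronecker sum of the base model (only
    single-base changes have positive rate), multiplied by ``stem_bonus``
    on changes between two pairable doublets (WC or G·U — compensated,
    pairing-preserving substitutions).  Stationary frequencies are the
    product ``pi_i * pi_j`` upweighted by ``pair_bias`` on pairable
    doublets, then renormalized; ``pair_bias > 1`` concentrates stationary
    mass on formable pairs the way conserved stem columns do.  With both
    factors at 1 the model is exactly two independent copies of ``base``.
    """
    if base.size != 4:
        raise ValueError("doublet model requires a 4-state base model")
    if stem_bonus <= 0 or pair_bias <= 0:
        raise ValueError("stem_bonus and pair_bias must be positive")
    s4, pi4 = base.exchangeabilities, base.frequencies
    k = 16
    s = np.zeros((k, k))
    pi = np.empty(k)
    pairable = np.array([d in PAIRABLE for d in DOUBLETS])
    for x in range(k):
        a, b = divmod(x, 4)
        pi[x] = pi4[a] * pi4[b] * (pair_bias if pairable[x] else 1.0)
        for y in range(k):
            c, d = divmod(y, 4)
            # dividing by the shared base's frequency makes Q (at neutral
            # bonus/bias) exactly the Kronecker sum of two base models
            if a == c and b != d:
                s[x, y] = s4[b, d] / pi4[a]
            elif b == d and a != c:
                s[x, y] = s4[a, c] / pi4[b]
            if s[x, y] and pairable[x] and pairable[y]:
                s[x, y] *= stem_bonus
    pi /= pi.sum()
    return build_gtr_rate_matrix(s, pi, DOUBLET_ALPHABET, sites_per_state=2)


# ---------------------------------------------------------------------------
# plain-text rate-matrix files
#
# line 1: K; then K rows of exchangeabilities; then one row of K
# frequencies.  '#' starts a comment.


def read_rate_matrix(path, sites_per_state: int | None = None) -> RateMatrix:
    """Read a GTR model from the plain-text exchangeability/frequency format."""
    tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens:
        raise ValueError(f"{path}: empty rate-matrix file")
    k = int(tokens[0])
    need = 1 + k * k + k
    if len(tokens) != need:
        raise ValueError(f"{path}: expected {need} numbers for K={k}, got {len(tokens)}")
    vals = np.array([float(x) for x in tokens[1:]])
    s = vals[: k * k].reshape(k, k)
    pi = vals[k * k :]
    if sites_per_state is None:
        sites_per_state = 2 if k == 16 else 1
    return build_gtr_rate_matrix(s, pi, sites_per_state=sites_per_state)


def write_rate_matrix(model: RateMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# GTR model over {model.alphabet.name or 'states'}\n")
        fh.write(f"{model.size}\n")
        for row in model.exchangeabilities:
            fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")
        fh.write(" ".join(f"{x:.10g}" for x in model.frequencies) + "\n")
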