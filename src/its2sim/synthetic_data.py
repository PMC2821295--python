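"""Synthetic ITS2-like ancestors and the default substitution-model bundle.

Real ITS2 sequences are ~200-300 nt with a conserved secondary structure of
four helices, the third being the longest.  The generator here emulates
that shape: it lays out four hairpin helices separated by single-stranded
spacers, samples stem base pairs (G·C vs A·U with a configurable bias,
random orientation) and draws loop/spacer bases from the nucleotide model's
stationary frequencies, so simulations start at compositional equilibrium.

The default model bundle stands in for substitution matrices estimated from
biological ITS2 alignments: a uniform-exchangeability 4-state GTR for
unpaired sites, a 16-state doublet model for stems whose stationary mass
concentrates on formable (WC/G·U) pairs — stems in real ITS2 stay paired
through compensatory change, and the acceptance filter (75% helix transfer
at every branch length of the study grid) requires exactly that — and a
uniform 12-state GTR over the pseudoprotein alphabet for distance
estimation on sequence-structure data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    NT_ALPHABET,
    PSEUDO_ALPHABET,
    RateMatrix,
    build_gtr_rate_matrix,
    doublet_model,
)
from .structures import AnnotatedSequence, SecondaryStructure


@dataclass(frozen=True)
class AncestorSpec:
    """Layout of a synthetic ITS2-like ancestor.

    ``helix_stem_lengths`` are base pairs per helix (third strictly
    longest); ``loop_lengths`` are the five single-stranded runs: before
    helix 1, hairpin loops... laid out as spacer, helix, spacer, ... with
    each helix closed by a terminal loop taken from its spacer budget.
    Concretely the layout is::

        spacer0 H1( loop1 )H1 spacer... — see generate_ancestor

    ``2 * sum(stems) + sum(loops) == total_length`` must hold.
    """

    total_length: int = 250
    helix_stem_lengths: tuple[int, int, int, int] = (8, 10, 16, 11)
    loop_lengths: tuple[int, ...] = (12, 8, 24, 8, 26, 8, 30, 8, 36)
    gc_bias: float = 0.5
    seed: int = 0

    def __post_init__(self):
        stems = self.helix_stem_lengths
        if len(stems) != 4:
            raise ValueError("exactly four helices are required")
        if not all(s >= 2 for s in stems):
            raise ValueError("each helix needs at least 2 base pairs")
        if not all(stems[2] > s for i, s in enumerate(stems) if i != 2):
            raise ValueError(
                f"third helix ({stems[2]} bp) must be strictly the longest, got {stems}"
            )
        if len(self.loop_lengths) != 9:
            raise ValueError(
                "loop_lengths must have 9 entries: 5 spacers interleaved with 4 hairpin loops"
            )
        if any(l < 0 for l in self.loop_lengths):
            raise ValueError("loop lengths must be non-negative")
        if any(self.loop_lengths[i] < 3 for i in (1, 3, 5, 7)):
            raise ValueError("hairpin loops need at least 3 unpaired bases")
        total = 2 * sum(stems) + sum(self.loop_lengths)
        if total != self.total_length:
            raise ValueError(
                f"2*stems + loops = {total} inconsistent with total_length {self.total_length}"
            )
        if not (0.0 <= self.gc_bias <= 1.0):
            raise ValueError("gc_bias must be a probability")


def generate_ancestor(
    spec: AncestorSpec = AncestorSpec(),
    label: str = "ancestor",
    nt_frequencies: np.ndarray | None = None,
) -> AnnotatedSequence:
    """Sample an ancestral sequence + structure from an :class:`AncestorSpec`.

    Deterministic given ``spec.seed``.  Unpaired bases are drawn from
    ``nt_frequencies`` (default uniform, the 4-state model's stationary
    distribution); each stem pair is G·C with probability ``gc_bias`` and
    A·U otherwise, in random orientation.
    """
    rng = np.random.default_rng(spec.seed)
    if nt_frequencies is None:
        nt_frequencies = np.full(4, 0.25)
    bases = np.array(list("ACGU"))

    seq = ["?"] * spec.total_length
    pairs: list[tuple[int, int]] = []
    loops = list(spec.loop_lengths)
    pos = 0
    unpaired_positions: list[int] = []

    def add_loop(n: int):
        nonlocal pos
        unpaired_positions.extend(range(pos, pos + n))
        pos += n

    for h in range(4):
        add_loop(loops[2 * h])  # spacer before helix h
        stem = spec.helix_stem_lengths[h]
        loop = loops[2 * h + 1]
        open_start = pos
        close_end = pos + 2 * stem + loop  # exclusive
        for k in range(stem):
            pairs.append((open_start + k, close_end - 1 - k))
        pos = open_start + stem
        add_loop(loop)
        pos = close_end
    add_loop(loops[8])  # trailing spacer
    assert pos == spec.total_length

    draws = rng.choice(4, size=len(unpaired_positions), p=nt_frequencies)
    for i, b in zip(unpaired_positions, draws):
        seq[i] = bases[b]
    for i, j in pairs:
        gc = rng.random() < spec.gc_bias
        pair = ("G", "C") if gc else ("A", "U")
        if rng.random() < 0.5:
            pair = pair[::-1]
        seq[i], seq[j] = pair

    structure = SecondaryStructure(spec.total_length, tuple(pairs))
    return AnnotatedSequence(label, "".join(seq), structure)


@dataclass(frozen=True)
class ModelBundle:
    """The three substitution models used by the study pipeline."""

    nucleotide: RateMatrix  # 4-state, unpaired sites
    doublet: RateMatrix  # 16-state, stem base pairs
    pseudoprotein: RateMatrix  # 12-state, distance estimation


def default_substitution_models(
    stem_bonus: float = 2.0, pair_bias: float = 15.0
) -> ModelBundle:
    """Default 4/16/12-state GTR models.

    * 4-state: uniform exchangeabilities, uniform frequencies (Jukes-Cantor).
    * 16-state: doublet model from the 4-state default; ``stem_bonus``
      multiplies exchangeabilities of pairing-preserving substitutions and
      ``pair_bias`` upweights stationary frequencies of pairable doublets.
      The default ``pair_bias=15`` puts 90% of stationary mass on formable
      pairs, matching the near-complete pairing of real ITS2 stem columns;
      with both knobs at 1 the model reduces to two independent 4-state
      copies.
    * 12-state: uniform-exchangeability GTR over the pseudoprotein states.

    Estimated matrices can replace any of the three via
    :func:`its2sim.models.read_rate_matrix`.
    """
    ones4 = np.ones((4, 4))
    nt = build_gtr_rate_matrix(ones4, np.full(4, 0.25), NT_ALPHABET)
    dbl = doublet_model(nt, stem_bonus=stem_bonus, pair_bias=pair_bias)
    ones12 = np.ones((12, 12))
    ps = build_gtr_rate_matrix(ones12, np.full(12, 1 / 12), PSEUDO_ALPHABET)
    return ModelBundle(nt, dbl, ps)
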