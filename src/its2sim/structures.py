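"""RNA secondary structures, homology modeling, pseudoprotein encoding.

A :class:`SecondaryStructure` is a pseudoknot-free set of base pairs over a
sequence of fixed length, serialized as Vienna dot-bracket.  Structures are
assigned to simulated sequences by *homology modeling*: each base pair of a
template (ancestral) structure is kept iff the target bases can still form a
Watson-Crick or G·U pair, and the percentage of transferred pairs doubles as
the ITS2-likeness acceptance score (threshold 75%, inclusive).

The sequence-structure data combine into a 12-letter *pseudoprotein*
alphabet: each position is its nucleotide together with its structural role
(unpaired, opening half of a pair, closing half).

Positions are 0-based internally and 1-based in human-readable messages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

from .models import NUCLEOTIDES, PAIRABLE, PSEUDO_STATES

#: one FASTA-safe letter per pseudoprotein state, base-major order
#: (A C G U) x (unpaired, opening, closing)
PSEUDO_LETTERS: str = "ABECDFGHIUVW"

_STATE_TO_LETTER = dict(zip(PSEUDO_STATES, PSEUDO_LETTERS))
_LETTER_TO_STATE = {v: k for k, v in _STATE_TO_LETTER.items()}


@dataclass(frozen=True)
class SecondaryStructure:
    """Pseudoknot-free pairing of sequence positions.

    ``pairs`` is a sorted tuple of ``(i, j)`` with ``i < j``; every position
    occurs in at most one pair and pairs are non-crossing.
    """

    length: int
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        pairs = tuple(sorted(tuple(p) for p in self.pairs))
        object.__setattr__(self, "pairs", pairs)
        seen: set[int] = set()
        for i, j in pairs:
            if not (0 <= i < j < self.length):
                raise ValueError(f"pair ({i + 1},{j + 1}) outside sequence of length {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"position {(i if i in seen else j) + 1} paired twice")
            seen.update((i, j))
        for a, (i, j) in enumerate(pairs):
            for k, l in pairs[a + 1 :]:
                if k >= j:
                    break
                if i < k < j < l:
                    raise ValueError(
                        f"crossing pairs ({i + 1},{j + 1}) and ({k + 1},{l + 1})"
                    )

    @cached_property
    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i], d[j] = j, i
        return d

    @cached_property
    def helices(self) -> tuple[tuple[tuple[int, int], ...], ...]:
        """Maximal runs of stacked pairs: (i, j) followed by (i+1, j-1)."""
        runs: list[list[tuple[int, int]]] = []
        for p in self.pairs:
            if runs and (runs[-1][-1][0] + 1, runs[-1][-1][1] - 1) == p:
                runs[-1].append(p)
            else:
                runs.append([p])
        return tuple(tuple(r) for r in runs)

    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i], chars[j] = "(", ")"
        return "".join(chars)

    def __len__(self) -> int:
        return self.length


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse a dot-bracket string; rejects unbalanced brackets.

    Crossing pairs cannot be expressed with a single bracket type, so the
    result is always pseudoknot-free.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(text):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unmatched ')' at position {pos + 1}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise ValueError(f"invalid character {ch!r} at position {pos + 1}")
    if stack:
        raise ValueError(f"unclosed '(' at position {stack[0] + 1}")
    return SecondaryStructure(len(text), tuple(pairs))


@dataclass(frozen=True)
class AnnotatedSequence:
    """A labelled nucleotide sequence with its secondary structure."""

    label: str
    seq: str
    structure: SecondaryStructure

    def __post_init__(self):
        bad = set(self.seq) - set(NUCLEOTIDES)
        if bad:
            raise ValueError(f"{self.label}: invalid nucleotides {sorted(bad)}")
        if len(self.seq) != self.structure.length:
            raise ValueError(
                f"{self.label}: sequence length {len(self.seq)} != structure length "
                f"{self.structure.length}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    """Whether bases ``a``/``b`` can form a pair (WC, optionally G·U)."""
    d = a + b
    if not allow_gu and d in ("GU", "UG"):
        return False
    return d in PAIRABLE


def homology_model(
    template: AnnotatedSequence,
    target_seq: str,
    threshold: float = 75.0,
    allow_gu: bool = True,
    per_helix: bool = False,
) -> tuple[SecondaryStructure, float]:
    """Transfer the template structure onto a target sequence.

    Keeps every template pair whose target bases can still pair and scores
    the transfer as ``100 * kept / total`` over the whole structure (the
    default), or — with ``per_helix`` — as the worst per-helix kept
    fraction, which demands that every individual helix transfers.
    Acceptance means the score is ``>= threshold`` (inclusive); the
    threshold itself is not applied here, only reported via the score.
    """
    if len(target_seq) != len(template):
        raise ValueError(
            f"target length {len(target_seq)} != template length {len(template)}"
        )
    total = len(template.structure.pairs)
    if total == 0:
        raise ValueError("template structure has no pairs; transfer undefined")
    kept = tuple(
        (i, j)
        for i, j in template.structure.pairs
        if can_pair(target_seq[i], target_seq[j], allow_gu=allow_gu)
    )
    if per_helix:
        kept_set = set(kept)
        fractions = [
            sum(p in kept_set for p in helix) / len(helix)
            for helix in template.structure.helices
        ]
        percent = 100.0 * min(fractions)
    else:
        percent = 100.0 * len(kept) / total
    return SecondaryStructure(len(template), kept), percent


def encode_pseudoprotein(s: AnnotatedSequence) -> str:
    """Encode sequence + structure as a 12-letter pseudoprotein string."""
    partner = s.structure.partner
    out = []
    for i, base in enumerate(s.seq):
        j = partner.get(i)
        role = "." if j is None else ("(" if i < j else ")")
        out.append(_STATE_TO_LETTER[base + role])
    return "".join(out)


def decode_pseudoprotein(text: str, label: str = "") -> AnnotatedSequence:
    """Inverse of :func:`encode_pseudoprotein`."""
    seq = []
    brackets = []
    for pos, ch in enumerate(text):
        state = _LETTER_TO_STATE.get(ch)
        if state is None:
            raise ValueError(f"invalid pseudoprotein letter {ch!r} at position {pos + 1}")
        seq.append(state[0])
        brackets.append(state[1])
    structure = parse_dotbracket("".join(brackets))
    return AnnotatedSequence(label, "".join(seq), structure)


def write_fasta(records: list[AnnotatedSequence], path) -> None:
    """Write sequences (without structures) as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(r.seq), id=r.label, description="") for r in records],
        path,
        "fasta",
    )


def read_fasta(path) -> list[tuple[str, str]]:
    """Read (label, RNA sequence) pairs from FASTA; T is converted to U."""
    from Bio.SeqIO import parse as seqio_parse

    return [
        (rec.id, str(rec.seq).upper().replace("T", "U"))
        for rec in seqio_parse(path, "fasta")
    ]


# ---------------------------------------------------------------------------
# Vienna files: '>' header line, sequence line, dot-bracket line


def write_vienna(records: list[AnnotatedSequence], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.label}\n{rec.seq}\n{rec.structure.dot_bracket()}\n")


def read_vienna(path) -> list[AnnotatedSequence]:
    records: list[AnnotatedSequence] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>' header at line {i + 1}")
        if i + 2 >= len(lines):
            raise ValueError(f"{path}: truncated record {lines[i][1:]!r}")
        label, seq, db = lines[i][1:].strip(), lines[i + 1].strip(), lines[i + 2].strip()
        seq = seq.upper().replace("T", "U")
        records.append(AnnotatedSequence(label, seq, parse_dotbracket(db)))
        i += 3
    return records
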