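"""Accuracy and robustness metrics for reconstructed trees.

Accuracy is measured against the reference topology with two distances:
Robinson-Foulds (size of the symmetric difference of the two trees'
nontrivial bipartition sets — the raw, unhalved PHYLIP treedist
convention, maximum ``2(n-3)`` for binary trees) and the quartet distance
(number of 4-leaf subsets on which the two trees induce different unrooted
quartet topologies, maximum ``C(n, 4)``), computed by explicit enumeration
— exact and cheap at the study's n <= 18.  Robustness is the pooled
distribution of bootstrap support values over the internal branches of all
replicate trees of a scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .trees import PhyloTree


def tree_bipartitions(t: PhyloTree) -> set[frozenset[str]]:
    """Canonical nontrivial bipartitions of an unrooted tree.

    A binary tree on n leaves yields exactly ``n - 3``; multifurcating
    trees yield only the bipartitions of their resolved edges (a star tree
    yields none).
    """
    return t.bipartitions()


def _check_leaf_sets(t1: PhyloTree, t2: PhyloTree) -> frozenset[str]:
    s1, s2 = frozenset(t1.leaf_labels()), frozenset(t2.leaf_labels())
    if s1 != s2:
        raise ValueError(
            f"leaf sets differ: only-in-first={sorted(s1 - s2)}, "
            f"only-in-second={sorted(s2 - s1)}"
        )
    return s1


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance (raw symmetric-difference count)."""
    _check_leaf_sets(t1, t2)
    return len(t1.bipartitions() ^ t2.bipartitions())


def _quartet_topologies(t: PhyloTree, labels: list[str]) -> dict:
    """Map each resolved quartet {a,b,c,d} -> its induced split.

    The split is stored as ``(pair1, pair2)`` with canonical ordering.  A
    quartet ab|cd is induced iff some bipartition separates {a, b} from
    {c, d}; for a binary tree every quartet is resolved by at least one
    edge, and all resolving edges agree.
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    full = frozenset(labels)
    out: dict[frozenset, tuple] = {}
    for side in t.bipartitions():
        other = full - side
        for a, b in combinations(sorted(side, key=idx.get), 2):
            for c, d in combinations(sorted(other, key=idx.get), 2):
                quartet = frozenset((a, b, c, d))
                pair1, pair2 = tuple(sorted((a, b))), tuple(sorted((c, d)))
                split = (pair1, pair2) if pair1 < pair2 else (pair2, pair1)
                out.setdefault(quartet, split)
    return out


def quartet_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Number of 4-leaf subsets with different induced quartet topologies.

    Exhaustive over all C(n, 4) subsets; quartets unresolved in exactly one
    tree count as different.
    """
    labels = sorted(_check_leaf_sets(t1, t2))
    if len(labels) < 4:
        raise ValueError("quartet distance needs at least 4 leaves")
    q1 = _quartet_topologies(t1, labels)
    q2 = _quartet_topologies(t2, labels)
    diff = 0
    for quartet in {frozenset(q) for q in combinations(labels, 4)}:
        if q1.get(quartet) != q2.get(quartet):
            diff += 1
    return diff


def max_rf(n_taxa: int) -> int:
    return 2 * (n_taxa - 3)


def max_quartets(n_taxa: int) -> int:
    return comb(n_taxa, 4)


# ---------------------------------------------------------------------------
# scenario summaries


@dataclass
class ReplicateResult:
    """Metrics of one reconstructed replicate of one data-set kind."""

    kind: str  # sequence | structure | doubled
    supports: np.ndarray  # bootstrap values of the replicate tree's branches
    rf: int
    quartet: int


@dataclass
class ScenarioSummary:
    """Pooled per-scenario distributions and summary statistics."""

    scenario_id: str
    n_taxa: int
    branch_length: float
    tree_class: str
    kinds: dict[str, dict] = field(default_factory=dict)

    def table_rows(self) -> list[dict]:
        rows = []
        for kind, stats in self.kinds.items():
            row = {
                "scenario": self.scenario_id,
                "n_taxa": self.n_taxa,
                "branch_length": self.branch_length,
                "tree_class": self.tree_class,
                "kind": kind,
            }
            row.update(
                {k: v for k, v in stats.items() if not isinstance(v, np.ndarray)}
            )
            rows.append(row)
        return rows


def _dist_stats(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"mean": float(np.mean(x)), "median": float(med), "q1": float(q1), "q3": float(q3)}


def summarize_scenario(
    results: list[ReplicateResult],
    scenario_id: str,
    n_taxa: int,
    branch_length: float,
    tree_class: str = "equidistant",
) -> ScenarioSummary:
    """Pool replicate results of a scenario per data-set kind.

    Bootstrap values of all internal branches of all replicate trees are
    pooled into one distribution (``n_replicates * (n_taxa - 3)`` values
    for binary trees); RF and quartet distances are pooled and reported in
    absolute and normalized (per-split, per-quartet) form.
    """
    if not results:
        raise ValueError("no replicate results to summarize")
    summary = ScenarioSummary(scenario_id, n_taxa, branch_length, tree_class)
    for kind in sorted({r.kind for r in results}):
        rs = [r for r in results if r.kind == kind]
        pooled = np.concatenate([np.asarray(r.supports, dtype=float) for r in rs])
        rf = np.array([r.rf for r in rs], dtype=float)
        qd = np.array([r.quartet for r in rs], dtype=float)
        stats = {
            "n_replicates": len(rs),
            "pooled_support": pooled,
            "pooled_rf": rf,
            "pooled_quartet": qd,
            "n_pooled_support": int(pooled.size),
        }
        for name, arr in (("support", pooled), ("rf", rf), ("quartet", qd)):
            for stat, v in _dist_stats(arr).items():
                stats[f"{name}_{stat}"] = v
        stats["rf_normalized_mean"] = float(np.mean(rf / max_rf(n_taxa)))
        stats["quartet_normalized_mean"] = float(np.mean(qd / max_quartets(n_taxa)))
        summary.kinds[kind] = stats
    return summary
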