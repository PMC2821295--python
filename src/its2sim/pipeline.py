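"""End-to-end scenario grid: simulate, reconstruct, evaluate, summarize.

The full study design crosses 10 branch lengths x 5 ancestors x 6
reference trees (3 taxa counts, equidistant and variable branch lengths)
into 300 scenarios with 2,000 accepted sequence sets each (600,000 sets).
That scale is a cluster job; the default :class:`ExperimentPlan` keeps the
same design at desk scale (200 accepted sets, 100 replicates per data-set
kind) and every axis is one config edit away from full scale.

Within a scenario the paired design of the study is preserved: the
accepted sets are shuffled, the first half becomes the *sequence* data set
and — with homology-modeled individual structures — the *sequence-structure*
data set; the second half is concatenated taxon-wise with the first to
form the *doubled* data set.  Each replicate of each kind is reconstructed
(NJ by default), bootstrapped with 100 pseudo-replicates, and compared to
the reference tree.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import ReplicateResult, ScenarioSummary, quartet_distance, rf_distance, summarize_scenario
from .reconstruct import (
    CharacterAlignment,
    bootstrap_support,
    build_doubled_set,
    build_structure_set,
    profile_neighbor_joining,
)
from .simulator import (
    BRANCH_LENGTH_GRID,
    ScenarioConfig,
    generate_reference_tree,
    simulate_accepted_sets,
)
from .synthetic_data import AncestorSpec, ModelBundle, default_substitution_models, generate_ancestor

KINDS = ("sequence", "structure", "doubled")


def _default_ancestors() -> tuple[AncestorSpec, ...]:
    # five ancestors standing in for the five eukaryote lineages; identical
    # layout, independent seeds
    return tuple(AncestorSpec(seed=s) for s in range(1, 6))


@dataclass(frozen=True)
class ExperimentPlan:
    """The experiment grid and its per-scenario effort."""

    branch_lengths: tuple[float, ...] = BRANCH_LENGTH_GRID
    ancestors: tuple[AncestorSpec, ...] = field(default_factory=_default_ancestors)
    taxa_counts: tuple[int, ...] = (10, 14, 18)
    tree_classes: tuple[str, ...] = ("equidistant", "variable")
    topology_shape: str = "balanced"
    n_sets: int = 200  # accepted sets per scenario (full study: 2,000)
    replicates: int = 100  # replicates used per data-set kind (full study: 1,000)
    bootstraps: int = 100
    master_seed: int = 0

    def __post_init__(self):
        for name in ("branch_lengths", "ancestors", "taxa_counts", "tree_classes"):
            if not getattr(self, name):
                raise ValueError(f"empty plan axis: {name}")
        if self.n_sets < 2 * self.replicates:
            raise ValueError(
                "n_sets must be >= 2 * replicates (sequence + doubled halves)"
            )

    @property
    def n_scenarios(self) -> int:
        return (
            len(self.branch_lengths)
            * len(self.ancestors)
            * len(self.taxa_counts)
            * len(self.tree_classes)
        )

    @property
    def total_sets(self) -> int:
        return self.n_scenarios * self.n_sets

    @classmethod
    def full_scale(cls, master_seed: int = 0) -> "ExperimentPlan":
        return cls(n_sets=2000, replicates=1000, master_seed=master_seed)


def _scenario_seed(master_seed: int, index: int) -> int:
    return int(
        np.random.SeedSequence(master_seed, spawn_key=(index,)).generate_state(1)[0]
        % (2**31)
    )


def scenario_grid(plan: ExperimentPlan) -> list[ScenarioConfig]:
    """Full cross product, deterministic order, derived per-scenario seeds.

    Order: branch length (outer) x ancestor x taxa count x tree class.
    """
    cfgs = []
    index = 0
    for bl in plan.branch_lengths:
        for anc in plan.ancestors:
            for n_taxa in plan.taxa_counts:
                for tree_class in plan.tree_classes:
                    cfgs.append(
                        ScenarioConfig(
                            branch_length=bl,
                            n_taxa=n_taxa,
                            tree_class=tree_class,
                            topology_shape=plan.topology_shape,
                            ancestor=anc,
                            n_sets=plan.n_sets,
                            seed=_scenario_seed(plan.master_seed, index),
                        )
                    )
                    index += 1
    return cfgs


def scenario_id(cfg: ScenarioConfig) -> str:
    return (
        f"bl{cfg.branch_length:g}_n{cfg.n_taxa}_{cfg.tree_class}"
        f"_{cfg.topology_shape}_anc{cfg.ancestor.seed}"
    )


def run_scenario(
    cfg: ScenarioConfig,
    replicates: int = 100,
    bootstraps: int = 100,
    kinds: tuple[str, ...] = KINDS,
    models: ModelBundle | None = None,
    estimator: str = "model",
    engine: str = "nj",
) -> ScenarioSummary:
    """Simulate one scenario and evaluate all requested data-set kinds.

    ``estimator`` selects the distance correction: ``"model"`` (default)
    estimates ML branch lengths under the bundle's 4-state (sequence,
    doubled) or 12-state (sequence-structure) rate matrix — distances under
    *given* substitution matrices; ``"logdet"`` uses the matrix-free
    logdet-style GTR estimator instead.
    """
    if estimator not in ("model", "logdet"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if engine not in ("nj", "pnj"):
        raise ValueError(f"unknown engine {engine!r}")
    sid = scenario_id(cfg)
    if cfg.n_sets < 2 * replicates and "doubled" in kinds:
        raise ValueError(f"{sid}: need n_sets >= 2*replicates for the doubled set")
    try:
        reference = generate_reference_tree(
            cfg.n_taxa, cfg.branch_length, cfg.tree_class, cfg.topology_shape
        )
        ancestor = generate_ancestor(cfg.ancestor)
        if models is None:
            models = cfg.get_models()
        cfg = dataclasses.replace(cfg, models=models)
        sets, log = simulate_accepted_sets(cfg, tree=reference, ancestor=ancestor)

        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(10**6,)))
        order = rng.permutation(len(sets))
        first = [sets[i] for i in order[:replicates]]
        second = [sets[i] for i in order[replicates : 2 * replicates]]

        results: list[ReplicateResult] = []
        degenerate = False
        for r in range(replicates):
            boot_seed = np.random.SeedSequence(cfg.seed, spawn_key=(10**6 + 1, r))
            alns = {}
            if "sequence" in kinds:
                alns["sequence"] = CharacterAlignment.from_sequences(first[r])
            if "structure" in kinds:
                alns["structure"] = CharacterAlignment.from_pseudoproteins(
                    build_structure_set(first[r], ancestor)
                )
            if "doubled" in kinds:
                alns["doubled"] = build_doubled_set(first[r], second[r])
            for kind, aln in alns.items():
                if np.all(aln.data == aln.data[0]):
                    degenerate = True  # zero signal: all rows identical
                dist_model = None
                if estimator == "model":
                    dist_model = (
                        models.pseudoprotein if kind == "structure" else models.nucleotide
                    )
                if engine == "nj":
                    tree, supports = bootstrap_support(
                        aln, n_replicates=bootstraps, seed=boot_seed, model=dist_model
                    )
                else:
                    tree = profile_neighbor_joining(
                        aln, n_replicates=bootstraps, seed=boot_seed
                    )
                    _, _, reps = bootstrap_support(
                        aln,
                        n_replicates=bootstraps,
                        seed=boot_seed,
                        model=dist_model,
                        return_replicates=True,
                    )
                    supports = {
                        bp: 100.0 * sum(bp in r for r in reps) / len(reps)
                        for bp in tree.bipartitions()
                    }
                results.append(
                    ReplicateResult(
                        kind=kind,
                        supports=np.array(list(supports.values())),
                        rf=rf_distance(tree, reference),
                        quartet=quartet_distance(tree, reference),
                    )
                )
        summary = summarize_scenario(
            results, sid, cfg.n_taxa, cfg.branch_length, cfg.tree_class
        )
        for stats in summary.kinds.values():
            stats["acceptance_rate"] = log.acceptance_rate
            stats["degenerate"] = degenerate
        return summary
    except Exception as exc:
        raise RuntimeError(f"scenario {sid} failed: {exc}") from exc


def run_experiment(
    plan: ExperimentPlan,
    out_dir=None,
    kinds: tuple[str, ...] = KINDS,
    progress: bool = False,
):
    """Execute every scenario of a plan; failures are recorded, not fatal.

    Returns ``(results_table, manifest)``: a tidy DataFrame with one row
    per scenario x kind, and a manifest of the plan, seeds and failures.
    Results are independent of execution order because every scenario
    derives its own random streams from its recorded seed.
    """
    cfgs = scenario_grid(plan)
    rows: list[dict] = []
    failures: list[dict] = []
    t0 = time.time()
    for i, cfg in enumerate(cfgs):
        if progress:
            print(f"[{i + 1}/{len(cfgs)}] {scenario_id(cfg)}", flush=True)
        try:
            summary = run_scenario(
                cfg, replicates=plan.replicates, bootstraps=plan.bootstraps, kinds=kinds
            )
            rows.extend(summary.table_rows())
        except Exception as exc:  # partial-failure handling
            failures.append({"scenario": scenario_id(cfg), "error": str(exc)})
    table = pd.DataFrame(rows)
    manifest = {
        "plan": {
            "branch_lengths": list(plan.branch_lengths),
            "n_ancestors": len(plan.ancestors),
            "ancestor_seeds": [a.seed for a in plan.ancestors],
            "taxa_counts": list(plan.taxa_counts),
            "tree_classes": list(plan.tree_classes),
            "topology_shape": plan.topology_shape,
            "n_sets": plan.n_sets,
            "replicates": plan.replicates,
            "bootstraps": plan.bootstraps,
            "master_seed": plan.master_seed,
        },
        "n_scenarios": plan.n_scenarios,
        "total_sets": plan.total_sets,
        "scenario_seeds": {scenario_id(c): c.seed for c in cfgs},
        "failures": failures,
        "runtime_seconds": time.time() - t0,
    }
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "results.csv"), index=False)
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        if len(table):
            for metric in ("support_median", "quartet_median", "rf_median"):
                try:
                    plot_summary(table, metric, os.path.join(out_dir, f"summary_{metric}.png"))
                except Exception:
                    pass
    return table, manifest


def branch_length_support_sweep(
    branch_lengths: tuple[float, ...] = BRANCH_LENGTH_GRID,
    n_taxa: int = 14,
    tree_class: str = "equidistant",
    replicates: int = 50,
    bootstraps: int = 100,
    seed: int = 0,
    kind: str = "sequence",
) -> dict[float, float]:
    """Mean pooled bootstrap support per branch length for one data kind.

    Runs one scenario per grid value (same ancestor, seeds derived from
    ``seed``) and pools supports over all replicate trees — the curve whose
    maximum locates the optimal divergence for reconstruction.
    """
    out: dict[float, float] = {}
    for i, bl in enumerate(branch_lengths):
        cfg = ScenarioConfig(
            branch_length=bl,
            n_taxa=n_taxa,
            tree_class=tree_class,
            ancestor=AncestorSpec(seed=1),
            n_sets=replicates if kind != "doubled" else 2 * replicates,
            seed=_scenario_seed(seed, i),
        )
        summary = run_scenario(
            cfg, replicates=replicates, bootstraps=bootstraps, kinds=(kind,)
        )
        out[bl] = summary.kinds[kind]["support_mean"]
    return out


def plot_summary(table: pd.DataFrame, metric: str, out_path) -> None:
    """Median (with quartile ribbons where available) vs branch length,
    one curve per data-set kind."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    base = metric.rsplit("_", 1)[0]
    for kind, sub in table.groupby("kind"):
        agg = sub.groupby("branch_length")[metric].median()
        ax.plot(agg.index, agg.values, marker="o", label=kind)
        lo, hi = f"{base}_q1", f"{base}_q3"
        if lo in sub.columns and hi in sub.columns:
            alo = sub.groupby("branch_length")[lo].median()
            ahi = sub.groupby("branch_length")[hi].median()
            ax.fill_between(agg.index, alo.values, ahi.values, alpha=0.2)
    ax.set_xlabel("branch length (subs/site)")
    ax.set_ylabel(metric)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
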