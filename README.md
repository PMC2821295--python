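# its2sim

Does a marker's own RNA secondary structure help phylogenetic
reconstruction — and is that help the same thing as simply sequencing a
longer marker? `its2sim` answers this for ITS2-like spacers (fast-evolving
~250-nt sequences with a conserved four-helix fold, the third helix
longest) by simulation: it evolves annotated sequences along known
reference trees, reconstructs those trees from three kinds of data, and
measures robustness and accuracy against the truth. It is aimed at
molecular phylogeneticists who want a controlled, reproducible testbed for
structure-aware distance methods.

## The model

Unpaired (loop) sites evolve under a 4-state GTR model
(`Q[i,j] = s[i,j] pi[j]`, detailed balance `pi_i Q_ij = pi_j Q_ji`, mean
rate 1 substitution/site). Each stem base pair evolves *jointly* as one
16-state doublet under a second GTR model whose exchangeabilities favor
pairing-preserving (compensatory) substitutions and whose stationary
frequencies concentrate on formable WC/G·U pairs — so stems stay stems, as
in real ITS2. Branch lengths are substitutions per site everywhere (the
doublet matrix has mean rate 2 per doublet).

Simulated sets are accepted as ITS2-like only if every sequence's
structure is recoverable from the ancestral template by homology modeling
(>= 75% of template pairs still formable). Each accepted replicate yields
three data sets:

* **sequence** — the plain nucleotides (250 columns, 4 states);
* **sequence-structure** — the same nucleotides fused with their
  individually modeled structures into a 12-letter *pseudoprotein*
  alphabet (base x unpaired/opening/closing);
* **doubled** — the nucleotides concatenated with an independent
  replicate's nucleotides (500 columns): marker elongation without
  structure.

Pairwise distances are ML branch lengths under the corresponding 4x4 or
12x12 rate matrix (a matrix-free logdet-style GTR estimator
`d = -tr(Pi log(Pi^-1 F))` is also provided); trees come from Neighbor
Joining (a simplified Profile NJ is included); robustness is bootstrap
support over 100 column resamples, accuracy is Robinson-Foulds and quartet
distance to the reference tree. See `docs/methods.md` for the full model
description and design rationale.

## Worked example

```python
import its2sim as it
from its2sim.pipeline import run_scenario

cfg = it.ScenarioConfig(branch_length=0.35, n_taxa=14, n_sets=40, seed=7)
s = run_scenario(cfg, replicates=20, bootstraps=100)
for kind in ("sequence", "structure", "doubled"):
    st = s.kinds[kind]
    print(f"{kind:10} mean support {st['support_mean']:5.1f}   "
          f"mean quartet distance {st['quartet_mean']:6.1f} / 1001   "
          f"mean RF {st['rf_mean']:5.2f} / 22")
```

prints

```
sequence   mean support  86.9   mean quartet distance   26.4 / 1001   mean RF  0.50 / 22
structure  mean support  93.6   mean quartet distance   21.6 / 1001   mean RF  0.40 / 22
doubled    mean support  97.4   mean quartet distance    0.0 / 1001   mean RF  0.00 / 22
```

Reading this: at branch length 0.35 on a 14-taxon equidistant tree,
adding each sequence's own structure raises mean bootstrap support from
86.9 to 93.6 and removes about a fifth of the quartet errors at identical
sequence content, while doubling the marker length is worth more still on
both axes (with a known true alignment, 500 independent columns are hard
to beat — see the methods note on what this does and does not say about
realigned biological data).

A command-line interface mirrors the library:

```sh
its2sim ancestor --seed 1 --out anc.vienna
its2sim simulate --branch-length 0.3 --taxa 14 --sets 10 --out-dir sim/
its2sim reconstruct --vienna sim/set0000.vienna --mode structure --out tree.nwk
its2sim evaluate tree.nwk sim/reference.nwk
its2sim experiment --out results/ --branch-lengths 0.1,0.3 --ancestors 1 --taxa 14
```

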