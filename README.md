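# cflfit

Train constrained-fuzzy-logic models of protein signal-transduction pathways
against single-time-point perturbation data.

## What it does

Cells process extracellular cues (growth factors, cytokines) through networks
of protein kinases. A qualitative wiring diagram of such a network — the
prior knowledge network — is usually available, but it describes the
*possible* interactions, not the ones actually operating in a given cell
type. `cflfit` bridges that gap: it simulates the wiring diagram as a logic
model with continuous activation levels and fits per-interaction parameters
to measured phosphoprotein responses, so that interactions the data do not
support are switched off and the surviving model is quantitatively
predictive.

The model is **constrained fuzzy logic**: every species carries an
activation in [0, 1], and each reaction transmits signal through a
normalized Hill transfer function

```
f(x) = a · H(x) / H(1),    H(x) = x^n / (p^n + x^n)
```

with gain `a ∈ [0, 1]` (a ≈ 0 means the reaction is effectively absent),
midpoint `p`, and a fixed integer steepness `n = 4`. Two-input reactions act
as AND gates (bilinear product of the inputs, inhibitory inputs entering as
their complement `1 − x`); several reactions producing the same species are
OR-combined by the probabilistic sum. At the Boolean corners {0, 1} the
model reproduces classical Boolean logic exactly, while staying
differentiable in between — which is what makes gradient-based training
possible.

The package provides:

- **I/O** — prior knowledge networks in a 3-column SIF dialect (with
  `and<N>` helper nodes encoding AND gates) and datasets in a MIDAS-dialect
  CSV (`TR:` treatment, `DA:` time, `DV:` measured-value columns).
- **Simulation** — pseudo-steady-state network evaluation: one topological
  pass for acyclic networks, synchronous fixed-point iteration for cyclic
  ones.
- **Fitting** — bounded nonlinear optimization of all `(a, p)` pairs
  (reduced-space formulation, L-BFGS-B backend, smoothed-absolute-value
  mismatch), with multistart families to assess local-optimum spread.
- **Network reduction** — equivalent-class compartmentalization (species the
  experiments cannot distinguish are merged before fitting) and iterative
  pruning (the lowest-activity reaction is removed and the model refit until
  the fit degrades).
- **Evaluation** — hold-out cross-validation over random exclusion
  fractions, and multistart family statistics.
- **Synthetic data** — a ten-reaction toy model with a known ground truth,
  random acyclic logic networks, and noisy dataset generation.

## Worked example

Generate the bundled toy study — a 10-species, 10-reaction network (20 free
parameters) probed by 9 treatment combinations of 2 stimuli and 2 kinase
inhibitors, with 5 phosphoproteins measured (45 data cells). The
data-generating truth switches three reactions off (`a = 0`):

```bash
cflfit toy --out data
# wrote data/toy_model.sif and data/toy_data.csv

echo "p_bounds: [0.3, 0.7]" > toycfg.yaml
cflfit fit --sif data/toy_model.sif --midas data/toy_data.csv \
       --runs 5 --seed 0 --config toycfg.yaml --out fitted
# mean fitness error: 13.3% -> 0.0% (5 run(s))
```

The fitted gains recover the planted truth exactly — reactions 1, 3 and 9
(the three disabled ones) end at `a = 0`, all others at `a = 1`:

```
$ head -6 fitted/solution.csv
reaction,a,p,max_activity
0,1.0,0.6263414216486128,1.0
1,0.0,0.562296115266148,0.0
2,1.0,0.6429617106350277,1.0
3,0.0,0.3257997094620807,0.0
4,1.0,0.3,1.0
```

Pruning removes exactly those three reactions and stops at the first vital
one (removing reaction 0 would push the error from 0% to 6.7%):

```bash
cflfit reduce --sif data/toy_model.sif --midas data/toy_data.csv \
       --mode prune --config toycfg.yaml --seed 0 --out pruned
# removed 3 reactions (baseline MAE 0.0%)

$ cat pruned/prune_trace.csv
step,reaction,max_activity,mae
1,1,0.0,0.0
2,3,0.0,0.0
3,9,0.0,0.0
4,0,1.0,0.06666666666666667
```

Cross-validation on the same data (seed 0, 5 replicates) shows the expected
shape: the total fit error rises from 0% toward the 31.1% null-solution
ceiling as larger random portions of the data are excluded from training —
total MAE 0.0%, 0.0%, 2.2%, 12.2%, 13.2%, 16.9% at exclusion fractions
0, 0.2, 0.4, 0.6, 0.8, 0.95:

```bash
cflfit crossval --sif data/toy_model.sif --midas data/toy_data.csv \
       --config toycfg.yaml --seed 0 --out cv
```

Every command writes a `manifest.json` with input hashes, the seed, and
wall time, so runs are fully reproducible.

## Library use

```python
import cflfit as cf

truth = cf.make_toy_ground_truth()          # pathway + design + dataset
family = cf.multistart(truth.pathway, truth.design, truth.measurements,
                       cf.FitConfig.toy(), n_runs=50, seed=0)
best = family.best                          # best.mae == 0.0
reduced, cmap = cf.compartmentalize(truth.pathway, truth.design)
```

See `docs/methods.md` for the model definition, parameter conventions, and
numerical choices.
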