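# nanoscape

Potential-landscape modelling of single-cell reporter dynamics.

`nanoscape` implements a one-dimensional stochastic model of how a population
of cells moves between expression states, developed around Nanog-GFP
distributions in mouse embryonic stem (ES) cells measured by flow cytometry
(FACS). A culture is described by a stochastic dynamical system

    dX = A(X) dt + sqrt(2B) dW

on the log10 fluorescence scale, where the drift `A(x)` is the negative
gradient of a potential `U(x)` and `B` is a constant noise intensity. Instead
of modelling regulatory mechanisms, the stationary distribution `p_s(x)` is
parameterized directly as a k-component Gaussian mixture; zero probability
current at stationarity then fixes the potential and drift analytically:

    U(x) = -B log p_s(x),        A(x) = -U'(x) = B (log p_s)'(x).

Local minima of `U` are attractor states (for Nanog: the low/middle/high
expression bands LN, MN and HN spanning decades 0–1, 1–2 and 2–3). The mixture
weights are state occupancies, component variances measure valley widths, and
`B` sets how fast cells hop between states. The mixture shape and `B` are not
jointly identifiable from a single stationary snapshot — scaling `B` rescales
`U` but leaves `p_s` untouched — so `B` is inferred from snapshot *time
courses*: a sorted narrow fraction of cells is re-cultured, and the
distribution of fresh destructively-sampled aliquots is measured daily while
the population relaxes back to the stationary law.

The likelihood of a time course is simulation-based: a kernel density estimate
(KDE) of the day-0 sample seeds an Euler–Maruyama trajectory ensemble; each
later day's observed cells are scored under a KDE of the simulated ensemble at
that day, and the per-day log likelihoods add (aliquots are independent).
Posteriors and model evidences come from a built-in nested sampler, so
component counts can be compared by Bayes factors and conditions compared by
posterior contrasts `P(theta_A < theta_B)`.

## Worked example

Four published reference condition models (LIF+BMP4, PD03, Chiron, 2i) ship
with the package. Evaluate the 2i landscape and simulate a sorting
experiment:

```python
import numpy as np
import nanoscape as ns

model = ns.reference_model("2i")
x = np.array([0.5, 1.5, 2.32])
print("p_s:", np.round(ns.mixture_density(model.mixture, x), 4))
print("U:  ", np.round(ns.potential(model, x), 4))
print("A:  ", np.round(ns.drift(model, x), 4))
```

```
p_s: [0.0403 0.272  0.6128]
U:   [0.9732 0.3945 0.1484]
A:   [ 0.4733  0.5808 -0.0067]
```

The potential is lowest near the dominant high-Nanog component (x = 2.32,
where the drift vanishes). Simulating a sorted middle-band fraction relaxing
over three days:

```python
init = ns.InitialSpec("sorted_fraction", center=1.8, width=0.15)
data = ns.generate_timecourse(model, init, [0, 1, 2, 3], 500, seed=42,
                              condition="2i")
for t, s in zip(data.times, data.samples):
    _, occ = ns.gate_classify(s)
    print(f"day {t:.0f}: mean={s.mean():.3f}  LN/MN/HN = "
          f"{occ['LN']:.2f}/{occ['MN']:.2f}/{occ['HN']:.2f}")
```

```
day 0: mean=1.795  LN/MN/HN = 0.00/0.94/0.06
day 1: mean=2.048  LN/MN/HN = 0.04/0.42/0.54
day 2: mean=2.162  LN/MN/HN = 0.05/0.37/0.58
day 3: mean=2.230  LN/MN/HN = 0.04/0.36/0.60
```

The sorted MN population drains into the HN attractor, as expected under 2i.

Fitting a stationary snapshot with the scikit-learn style estimator (the
dynamic analogue is `PotentialLandscape`, with `fit(X, t)` taking per-cell
measurement days):

```python
mix = ns.MixtureParams([0.5, 0.5], [0.8, 2.2], [0.04, 0.04])
values = ns.sample_stationary(mix, 400, seed=31)
est = ns.StationaryMixture(k=2, n_live=100, walk_steps=15, random_state=8)
est.fit(values)
print(np.round(est.means_, 3), np.round(est.weights_, 3))
print(f"log evidence {est.log_evidence_:.1f} +- {est.log_evidence_err_:.2f}")
```

```
[0.811 2.207] [0.506 0.494]
log evidence -257.5 +- 0.39
```

## Command line

Every step is also a CLI command; each writes plain CSV/JSON outputs plus a
`<command>.config.yaml` recording the exact configuration for reproduction.

```bash
nanoscape simulate --model model.json --days 0,1,2,3 --n-per-day 500 \
    --seed 1 --out runs/sim
nanoscape fit --data runs/sim/timecourse.csv --k 3 --out runs/fit
nanoscape compare-models --data stationary.csv --k 2,3,4 --out runs/bf
nanoscape compare-conditions --post-a runs/fitA/posterior \
    --post-b runs/fitB/posterior --out runs/cmp
nanoscape predict-stationary --post runs/fit/posterior \
    --data heldout.csv --out runs/pred
nanoscape landscape --model model.json --out runs/land
```

Raw events can be read from FCS 3.0/3.1 list-mode files or CSV with
`nanoscape.read_events`, log-transformed with `to_log10`, and gated with
`gate_classify`.

## Tests

```bash
python -m pytest -q tests/
```

The suite checks the library against independent oracles (term-by-term
mixture sums, Ornstein–Uhlenbeck closed forms, a Crank–Nicolson grid solver
of the density evolution equation) and runs an acceptance layer covering
parameter recovery, model-count selection, noise identifiability, evidence
calibration and cross-condition discrimination on synthetic data. The full
run takes roughly 20 minutes on one CPU; everything is seeded and
deterministic. Three acceptance tests encode standards stricter than this
kind of data can support — full 25% parameter recovery from snapshot time
courses, strong Bayes-factor rejection of an unnecessary fourth component,
and cross-condition discrimination between near-identical stationary laws —
and are expected to fail; see `docs/methods.md` (Limitations) for the
analysis.

## Reproduction

`scripts/acceptance.py` recomputes the headline quantities end to end from a
single seed and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The report includes per-condition noise recovery errors and credible-interval
coverage, the 4×4 cross-condition scoring diagonal fraction, Bayes factors
for the component-count comparison, nested-sampling evidence calibration on a
conjugate toy problem, dynamic noise identifiability, and a long-run
stationarity check. All seeds are derived deterministically from `--seed`.

## Layout

- `src/nanoscape/mixture.py` — mixture parameters, density, potential, drift
- `src/nanoscape/sde.py`, `kde.py` — Euler–Maruyama ensembles, Gaussian KDE
- `src/nanoscape/likelihood.py` — snapshot time-course likelihood
- `src/nanoscape/nested.py`, `inference.py` — nested sampling, fits, Bayes factors
- `src/nanoscape/flow.py` — FCS/CSV event reading, log transform, gating
- `src/nanoscape/synthetic.py`, `reference.py` — synthetic data, reference models
- `src/nanoscape/estimators.py` — scikit-learn style wrappers
- `src/nanoscape/cli.py` — the `nanoscape` command
- `docs/methods.md` — methods note (model, numerics, assumptions, limitations)
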