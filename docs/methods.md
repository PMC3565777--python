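# Methods note

## Model

Cell state is summarized by one coordinate `x`, the log10 reporter
fluorescence of a single cell, on the calibrated range of decades 0–3.
Population dynamics follow the Itô stochastic differential equation

    dX_t = A(X_t) dt + sqrt(2B) dW_t,

with constant noise intensity `B > 0`. The corresponding density evolution
(Fokker–Planck) equation is `dp/dt = -(A p)' + B p''`, i.e. the diffusion
coefficient is `2B`. Rather than specifying `A` mechanistically, the
stationary density is parameterized directly as a Gaussian mixture

    p_s(x) = sum_i alpha_i N(x; mu_i, sigma_i^2),   sum_i alpha_i = 1,

and the zero-current stationarity condition determines the landscape:

    U(x) = -B log p_s(x),     A(x) = -U'(x) = B * d/dx log p_s(x).

The drift is evaluated analytically as a responsibility-weighted sum of
Gaussian scores computed in log space (no finite differences), which is exact
and stable far into the tails. Scaling `B -> cB` with the mixture held fixed
leaves `p_s` unchanged and scales `U` by `c` exactly: the noise is not
identifiable from stationary data alone, only from dynamics.

## Parameters, units and defaults

| parameter | meaning | units | default prior |
|---|---|---|---|
| `alpha_1..k` | component occupancies | fraction | symmetric Dirichlet(1) via stick-breaking |
| `mu_1..k` | component means | log10 fluorescence decades | sorted uniforms on (-0.5, 3.5) |
| `sigma_1..k` | component s.d. (variance `sigma^2` is reported) | decades | log-uniform on (0.05, 1.5) |
| `B` | noise intensity | decades^2 per day | log-uniform on (0.01, 3) |

Time is measured in days. Sorting the means collapses the k! label
permutations. Stationary (snapshot-only) fits drop `B` from the parameter
vector. The derived quantity `sigma^2 / B` (valley width in units of noise)
is reported in the CLI parameter table.

## Likelihood for snapshot time courses

Daily samples are destructive (separate aliquots), so days are independent
given the model. For observed samples `x_0, x_1, ..., x_R` at days
`t_0 = 0 < t_1 < ... < t_R`:

1. fit a Gaussian KDE to the day-0 sample (Silverman bandwidth
   `0.9 min(sd, IQR/1.34) n^(-1/5)`);
2. draw `n_traj` initial states by smoothed bootstrap from that KDE;
3. run one Euler–Maruyama ensemble, recording the state at each `t_r`;
4. for each `r >= 1`, fit a KDE to the simulated ensemble at `t_r` and sum
   the log densities of the observed `x_{i,r}`;
5. return the sum over days.

The likelihood is frozen under a fixed seed (common random numbers), so
nested sampling sees a smooth deterministic surface; the Monte-Carlo error of
the surface shrinks as `n_traj` grows. A log-density floor of -700 guards
against observed points outside the simulated support.

## Nested sampling

A classic static nested sampler: `n_live` points in the unit hypercube,
worst-point replacement by a Metropolis random walk under the hard likelihood
threshold (with reflection at the cube boundary and an adaptive step scale),
deterministic shrinkage `X_i = exp(-i / n_live)`, termination when the
maximum remaining contribution falls below 1e-3 of the accumulated evidence,
live points folded in at equal volume. The evidence uncertainty is the
standard information estimate `sqrt(H / n_live)`. Runs are deterministic for
a fixed seed. Bayes factors are evidence ratios; magnitudes 1–3 are labelled
marginal, 3–10 substantial, above 10 strong. Cross-condition contrasts
`P(theta_A < theta_B)` are computed by pairing equal-weight posterior
resamples, ties counting one half.

## Numerical choices

- **SDE integration**: Euler–Maruyama with user-set `dt` (defaults: 0.01 for
  data generation, 0.02 for fitting); record times are snapped to multiples
  of `dt`; Gaussian increments come from a counter-based Philox generator so
  ensembles are reproducible and segment-blocked for memory.
- **KDE evaluation**: exact pairwise summation when `m*n <= 40,000`
  query-sample products, otherwise linear binning on a grid of spacing
  `h/32` with kernel halfwidth `8h` and FFT convolution; the binned path
  matches the exact path to ~1e-4 mean absolute log error.
- **Hot loops** (mixture log densities, Euler–Maruyama steps, KDE sums) are
  numba-compiled with preallocated buffers.
- **Gates**: LN `[0,1)`, MN `[1,2)`, HN `[2,3]` on the log10 scale; values
  outside the calibrated decades are labelled `out` and excluded from
  occupancy fractions. Non-positive raw intensities are dropped (with a
  logged count) before the log transform.

## Synthetic data generator

`generate_timecourse` emulates the sorting experiment: day 0 is either the
full stationary mixture or a sorted middle-band fraction, modelled as a
truncated normal (center 1.8, width 0.15, cut at ±2 widths) or, optionally, a
hard gate on stationary draws. Every later day is an independent ensemble
started from fresh day-0 draws (destructive sampling), keeping endpoints
only. Generating parameters ride along in dataset metadata and a
`.truth.json` sidecar so recovery studies are self-describing. The defaults
are the study conditions used by the tests and the acceptance script.

## Test oracles

The suite validates the library against independently coded references:
term-by-term mixture sums and analytic tail masses; Ornstein–Uhlenbeck closed
forms for the k=1 model (moment relaxation and the exact propagated-KDE
day-t density); a Crank–Nicolson finite-difference solution of the density
evolution equation (validated itself against the OU closed form); and
finite-difference checks that the drift is the negative potential gradient.

## Limitations

- The model is one-dimensional with constant, state-independent noise;
  multimodality in other markers or intensity-dependent measurement noise is
  out of scope.
- The simulation-based likelihood inherits KDE smoothing bias and
  Euler–Maruyama discretization bias; both shrink with larger `n_traj`,
  larger samples and smaller `dt`, but the likelihood is not exact.
- From a few snapshot days starting at a narrow sorted fraction, the full
  10-parameter k=3 dynamic model is only weakly identified: the noise `B` is
  recovered far better than the mixture shape, and posterior credible
  intervals on occupancies and variances are wide. Recovery standards that
  require every parameter within 25% of truth, or reliable cross-condition
  discrimination between conditions with similar stationary laws, are not
  attainable at this data size; the acceptance tests encoding them fail, by
  design, and document this limit.
- With a Dirichlet(1) occupancy prior, an unnecessary extra component costs
  only O(1) in log evidence, so evidence comparison cannot *strongly* reject
  k+1 components when k suffice — it can only strongly reject too few.
- The FCS reader supports uncompressed FCS 3.0/3.1 list-mode files with
  uniform float/double/integer channel widths; analysis segments, compressed
  data and FCS 2.0 are not supported.

No empirical claims are made beyond what the test suite and
`scripts/acceptance.py` compute.
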