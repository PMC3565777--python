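"""Nested sampling: posterior draws plus the Bayesian evidence.

A classic static nested-sampling loop: ``n_live`` points live in the unit
hypercube and are mapped to parameter space by the prior transform; at each
iteration the worst live point is replaced by a point drawn from the prior
subject to a hard likelihood threshold, obtained by a Metropolis random walk
started from a surviving live point.  Prior volumes shrink deterministically
as X_i = exp(-i / n_live); the run stops when the maximum possible remaining
contribution falls below a fraction of the accumulated evidence, and the
remaining live points are folded in with equal volume.

The reported evidence uncertainty is the usual sqrt(H / n_live) information
estimate.  The sampler is fully deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist

__all__ = ["PriorSpec", "PosteriorResult", "run_nested_sampling"]


@dataclass(frozen=True)
class PriorSpec:
    """Prior over a k-component landscape model via a hypercube transform.

    means: k sorted uniforms on ``mean_bounds`` (sorting collapses the k!
    labelings); sds: log-uniform on ``sd_bounds``; weights: symmetric
    Dirichlet(``weight_concentration``) through stick-breaking; noise B:
    log-uniform on ``noise_bounds`` (set noise_bounds=None for a purely
    stationary mixture fit with no dynamics).
    """

    k: int
    mean_bounds: tuple[float, float] = (-0.5, 3.5)
    sd_bounds: tuple[float, float] = (0.05, 1.5)
    noise_bounds: tuple[float, float] | None = (0.01, 3.0)
    weight_concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for lo, hi in filter(None, (self.mean_bounds, self.sd_bounds, self.noise_bounds)):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite and ordered")
        if self.sd_bounds[0] <= 0 or (self.noise_bounds and self.noise_bounds[0] <= 0):
            raise ValueError("sd and noise bounds must be positive")
        if self.weight_concentration <= 0:
            raise ValueError("weight concentration must be positive")

    @property
    def ndim(self) -> int:
        return (self.k - 1) + 2 * self.k + (1 if self.noise_bounds is not None else 0)

    @property
    def param_names(self) -> list[str]:
        k = self.k
        names = [f"alpha_{i+1}" for i in range(k)]
        names += [f"mu_{i+1}" for i in range(k)]
        names += [f"var_{i+1}" for i in range(k)]
        if self.noise_bounds is not None:
            names.append("B")
        return names

    def _stick_break(self, u: np.ndarray) -> np.ndarray:
        k, c = self.k, self.weight_concentration
        if k == 1:
            return np.ones(1)
        w = np.empty(k)
        remaining = 1.0
        for i in range(k - 1):
            b = c * (k - 1 - i)
            if c == 1.0:
                v = 1.0 - (1.0 - u[i]) ** (1.0 / b)
            else:
                v = float(beta_dist.ppf(u[i], c, b))
            w[i] = remaining * v
            remaining *= 1.0 - v
        w[k - 1] = remaining
        return np.clip(w, 1e-12, 1.0)

    def transform(self, u: np.ndarray) -> np.ndarray:
        """Map a unit-hypercube point to (alpha_1..k, mu_1..k, var_1..k[, B])."""
        u = np.asarray(u, dtype=float)
        k = self.k
        w = self._stick_break(u[: k - 1])
        w = w / w.sum()
        lo, hi = self.mean_bounds
        mu = lo + (hi - lo) * np.sort(u[k - 1: 2 * k - 1])
        slo, shi = self.sd_bounds
        sd = np.exp(np.log(slo) + (np.log(shi) - np.log(slo)) * u[2 * k - 1: 3 * k - 1])
        theta = np.concatenate([w, mu, sd**2])
        if self.noise_bounds is not None:
            blo, bhi = self.noise_bounds
            B = np.exp(np.log(blo) + (np.log(bhi) - np.log(blo)) * u[3 * k - 1])
            theta = np.append(theta, B)
        return theta


@dataclass
class PosteriorResult:
    """Weighted posterior draws plus the log evidence of one run."""

    param_names: list[str]
    samples: np.ndarray          # (n_draws, n_params) in parameter space
    log_weights: np.ndarray      # normalized: logsumexp(log_weights) == 0
    logz: float
    logzerr: float
    n_live: int
    n_iter: int
    seed: int
    settings: dict = field(default_factory=dict)

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    def __post_init__(self) -> None:
        if self.logzerr <= 0:
            raise ValueError("evidence uncertainty must be positive")
        if abs(logsumexp(self.log_weights)) > 1e-8:
            raise ValueError("posterior weights must be normalized")

    def column(self, name: str) -> np.ndarray:
        try:
            return self.samples[:, self.param_names.index(name)]
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}; have {self.param_names}") from None

    def posterior_mean(self) -> dict[str, float]:
        w = self.weights
        return {n: float(np.dot(w, self.samples[:, i])) for i, n in enumerate(self.param_names)}

    def credible_interval(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Equal-tailed weighted-quantile intervals per parameter."""
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        out = {}
        w = self.weights
        for i, name in enumerate(self.param_names):
            order = np.argsort(self.samples[:, i])
            vals = self.samples[order, i]
            cum = np.cumsum(w[order])
            cum /= cum[-1]
            out[name] = (float(np.interp(lo_q, cum, vals)), float(np.interp(hi_q, cum, vals)))
        return out

    def resample(self, n: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
        """Equal-weight posterior draws, shape (n, n_params)."""
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        idx = rng.choice(self.samples.shape[0], size=n, p=self.weights)
        return self.samples[idx]

    # -- directory serialization ------------------------------------------

    def to_dir(self, path) -> None:
        import pandas as pd
        import yaml

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(self.samples, columns=self.param_names)
        df["weight"] = self.weights
        df.to_csv(path / "draws.csv", index=False)
        with open(path / "evidence.json", "w") as fh:
            json.dump(
                {"logz": self.logz, "logzerr": self.logzerr, "n_live": self.n_live,
                 "n_iter": self.n_iter, "seed": self.seed},
                fh, indent=2,
            )
        with open(path / "settings.yaml", "w") as fh:
            yaml.safe_dump(self.settings, fh)

    @classmethod
    def from_dir(cls, path) -> "PosteriorResult":
        import pandas as pd
        import yaml

        path = Path(path)
        df = pd.read_csv(path / "draws.csv")
        with open(path / "evidence.json") as fh:
            ev = json.load(fh)
        settings_file = path / "settings.yaml"
        settings = yaml.safe_load(settings_file.read_text()) if settings_file.exists() else {}
        names = [c for c in df.columns if c != "weight"]
        w = df["weight"].to_numpy(dtype=float)
        w = w / w.sum()
        return cls(
            param_names=names,
            samples=df[names].to_numpy(dtype=float),
            log_weights=np.log(np.clip(w, 1e-300, None)),
            logz=float(ev["logz"]),
            logzerr=float(ev["logzerr"]),
            n_live=int(ev["n_live"]),
            n_iter=int(ev["n_iter"]),
            seed=int(ev["seed"]),
            settings=settings or {},
        )


def _reflect(u: np.ndarray) -> np.ndarray:
    u = np.mod(u, 2.0)
    return np.where(u > 1.0, 2.0 - u, u)


def run_nested_sampling(
    loglik_fn,
    prior,
    n_live: int = 400,
    seed: int | None = None,
    *,
    ndim: int | None = None,
    walk_steps: int = 25,
    f_remain: float = 1e-3,
    max_iter: int = 200_000,
) -> PosteriorResult:
    """Run static nested sampling and return draws + evidence.

    ``prior`` is a PriorSpec (or any object with .transform and .ndim), or a
    bare callable hypercube transform together with ``ndim``.  ``loglik_fn``
    takes the transformed parameter vector and must return a finite float on
    the whole prior support.
    """
    if hasattr(prior, "transform"):
        transform, ndim = prior.transform, prior.ndim
        names = list(getattr(prior, "param_names", []))
    else:
        transform = prior
        if ndim is None:
            raise ValueError("ndim is required when prior is a bare transform")
        names = []
    seed = 0 if seed is None else int(seed)
    rng = np.random.Generator(np.random.Philox(seed))

    def _eval(u: np.ndarray) -> tuple[np.ndarray, float]:
        theta = np.asarray(transform(u), dtype=float)
        ll = float(loglik_fn(theta))
        if not np.isfinite(ll):
            raise ValueError(f"non-finite log likelihood at parameters {theta.tolist()}")
        return theta, ll

    u_live = rng.random((n_live, ndim))
    pairs = [_eval(u_live[i]) for i in range(n_live)]
    theta_live = np.array([p[0] for p in pairs])
    logl_live = np.array([p[1] for p in pairs])
    if not names:
        names = [f"theta_{i+1}" for i in range(theta_live.shape[1])]

    dead_theta: list[np.ndarray] = []
    dead_logl: list[float] = []
    dead_logw: list[float] = []

    ln_shrink = -1.0 / n_live
    logz = -np.inf
    scale = 0.1
    it = 0
    log_f_remain = np.log(f_remain)

    while it < max_iter:
        it += 1
        worst = int(np.argmin(logl_live))
        logl_star = logl_live[worst]
        # trapezoid weight: X_{i-1} - X_i
        ln_x_prev = ln_shrink * (it - 1)
        ln_x = ln_shrink * it
        ln_w = ln_x_prev + np.log1p(-np.exp(ln_shrink))
        dead_theta.append(theta_live[worst].copy())
        dead_logl.append(float(logl_star))
        dead_logw.append(float(ln_w))
        logz = np.logaddexp(logz, ln_w + logl_star)

        # replacement via constrained random walk from a surviving live point
        start_choices = [i for i in range(n_live) if i != worst] or [worst]
        src = start_choices[int(rng.integers(len(start_choices)))]
        u = u_live[src].copy()
        theta_u, logl_u = theta_live[src].copy(), logl_live[src]
        n_accept = n_total = 0
        local_scale = scale
        for _round in range(5):
            for _ in range(walk_steps):
                u_prop = _reflect(u + local_scale * rng.standard_normal(ndim))
                theta_prop, logl_prop = _eval(u_prop)
                n_total += 1
                if logl_prop > logl_star:
                    u, theta_u, logl_u = u_prop, theta_prop, logl_prop
                    n_accept += 1
            if n_accept > 0:
                break
            local_scale *= 0.3
        u_live[worst] = u
        theta_live[worst] = theta_u
        logl_live[worst] = logl_u
        facc = n_accept / max(1, n_total)
        scale = float(np.clip(scale * np.exp((facc - 0.5) / ndim), 1e-5, 10.0))

        ln_remain = np.max(logl_live) + ln_x
        if ln_remain - logz < log_f_remain:
            break

    # fold in remaining live points with equal volume X_final / n_live
    ln_x_final = ln_shrink * it
    ln_w_live = ln_x_final - np.log(n_live)
    for i in range(n_live):
        dead_theta.append(theta_live[i].copy())
        dead_logl.append(float(logl_live[i]))
        dead_logw.append(float(ln_w_live))
        logz = np.logaddexp(logz, ln_w_live + logl_live[i])

    logl_arr = np.array(dead_logl)
    logw_arr = np.array(dead_logw)
    log_post = logw_arr + logl_arr - logz
    log_post -= logsumexp(log_post)
    p = np.exp(log_post)
    h = float(np.sum(p * (logl_arr - logz)))
    logzerr = float(max(np.sqrt(max(h, 0.0) / n_live), 1e-12))

    return PosteriorResult(
        param_names=names,
        samples=np.array(dead_theta),
        log_weights=log_post,
        logz=float(logz),
        logzerr=logzerr,
        n_live=n_live,
        n_iter=it,
        seed=seed,
        settings={
            "walk_steps": walk_steps,
            "f_remain": f_remain,
            "n_live": n_live,
            "seed": seed,
        },
    )
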