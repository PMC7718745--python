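"""Bayesian whole-genome regression by single-site Gibbs sampling.

Four model classes share one sampler:

* ``A``   — additive marker effects on the NOIA additive coding.
* ``AD``  — additive + dominance marker effects.
* ``ADE`` — AD plus three first-order epistatic random effects whose
  covariances are the trace-normalized Hadamard kernels Vaa, Vad, Vdd
  (pairwise epistatic effects are never materialized).
* ``GK``  — a single Gaussian-kernel (RKHS) random effect.

Marker-effect blocks take one of the Bayesian-alphabet priors: BRR (one
common effect variance), BayesA (per-marker scaled-inverse-chi-square
variances), BayesB (spike-and-slab with per-marker slab variances) or
BayesC (spike-and-slab with one common slab variance). The same prior is
applied to the additive and dominance blocks. Kernel random effects are
sampled in the eigenbasis of their covariance matrix; the residual variance
has a scaled-inverse-chi-square full conditional.

Phenotypes may contain NaN: missing entries are treated as unobserved and
sampled from their full conditional each iteration, which is how
cross-validation prediction extends kernel terms to test individuals
without any train/test kernel algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._gibbs import (
    update_effects_gaussian,
    update_effects_spike_slab,
    update_eigen_effects,
)
from .noia import KernelSet, NOIADesign

MODELS = ("A", "AD", "ADE", "GK")
PRIORS = ("BRR", "BayesA", "BayesB", "BayesC")


@dataclass
class ModelSpec:
    """Model class, marker-effect prior and MCMC settings."""

    model: str = "A"
    prior: str = "BRR"
    n_iter: int = 30_000
    burn_in: int = 15_000
    thin: int = 5
    seed: int | None = None
    R2: float = 0.5
    df: float = 5.0
    df_e: float = 5.0
    pi_counts: tuple[float, float] = (2.0, 8.0)
    fix_sigma2_e: float | None = None
    fix_sigma2_marker: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.prior not in PRIORS:
            raise ValueError(f"prior must be one of {PRIORS}, got {self.prior!r}")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def label(self) -> str:
        return self.model if self.model == "GK" else f"{self.model}-{self.prior}"

    @property
    def n_retained(self) -> int:
        return int(np.ceil((self.n_iter - self.burn_in) / self.thin))


@dataclass
class PosteriorSamples:
    """Retained MCMC draws from one model fit.

    ``u_terms`` maps each kernel term name ("aa", "ad", "dd" or "gk") to the
    per-draw genetic-value vectors of that term (draws x individuals).
    """

    spec: ModelSpec
    ids: np.ndarray
    mu: np.ndarray
    sigma2_e: np.ndarray
    a: np.ndarray | None = None
    d: np.ndarray | None = None
    u_terms: dict = field(default_factory=dict)
    sigma2_terms: dict = field(default_factory=dict)
    pi_terms: dict = field(default_factory=dict)
    observed: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return len(self.mu)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def posterior_mean_fitted(self, design: NOIADesign | None = None) -> np.ndarray:
        """Posterior-mean fitted value mu + g for every individual."""
        yhat = np.full(self.n_individuals, self.mu.mean())
        if self.a is not None:
            if design is None:
                raise ValueError("marker-effect model needs the NOIA design")
            yhat = yhat + design.Wa @ self.a.mean(axis=0)
        if self.d is not None:
            yhat = yhat + design.Wd @ self.d.mean(axis=0)
        for u in self.u_terms.values():
            yhat = yhat + u.mean(axis=0)
        return yhat

    def save(self, path: str | Path) -> None:
        """Persist draws as an .npz container with the spec embedded."""
        import json

        spec_json = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.spec.__dict__.items()}
        )
        arrays = {
            "ids": self.ids.astype(str),
            "mu": self.mu,
            "sigma2_e": self.sigma2_e,
            "spec_json": np.array(spec_json),
        }
        if self.a is not None:
            arrays["a"] = self.a
        if self.d is not None:
            arrays["d"] = self.d
        if self.observed is not None:
            arrays["observed"] = self.observed
        for k, v in self.u_terms.items():
            arrays[f"u_{k}"] = v
        for k, v in self.sigma2_terms.items():
            arrays[f"s2_{k}"] = v
        for k, v in self.pi_terms.items():
            arrays[f"pi_{k}"] = v
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorSamples":
        import json

        with np.load(path, allow_pickle=False) as z:
            d = json.loads(str(z["spec_json"]))
            d["pi_counts"] = tuple(d["pi_counts"])
            spec = ModelSpec(**d)
            kw = dict(
                spec=spec, ids=z["ids"], mu=z["mu"], sigma2_e=z["sigma2_e"],
                a=z["a"] if "a" in z else None,
                d=z["d"] if "d" in z else None,
                observed=z["observed"] if "observed" in z else None,
            )
            u_terms, s2, pi = {}, {}, {}
            for k in z.files:
                if k.startswith("u_"):
                    u_terms[k[2:]] = z[k]
                elif k.startswith("s2_"):
                    s2[k[3:]] = z[k]
                elif k.startswith("pi_"):
                    pi[k[3:]] = z[k]
            return cls(u_terms=u_terms, sigma2_terms=s2, pi_terms=pi, **kw)


class _MarkerTerm:
    def __init__(self, name, W, spec, r2_term, var_y, rng):
        self.name = name
        self.W = np.asfortranarray(W, dtype=np.float64)
        self.csum = np.ascontiguousarray((self.W**2).sum(axis=0))
        n, L = self.W.shape
        self.L = L
        msx = float(np.sum(np.var(self.W, axis=0)))
        if msx <= 0:
            raise ValueError(f"term {name!r}: coefficient matrix carries no variance")
        self.pi0 = spec.pi_counts[0] / sum(spec.pi_counts)
        mode = r2_term * var_y / msx
        if spec.prior in ("BayesB", "BayesC"):
            mode = mode / self.pi0
        if spec.fix_sigma2_marker is not None:
            self.S = None
            self.var = np.full(L, spec.fix_sigma2_marker)
        else:
            self.S = mode * (spec.df + 2.0) / spec.df
            self.var = np.full(L, mode)
        self.a = np.zeros(L)
        self.incl = np.ones(L, dtype=np.int64)
        self.pi = self.pi0
        self.spec = spec

    def sweep(self, e, sigma2_e, rng):
        spec = self.spec
        normals = rng.standard_normal(self.L)
        if spec.prior in ("BRR", "BayesA"):
            update_effects_gaussian(
                self.W, self.csum, self.a, e, self.var, sigma2_e, normals
            )
        else:
            uniforms = rng.random(self.L)
            logit_pi = np.log(self.pi / (1.0 - self.pi))
            update_effects_spike_slab(
                self.W, self.csum, self.a, self.incl, e, self.var, sigma2_e,
                logit_pi, normals, uniforms,
            )
        if spec.fix_sigma2_marker is not None:
            return
        df, S = spec.df, self.S
        if spec.prior == "BRR":
            v = (self.a @ self.a + df * S) / rng.chisquare(df + self.L)
            self.var[:] = v
        elif spec.prior == "BayesA":
            self.var = (self.a**2 + df * S) / rng.chisquare(df + 1.0, size=self.L)
        elif spec.prior == "BayesB":
            c_in = rng.chisquare(df + 1.0, size=self.L)
            c_out = rng.chisquare(df, size=self.L)
            self.var = np.where(
                self.incl == 1, (self.a**2 + df * S) / c_in, (df * S) / c_out
            )
        else:  # BayesC
            n_in = int(self.incl.sum())
            ssq = float(self.a @ self.a)
            v = (ssq + df * S) / rng.chisquare(df + n_in)
            self.var[:] = v
        if spec.prior in ("BayesB", "BayesC"):
            n_in = int(self.incl.sum())
            c1, c2 = spec.pi_counts
            self.pi = float(
                np.clip(rng.beta(c1 + n_in, c2 + self.L - n_in), 1e-6, 1 - 1e-6)
            )

    def var_summary(self) -> float:
        return float(self.var.mean())


class _KernelTerm:
    def __init__(self, name, K, spec, r2_term, var_y):
        self.name = name
        w, U = np.linalg.eigh(K)
        scale = max(1.0, float(w.max()) if len(w) else 1.0)
        if w.min() < -1e-8 * scale:
            raise ValueError(
                f"kernel {name!r} is not positive semi-definite "
                f"(min eigenvalue {w.min():.3g})"
            )
        keep = w > 1e-8
        self.eigval = np.ascontiguousarray(w[keep])
        self.U = np.asfortranarray(U[:, keep])
        self.m = int(keep.sum())
        mode = r2_term * var_y  # kernels are trace-normalized: mean diag = 1
        self.S = mode * (spec.df + 2.0) / spec.df
        self.sigma2_u = mode
        self.delta = np.zeros(self.m)
        self.spec = spec

    def sweep(self, e, sigma2_e, rng):
        normals = rng.standard_normal(self.m)
        update_eigen_effects(
            self.U, self.eigval, self.delta, e, self.sigma2_u, sigma2_e, normals
        )
        df, S = self.spec.df, self.S
        ssq = float(np.sum(self.delta**2 / self.eigval))
        self.sigma2_u = (ssq + df * S) / rng.chisquare(df + self.m)

    def genetic_value(self) -> np.ndarray:
        return self.U @ self.delta


def fit_model(
    spec: ModelSpec,
    y: np.ndarray,
    design: NOIADesign | None = None,
    kernels: KernelSet | None = None,
) -> PosteriorSamples:
    """Run the Gibbs sampler and return retained draws.

    ``y`` may contain NaN for individuals to predict (their phenotypes are
    sampled from the model each iteration). ``design`` is required for
    marker-effect models (A/AD/ADE); ``kernels`` for ADE (Vaa/Vad/Vdd) and
    GK (K).
    """
    y = np.asarray(y, dtype=float)
    if np.isinf(y).any():
        raise ValueError("phenotypes contain non-finite (inf) values")
    obs = ~np.isnan(y)
    if obs.sum() < 3:
        raise ValueError("need at least 3 observed phenotypes")
    n = len(y)

    if spec.model in ("A", "AD", "ADE"):
        if design is None:
            raise ValueError(f"model {spec.model} requires a NOIA design")
        if design.n_individuals != n:
            raise ValueError("design rows do not match phenotype length")
        ids = np.asarray(design.ids)
    else:
        if kernels is None or kernels.K is None:
            raise ValueError("GK model requires a KernelSet with K")
        if kernels.K.shape[0] != n:
            raise ValueError("kernel order does not match phenotype length")
        ids = np.asarray(kernels.ids)
    if spec.model == "ADE":
        if kernels is None or kernels.Vaa is None:
            raise ValueError("ADE model requires epistatic kernels Vaa/Vad/Vdd")

    rng = np.random.default_rng(spec.seed)
    var_y = float(np.var(y[obs]))
    if var_y == 0.0:
        var_y = 1e-8

    marker_terms: list[_MarkerTerm] = []
    kernel_terms: list[_KernelTerm] = []
    if spec.model in ("A", "AD", "ADE"):
        marker_terms.append(_MarkerTerm("a", design.Wa, spec, 0.0, var_y, rng))
    if spec.model in ("AD", "ADE"):
        marker_terms.append(_MarkerTerm("d", design.Wd, spec, 0.0, var_y, rng))
    if spec.model == "ADE":
        for nm, K in (("aa", kernels.Vaa), ("ad", kernels.Vad), ("dd", kernels.Vdd)):
            kernel_terms.append(_KernelTerm(nm, K, spec, 0.0, var_y))
    if spec.model == "GK":
        kernel_terms.append(_KernelTerm("gk", kernels.K, spec, 0.0, var_y))

    # equal R2 partition across active genetic terms
    n_terms = len(marker_terms) + len(kernel_terms)
    r2_term = spec.R2 / n_terms
    for t in marker_terms:
        if spec.fix_sigma2_marker is None:
            msx = float(np.sum(np.var(t.W, axis=0)))
            mode = r2_term * var_y / msx
            if spec.prior in ("BayesB", "BayesC"):
                mode = mode / t.pi0
            t.S = mode * (spec.df + 2.0) / spec.df
            t.var[:] = mode
    for t in kernel_terms:
        mode = r2_term * var_y
        t.S = mode * (spec.df + 2.0) / spec.df
        t.sigma2_u = mode

    if spec.fix_sigma2_e is not None:
        sigma2_e = float(spec.fix_sigma2_e)
    else:
        sigma2_e = var_y * (1.0 - spec.R2)
    S_e = var_y * (1.0 - spec.R2) * (spec.df_e + 2.0) / spec.df_e

    mu = float(np.mean(y[obs]))
    y_work = np.where(obs, y, np.mean(y[obs]))
    e = y_work - mu
    miss_idx = np.where(~obs)[0]

    T = spec.n_retained
    out_mu = np.empty(T)
    out_s2e = np.empty(T)
    out_a = np.empty((T, marker_terms[0].L)) if marker_terms else None
    out_d = (
        np.empty((T, marker_terms[1].L)) if len(marker_terms) > 1 else None
    )
    out_u = {t.name: np.empty((T, n)) for t in kernel_terms}
    out_s2 = {t.name: np.empty(T) for t in marker_terms + kernel_terms}
    out_pi = (
        {t.name: np.empty(T) for t in marker_terms}
        if spec.prior in ("BayesB", "BayesC")
        else {}
    )

    t_out = 0
    for it in range(spec.n_iter):
        # intercept (flat prior)
        e += mu
        mu = float(np.mean(e) + rng.standard_normal() * np.sqrt(sigma2_e / n))
        e -= mu

        for term in marker_terms:
            term.sweep(e, sigma2_e, rng)
        for term in kernel_terms:
            term.sweep(e, sigma2_e, rng)

        if miss_idx.size:
            e[miss_idx] = rng.standard_normal(miss_idx.size) * np.sqrt(sigma2_e)

        if spec.fix_sigma2_e is None:
            sse = float(e @ e)
            sigma2_e = (sse + spec.df_e * S_e) / rng.chisquare(spec.df_e + n)

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            out_mu[t_out] = mu
            out_s2e[t_out] = sigma2_e
            if out_a is not None:
                out_a[t_out] = marker_terms[0].a
            if out_d is not None:
                out_d[t_out] = marker_terms[1].a
            for term in marker_terms:
                out_s2[term.name][t_out] = term.var_summary()
                if spec.prior in ("BayesB", "BayesC"):
                    out_pi[term.name][t_out] = term.pi
            for term in kernel_terms:
                out_u[term.name][t_out] = term.genetic_value()
                out_s2[term.name][t_out] = term.sigma2_u
            t_out += 1

    return PosteriorSamples(
        spec=spec, ids=ids, mu=out_mu, sigma2_e=out_s2e, a=out_a, d=out_d,
        u_terms=out_u, sigma2_terms=out_s2, pi_terms=out_pi, observed=obs,
    )


def predict(
    samples: PosteriorSamples,
    test_ids: np.ndarray,
    design_all: NOIADesign | None = None,
) -> np.ndarray:
    """Posterior-mean predictions for the given individuals.

    The fit must have covered the test individuals (their phenotypes masked
    as NaN); marker-effect models need the same NOIA design used in the fit.
    """
    yhat = samples.posterior_mean_fitted(design_all)
    index = {str(i): k for k, i in enumerate(samples.ids)}
    try:
        rows = [index[str(t)] for t in test_ids]
    except KeyError as err:
        raise ValueError(f"unknown test individual {err.args[0]!r}") from None
    return yhat[rows]
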