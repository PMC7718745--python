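"""NOIA additive/dominance codings, relationship matrices and kernels.

The natural-and-orthogonal-interactions (NOIA) parameterization builds
additive and dominance marker codings from the *observed genotype
frequencies* at each locus, so additive and dominance effect components are
statistically orthogonal in the analyzed population itself — no
Hardy-Weinberg assumption. With genotype frequencies (p_AA, p_Aa, p_aa) and
alternate-allele counts coded 2/1/0, the codings are

    additive:   W_a = code - (p_Aa + 2 p_AA)
    dominance:  W_d = -2 p_Aa p_aa / Delta   (code 2)
                 4 p_AA p_aa / Delta         (code 1)
                -2 p_AA p_Aa / Delta         (code 0)

with Delta = p_AA + p_aa - (p_AA - p_aa)^2. Both columns sum to zero and
their cross-product vanishes at every non-degenerate locus.

First-order epistatic terms never materialize pairwise coefficient products:
their covariance structure equals Hadamard products of the additive and
dominance relationship matrices, each trace-normalized to n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform

from .markers import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

DEGENERATE_TOL = 1e-12


@dataclass
class NOIADesign:
    """Additive (Wa) and dominance (Wd) coefficient matrices.

    ``freqs`` holds per-locus genotype frequencies as columns
    (p_aa, p_Aa, p_AA); loci where the dominance denominator Delta falls
    below tolerance are flagged ``degenerate`` and carry an all-zero Wd
    column (they contribute additive information only).
    """

    Wa: np.ndarray
    Wd: np.ndarray
    freqs: np.ndarray
    degenerate: np.ndarray
    ids: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.Wa.shape[0]

    @property
    def n_markers(self) -> int:
        return self.Wa.shape[1]


def noia_coding(g: GenotypeMatrix, drop_monomorphic: bool = False) -> NOIADesign:
    """Compute NOIA additive/dominance codings from observed genotype classes.

    Genotype frequencies are computed from observed (non-missing) calls;
    missing cells then receive the mean-imputed additive code and zero
    dominance code. Monomorphic loci get all-zero columns (no information)
    and are flagged degenerate; with ``drop_monomorphic`` they are removed.
    """
    codes = g.codes
    n, L = codes.shape
    obs = codes != MISSING
    n_obs = obs.sum(axis=0).astype(float)
    if np.any(n_obs == 0):
        raise ValueError("marker with no observed genotypes")
    p2 = ((codes == 2) & obs).sum(axis=0) / n_obs  # p_AA
    p1 = ((codes == 1) & obs).sum(axis=0) / n_obs  # p_Aa
    p0 = ((codes == 0) & obs).sum(axis=0) / n_obs  # p_aa

    x = g.imputed()
    Wa = x - (p1 + 2.0 * p2)

    delta = p2 + p0 - (p2 - p0) ** 2
    degenerate = delta < DEGENERATE_TOL
    mono = ((p2 == 1.0) | (p1 == 1.0) | (p0 == 1.0))
    degenerate = degenerate | mono
    safe = np.where(degenerate, 1.0, delta)
    wd_by_code = np.stack(
        [
            -2.0 * p2 * p1 / safe,  # code 0
            4.0 * p2 * p0 / safe,   # code 1
            -2.0 * p1 * p0 / safe,  # code 2
        ]
    )
    Wd = np.zeros((n, L))
    for code in (0, 1, 2):
        mask = codes == code
        Wd[mask] = np.broadcast_to(wd_by_code[code], (n, L))[mask]
    Wd[:, degenerate] = 0.0
    Wd[codes == MISSING] = 0.0
    if mono.any():
        logger.info("noia_coding: %d monomorphic loci carry no information",
                    int(mono.sum()))
        Wa[:, mono] = 0.0
    design = NOIADesign(
        Wa=Wa, Wd=Wd, freqs=np.stack([p0, p1, p2]),
        degenerate=degenerate, ids=np.asarray(g.ids),
    )
    if drop_monomorphic and mono.any():
        keep = ~mono
        design = NOIADesign(
            Wa=Wa[:, keep], Wd=Wd[:, keep], freqs=design.freqs[:, keep],
            degenerate=degenerate[keep], ids=design.ids,
        )
    return design


def _trace_normalize(m: np.ndarray, name: str) -> np.ndarray:
    n = m.shape[0]
    tr = np.trace(m)
    if tr <= 0:
        raise ValueError(f"{name}: non-positive trace, matrix carries no signal")
    return m * (n / tr)


def relationship_matrices(design: NOIADesign) -> tuple[np.ndarray, np.ndarray]:
    """Additive (A) and dominance (D) relationship matrices, trace = n."""
    A = _trace_normalize(design.Wa @ design.Wa.T, "A")
    DD = design.Wd @ design.Wd.T
    if bool(np.all(design.degenerate)) or np.trace(DD) <= 0:
        raise ValueError(
            "dominance coding is degenerate at every locus (e.g. a fully "
            "inbred panel with no heterozygotes); D is undefined — fit "
            "additive-only models (disable AD/ADE)"
        )
    D = _trace_normalize(DD, "D")
    return A, D


def epistatic_kernels(
    A: np.ndarray, D: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First-order epistatic matrices: Hadamard products, trace-normalized.

    Vaa = (A o A) / (tr(A o A)/n), Vad likewise from A o D (covering both
    additive-by-dominance directions), Vdd from D o D.
    """
    if A.shape != D.shape or A.shape[0] != A.shape[1]:
        raise ValueError("A and D must be square matrices of the same order")
    Vaa = _trace_normalize(A * A, "Vaa")
    Vad = _trace_normalize(A * D, "Vad")
    Vdd = _trace_normalize(D * D, "Vdd")
    return Vaa, Vad, Vdd


def gaussian_kernel(
    g: GenotypeMatrix | np.ndarray, h: float
) -> tuple[np.ndarray, np.ndarray]:
    """Squared-Euclidean distance matrix S and Gaussian kernel K = exp(-h S)."""
    if h <= 0:
        raise ValueError(f"bandwidth h must be > 0, got {h}")
    x = g.imputed() if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    S = squareform(pdist(x, metric="sqeuclidean"))
    K = np.exp(-h * S)
    np.fill_diagonal(K, 1.0)
    return S, K


@dataclass
class KernelSet:
    """All relationship structures one model run needs."""

    A: np.ndarray
    D: np.ndarray | None
    Vaa: np.ndarray | None
    Vad: np.ndarray | None
    Vdd: np.ndarray | None
    S: np.ndarray | None
    K: np.ndarray | None
    h: float | None
    ids: np.ndarray


def build_kernels(
    g: GenotypeMatrix, h: float | None = None, with_gk: bool = True
) -> KernelSet:
    """Convenience constructor computing every matrix from one genotype set."""
    design = noia_coding(g)
    A, D = relationship_matrices(design)
    Vaa, Vad, Vdd = epistatic_kernels(A, D)
    S = K = None
    if with_gk:
        x = g.imputed()
        S = squareform(pdist(x, metric="sqeuclidean"))
        if h is None:
            med = np.median(S[S > 0]) if np.any(S > 0) else 1.0
            h = 1.0 / med
        K = np.exp(-h * S)
        np.fill_diagonal(K, 1.0)
    return KernelSet(A=A, D=D, Vaa=Vaa, Vad=Vad, Vdd=Vdd, S=S, K=K, h=h,
                     ids=np.asarray(g.ids))


# ---------------------------------------------------------------------------
# Gaussian-kernel bandwidth by REML

DEFAULT_H_GRID = (0.01, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0)


def _reml_loglik_kernel(y: np.ndarray, K: np.ndarray) -> float:
    """Profile REML log-likelihood of y = mu + u + e, u ~ N(0, K s2u),
    maximized over the variance ratio and the overall scale."""
    n = len(y)
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    ys = U.T @ y
    xs = U.T @ np.ones(n)

    def neg_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)  # s2u / s2e
        d = lam * w + 1.0
        xtvx = np.sum(xs**2 / d)
        beta = np.sum(xs * ys / d) / xtvx
        r = ys - xs * beta
        quad = np.sum(r**2 / d)
        s2e = quad / (n - 1)
        ll = -0.5 * (
            np.sum(np.log(d)) + (n - 1) * np.log(s2e) + np.log(xtvx) + (n - 1)
        )
        return -ll

    res = minimize_scalar(neg_ll, bounds=(-12.0, 12.0), method="bounded")
    return -float(res.fun)


def optimize_bandwidth(
    S: np.ndarray,
    y: np.ndarray,
    grid: tuple[float, ...] = DEFAULT_H_GRID,
) -> float:
    """Pick the Gaussian-kernel bandwidth maximizing the REML log-likelihood.

    Candidate bandwidths are ``grid / median(nonzero S)`` so the grid adapts
    to the scale of the distance matrix (h enters only through h*S). Ties,
    including the flat profile under pure noise, resolve to the smallest h.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 training observations")
    nz = S[S > 0]
    med = float(np.median(nz)) if nz.size else 1.0
    hs = [h0 / med for h0 in grid]
    if np.std(y) == 0:
        logger.warning("constant response: REML profile degenerate; "
                       "returning smallest grid bandwidth")
        return hs[0]
    best_h, best_ll = hs[0], -np.inf
    for h in hs:
        K = np.exp(-h * S)
        np.fill_diagonal(K, 1.0)
        ll = _reml_loglik_kernel(y, K)
        if ll > best_ll + 1e-9:
            best_ll, best_h = ll, h
    return best_h
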