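"""Block adjustment of field phenotypes from unreplicated designs.

The emulated trial allocates each breeding candidate to a single plot in one
of a small number of blocks, with replicated check genotypes tying the
blocks together. Adjusted values come from the mixed model

    y_ik = mu + g_i + b_k + e_ik

with genotype effects random i.i.d. N(0, s2_g) for unreplicated candidates,
fixed for replicated checks, block effects random N(0, s2_b) and residuals
N(0, s2_e). Variance components are estimated by EM-REML on the mixed-model
equations; the adjusted value of genotype i is mu_hat + g_hat_i (BLUP for
candidates, generalized-least-squares estimate for checks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)


@dataclass
class AdjustedPhenotypes:
    """One trait's adjusted values and REML variance components."""

    adjusted: pd.Series  # index genotype_id, value mu_hat + g_hat
    mu: float
    sigma2_g: float
    sigma2_b: float
    sigma2_e: float
    is_check: pd.Series
    loglik: float
    n_iter: int
    converged: bool


def adjust_phenotypes(
    obs: pd.DataFrame,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> dict[str, AdjustedPhenotypes]:
    """Fit the adjustment model independently for every trait in the table.

    ``obs`` is long-format with columns genotype_id, block, trait, value,
    is_check. Rows with missing values are dropped with a log entry.
    """
    required = {"genotype_id", "block", "trait", "value", "is_check"}
    if not required.issubset(obs.columns):
        raise ValueError(f"phenotype table needs columns {sorted(required)}")
    out = {}
    for trait, sub in obs.groupby("trait"):
        out[str(trait)] = adjust_single_trait(sub, max_iter=max_iter, tol=tol)
    return out


def adjust_single_trait(
    obs: pd.DataFrame,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> AdjustedPhenotypes:
    sub = obs.dropna(subset=["value"])
    n_dropped = len(obs) - len(sub)
    if n_dropped:
        logger.info("dropped %d observations with missing values", n_dropped)
    y = sub["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype values")
    gid = sub["genotype_id"].astype(str).to_numpy()
    block = sub["block"].astype(str).to_numpy()
    is_check = sub["is_check"].astype(bool).to_numpy()

    blocks = pd.unique(block)
    n_blocks = len(blocks)
    check_ids = pd.unique(gid[is_check])
    cand_ids = pd.unique(gid[~is_check])
    if len(cand_ids) == 0:
        raise ValueError("no unreplicated candidates in the table")
    if n_blocks > 1:
        # block effects are estimable only if some genotype spans blocks
        spanning = (
            pd.DataFrame({"g": gid, "b": block}).groupby("g")["b"].nunique() > 1
        )
        if not spanning.any():
            raise ValueError(
                "no replicated genotype spans blocks; block effects are "
                "inestimable — include replicated checks"
            )

    N = len(y)
    # fixed: intercept + one dummy per check genotype
    X = np.ones((N, 1 + len(check_ids)))
    X[:, 1:] = 0.0
    for j, cid in enumerate(check_ids):
        X[gid == cid, 1 + j] = 1.0
    # random: candidate genotypes, blocks
    cand_index = {c: j for j, c in enumerate(cand_ids)}
    Zg = np.zeros((N, len(cand_ids)))
    for i in range(N):
        if not is_check[i]:
            Zg[i, cand_index[gid[i]]] = 1.0
    use_block = n_blocks > 1
    if not use_block:
        logger.warning("single block: block variance fixed at 0")
    Zb = np.zeros((N, n_blocks if use_block else 0))
    if use_block:
        bindex = {b: j for j, b in enumerate(blocks)}
        for i in range(N):
            Zb[i, bindex[block[i]]] = 1.0

    fit = _em_reml(y, X, [Zg, Zb] if use_block else [Zg], max_iter, tol)
    beta, u_list, s2, s2e, ll, n_iter, converged = fit
    s2g = s2[0]
    s2b = s2[1] if use_block else 0.0

    mu = float(beta[0])
    adj = {}
    flag = {}
    for j, cid in enumerate(check_ids):
        adj[str(cid)] = mu + float(beta[1 + j])
        flag[str(cid)] = True
    for c, j in cand_index.items():
        adj[str(c)] = mu + float(u_list[0][j])
        flag[str(c)] = False
    adjusted = pd.Series(adj, name="adjusted")
    adjusted.index.name = "genotype_id"
    return AdjustedPhenotypes(
        adjusted=adjusted,
        mu=mu,
        sigma2_g=float(s2g),
        sigma2_b=float(s2b),
        sigma2_e=float(s2e),
        is_check=pd.Series(flag, name="is_check"),
        loglik=float(ll),
        n_iter=n_iter,
        converged=converged,
    )


def _em_reml(y, X, Z_list, max_iter, tol):
    """EM-REML for y = X beta + sum_k Z_k u_k + e with i.i.d. components.

    Works on the mixed-model equations M = W'W + diag(0, lam_1 I, ...) with
    lam_k = s2e/s2k; returns fixed effects, BLUPs, variance components and
    the REML log-likelihood (computed from the MME Cholesky factor).
    """
    N, p = X.shape
    q = [Z.shape[1] for Z in Z_list]
    W = np.hstack([X] + list(Z_list))
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    vy = float(np.var(y))
    if vy == 0.0:
        vy = 1.0
    floor = 1e-10 * vy
    s2 = [0.3 * vy if qq > 0 else 0.0 for qq in q]
    s2e = max(0.4 * vy, floor)

    rank_x = np.linalg.matrix_rank(X)
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        M = WtW.copy()
        ofs = p
        for k, qq in enumerate(q):
            lam = s2e / max(s2[k], floor)
            M[ofs:ofs + qq, ofs:ofs + qq] += lam * np.eye(qq)
            ofs += qq
        c, low = cho_factor(M, lower=True)
        theta = cho_solve((c, low), Wty)
        Minv = cho_solve((c, low), np.eye(M.shape[0]))

        quad = yty - float(theta @ Wty)  # y'y - theta' W'y = s2e * y'Py
        # REML log-likelihood via the MME identity
        dim = M.shape[0]
        logdetM = 2.0 * np.sum(np.log(np.diag(c)))
        ll = -0.5 * (
            (N - rank_x) * np.log(2 * np.pi)
            + N * np.log(s2e)
            + sum(qq * np.log(max(s2[k], floor)) for k, qq in enumerate(q))
            + (logdetM - dim * np.log(s2e))
            + quad / s2e
        )

        # EM updates
        ofs = p
        s2_new = []
        for k, qq in enumerate(q):
            u = theta[ofs:ofs + qq]
            tr = np.trace(Minv[ofs:ofs + qq, ofs:ofs + qq])
            s2_new.append(max((float(u @ u) + s2e * tr) / qq, floor))
            ofs += qq
        s2e_new = max(quad / (N - rank_x), floor)

        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (1.0 + abs(ll)):
            s2, s2e = s2_new, s2e_new
            converged = True
            break
        s2, s2e, ll_prev = s2_new, s2e_new, ll

    # final solve at converged variances
    M = WtW.copy()
    ofs = p
    for k, qq in enumerate(q):
        lam = s2e / max(s2[k], floor)
        M[ofs:ofs + qq, ofs:ofs + qq] += lam * np.eye(qq)
        ofs += qq
    c, low = cho_factor(M, lower=True)
    theta = cho_solve((c, low), Wty)
    beta = theta[:p]
    u_list = []
    ofs = p
    for qq in q:
        u_list.append(theta[ofs:ofs + qq])
        ofs += qq
    s2 = [0.0 if s <= floor * 1.01 else s for s in s2]
    return beta, u_list, s2, s2e, ll_prev, it, converged
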