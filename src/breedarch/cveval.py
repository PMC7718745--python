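"""Cross-validated predictive ability and model comparison.

Predictive ability of a model spec is the Pearson correlation r between
adjusted phenotypes and predictions assembled over one full round of
fivefold cross-validation (every individual predicted exactly once per
replication, with its phenotype masked during training). Replications use
fresh random fold partitions, shared across specs so comparisons are
paired. For comparison, r is variance-stabilized with the Fisher
z-transform and specs are compared by Tukey's HSD on the replication-level
z values, reported as a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .bayes import ModelSpec, fit_model, predict
from .noia import KernelSet, NOIADesign, optimize_bandwidth


def fisher_z(r: float) -> float:
    """Fisher z-transform atanh(r); defined only for |r| < 1."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError(f"|r| must be < 1 for the Fisher z-transform, got {r}")
    return float(np.arctanh(r))


@dataclass
class CVResult:
    """Replication-level predictive abilities per model spec."""

    records: pd.DataFrame  # columns: spec, replication, r, z
    folds: dict  # replication -> fold index per individual
    n_folds: int

    def mean_z(self) -> pd.Series:
        return self.records.groupby("spec")["z"].mean().sort_values(ascending=False)


def _partition(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(n)
    fold = np.empty(n, dtype=np.int64)
    for k, chunk in enumerate(np.array_split(perm, n_folds)):
        fold[chunk] = k
    return fold


def crossvalidate(
    y: np.ndarray,
    specs: list[ModelSpec],
    design: NOIADesign | None = None,
    kernels: KernelSet | None = None,
    n_folds: int = 5,
    n_reps: int = 20,
    seed: int | None = None,
) -> CVResult:
    """Fivefold cross-validation of every spec over shared fold partitions.

    Each fold is predicted by refitting the model with that fold's
    phenotypes masked (NaN), so kernel terms extend to held-out individuals
    through the full-population covariance. For GK specs the Gaussian-kernel
    bandwidth is re-optimized by REML on each training subset.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < n_folds:
        raise ValueError(f"n={n} individuals cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    rows = []
    folds_by_rep = {}
    for rep in range(n_reps):
        fold = _partition(n, n_folds, rng)
        counts = np.bincount(fold, minlength=n_folds)
        if counts.min() < 2:
            raise ValueError("a fold has fewer than 2 individuals")
        folds_by_rep[rep] = fold
        for spec in specs:
            yhat = np.full(n, np.nan)
            for k in range(n_folds):
                test = fold == k
                y_masked = y.copy()
                y_masked[test] = np.nan
                fit_seed = int(rng.integers(0, 2**31 - 1))
                fold_spec = replace(spec, seed=fit_seed)
                fold_kernels = kernels
                if spec.model == "GK":
                    if kernels is None or kernels.S is None:
                        raise ValueError("GK cross-validation needs the distance matrix S")
                    tr = ~test
                    h = optimize_bandwidth(kernels.S[np.ix_(tr, tr)], y[tr])
                    K = np.exp(-h * kernels.S)
                    np.fill_diagonal(K, 1.0)
                    fold_kernels = replace(kernels, K=K, h=h)
                samples = fit_model(fold_spec, y_masked, design=design,
                                    kernels=fold_kernels)
                yhat[test] = samples.posterior_mean_fitted(design)[test]
            r = float(np.corrcoef(y, yhat)[0, 1])
            rows.append(
                {"spec": spec.label, "replication": rep, "r": r, "z": fisher_z(r)}
            )
    return CVResult(records=pd.DataFrame(rows), folds=folds_by_rep, n_folds=n_folds)


# ---------------------------------------------------------------------------
# Tukey HSD with compact letter display


def compare_models(cv: CVResult, alpha: float = 0.01) -> pd.DataFrame:
    """Tukey-HSD grouping of specs on replication-level z values.

    One-way layout: spec is the factor, replications the observations.
    Returns specs sorted by descending mean z with a letter column; specs
    sharing a letter are not significantly different at ``alpha``. With zero
    within-group variance everywhere, any difference in means is declared
    significant (the studentized range is degenerate).
    """
    return tukey_letters(cv.records, value="z", group="spec", alpha=alpha)


def tukey_letters(
    df: pd.DataFrame, value: str, group: str, alpha: float = 0.01
) -> pd.DataFrame:
    groups = df.groupby(group)[value]
    means = groups.mean().sort_values(ascending=False)
    sizes = groups.size()
    k = len(means)
    if k < 2:
        raise ValueError("need at least 2 groups to compare")
    if (sizes < 2).any():
        raise ValueError("need at least 2 replications per group")
    n_tot = int(sizes.sum())
    dfe = n_tot - k
    sse = float(
        sum(((g - g.mean()) ** 2).sum() for _, g in groups)
    )
    mse = sse / dfe
    nh = k / float((1.0 / sizes).sum())  # harmonic mean group size
    if mse > 0:
        qcrit = studentized_range.ppf(1.0 - alpha, k, dfe)
        hsd = qcrit * np.sqrt(mse / nh)
    else:
        hsd = 0.0  # degenerate: any mean difference separates groups

    m = means.to_numpy()
    # interval-based compact letter display (equal-replication Tukey makes
    # non-significance an interval relation on the sorted means)
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and (m[i] - m[j + 1]) <= hsd + 1e-12:
            j += 1
        intervals.append((i, j))
    letters = [""] * k
    letter_ord = 0
    prev_end = -1
    for i, j in intervals:
        if j <= prev_end and i > 0:
            continue  # contained in an earlier interval: no new letter
        ch = chr(ord("a") + letter_ord)
        letter_ord += 1
        for t in range(i, j + 1):
            letters[t] += ch
        prev_end = j
    out = pd.DataFrame(
        {
            group: means.index,
            "mean": m,
            "n": sizes.loc[means.index].to_numpy(),
            "letters": letters,
        }
    )
    return out.reset_index(drop=True)
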