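"""Canonical synthetic study conditions and their summary quantities.

Each function here assembles one self-contained in-silico experiment at the
package's declared study conditions — simulate a population, run the
analysis, measure the result — and returns plain numbers. The acceptance
checks, the repository's analysis drivers and the reproduction script all
call these, so the conditions are defined in exactly one place.

Problem sizes (documented in docs/methods.md): recovery and cross-validation
studies run on scaled S0 populations of 500 individuals (125 families x 4
sibs); studies whose target quantity is known to need the full population
size — dominance-share recovery and window-based QTL detection — run at
1,000 individuals (250 families x 4), the size of the emulated program's
S0 generation.
"""

from __future__ import annotations

import numpy as np

from . import simdata
from .bayes import ModelSpec, fit_model
from .cveval import compare_models, crossvalidate
from .gwas import make_windows, regional_variance, wppa
from .noia import build_kernels, noia_coding
from .markers import GenotypeMatrix
from .pheno import adjust_single_trait
from .posterior import variance_components


def _sub(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31 - 1)


def random_population(rng: np.random.Generator, n: int, L: int) -> GenotypeMatrix:
    """Genotypes with arbitrary per-locus genotype frequencies (no HWE)."""
    probs = rng.dirichlet(np.ones(3), size=L)
    u = rng.random((n, L))
    c = np.cumsum(probs, axis=1)
    codes = (u[..., None] > c[None, :, :]).sum(axis=2).astype(np.int8)
    return GenotypeMatrix(
        codes, chrom=np.repeat("chr1", L), pos=np.arange(1, L + 1) * 1000,
        ids=np.array([f"i{i}" for i in range(n)]),
    )


def _population(seed: int, n_families: int, n_chrom: int, markers_per_chrom: int,
                chrom_length_cm: float = 100.0):
    panel = simdata.simulate_founders(
        n_chrom=n_chrom, markers_per_chrom=markers_per_chrom,
        chrom_length_cm=chrom_length_cm, seed=_sub(seed, 1),
    )
    plan = simdata.default_plan(panel, n_families=n_families,
                                sibs_per_family=4, seed=_sub(seed, 2))
    geno, ped = simdata.simulate_breeding_population(panel, plan, seed=_sub(seed, 3))
    return geno, ped


# ---------------------------------------------------------------------------
# NOIA orthogonality


def orthogonality_residuals(seed: int, n_populations: int = 100) -> dict:
    """Max NOIA identity residual over random (non-HWE) populations."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_populations):
        g = random_population(rng, int(rng.integers(20, 200)), 40)
        d = noia_coding(g)
        ok = ~d.degenerate
        res = max(
            np.abs(d.Wa[:, ok].sum(axis=0)).max(initial=0.0),
            np.abs(d.Wd[:, ok].sum(axis=0)).max(initial=0.0),
            np.abs((d.Wa[:, ok] * d.Wd[:, ok]).sum(axis=0)).max(initial=0.0),
        )
        worst = max(worst, res)
    return {"max_residual": float(worst), "n": n_populations}


# ---------------------------------------------------------------------------
# Conjugate oracle


def conjugate_brr_check(seed: int, n: int = 50, L: int = 20) -> dict:
    """BRR with fixed variances vs the closed-form ridge posterior mean.

    Returns the largest deviation in units of the MCMC standard error
    (batch means, 25 batches) and in absolute value.
    """
    rng = np.random.default_rng(seed)
    g = random_population(rng, n, L)
    design = noia_coding(g)
    beta = rng.normal(0, 0.3, L)
    y = design.Wa @ beta + rng.normal(0, 0.5, n)
    s2a, s2e = 0.09, 0.25
    spec = ModelSpec(model="A", prior="BRR", n_iter=21_000, burn_in=1000, thin=1,
                     seed=_sub(seed, 5), fix_sigma2_e=s2e, fix_sigma2_marker=s2a)
    samples = fit_model(spec, y, design=design)
    mu_bar = samples.mu.mean()
    lam = s2e / s2a
    ridge = np.linalg.solve(
        design.Wa.T @ design.Wa + lam * np.eye(L), design.Wa.T @ (y - mu_bar)
    )
    err = np.abs(samples.a.mean(axis=0) - ridge)
    n_batches = 25
    batches = np.array_split(samples.a, n_batches, axis=0)
    bm = np.stack([b.mean(axis=0) for b in batches])
    se = bm.std(axis=0, ddof=1) / np.sqrt(n_batches)
    informative = se > 0  # monomorphic loci carry a fixed zero effect
    return {
        "max_se_ratio": float((err[informative] / se[informative]).max()),
        "max_abs_error": float(err.max()),
        "n": n,
    }


# ---------------------------------------------------------------------------
# Parameter recovery


def additive_recovery(seed: int, n_iter: int = 6000) -> dict:
    """ADE-BayesB fit of a purely additive trait (n=500, L=300, H2=0.6)."""
    geno, _ = _population(seed, n_families=125, n_chrom=10, markers_per_chrom=30)
    design = noia_coding(geno)
    kernels = build_kernels(geno, with_gk=False)
    arch = simdata.simulate_trait_architecture(
        geno, n_qtl=50, dominance_degree=0.0, target_h2=0.6, seed=_sub(seed, 4)
    )
    vals = simdata.genotypic_values(geno, arch)
    g = vals["g_total"].to_numpy()
    rng = np.random.default_rng(_sub(seed, 5))
    y = g + rng.normal(0, np.sqrt(np.var(g) * (1 - 0.6) / 0.6), len(g))
    spec = ModelSpec(model="ADE", prior="BayesB", n_iter=n_iter,
                     burn_in=n_iter // 2, thin=3, seed=_sub(seed, 6))
    samples = fit_model(spec, y, design=design, kernels=kernels)
    vd = variance_components(samples, design)
    shares = vd.shares().mean()
    return {
        "additive_share": float(shares["a"]),
        "dominance_share": float(shares["d"]),
        "h2": float(vd.draws["h2"].mean()),
        "n": geno.n_individuals,
    }


def dominance_recovery(seed: int, n_iter: int = 6000) -> dict:
    """ADE-BayesB fit of a trait with ~30% dominance variance at n=1000."""
    geno, _ = _population(seed, n_families=250, n_chrom=10, markers_per_chrom=30)
    design = noia_coding(geno)
    kernels = build_kernels(geno, with_gk=False)
    arch = simdata.simulate_trait_architecture(
        geno, n_qtl=50, dominance_degree=0.8, target_h2=0.6, seed=_sub(seed, 4)
    )
    arch = simdata.scale_to_variance_shares(geno, arch, {"a": 0.7, "d": 0.3})
    vals = simdata.genotypic_values(geno, arch)
    g = vals["g_total"].to_numpy()
    true_d = float(np.var(vals["g_d"]) / np.var(g))
    rng = np.random.default_rng(_sub(seed, 5))
    y = g + rng.normal(0, np.sqrt(np.var(g) * (1 - 0.6) / 0.6), len(g))
    spec = ModelSpec(model="ADE", prior="BayesB", n_iter=n_iter,
                     burn_in=n_iter // 2, thin=3, seed=_sub(seed, 6))
    samples = fit_model(spec, y, design=design, kernels=kernels)
    vd = variance_components(samples, design)
    shares = vd.shares().mean()
    return {
        "dominance_share": float(shares["d"]),
        "true_dominance_share": true_d,
        "n": geno.n_individuals,
    }


# ---------------------------------------------------------------------------
# WPPA detection


def wppa_detection(seed: int, n_iter: int = 6000) -> dict:
    """Single major QTL (~25% of genetic variance) on a polygenic background.

    ADE-BayesB at n=1000, L=500 over ten 100-Mb chromosomes, 1-Mb windows.
    """
    geno, _ = _population(seed, n_families=250, n_chrom=10, markers_per_chrom=50)
    design = noia_coding(geno)
    kernels = build_kernels(geno, with_gk=False)
    rng = np.random.default_rng(_sub(seed, 4))
    qtl = np.sort(rng.choice(geno.n_markers, 50, replace=False))
    a = rng.normal(0, 1, 50)
    big = int(qtl[len(qtl) // 2])
    g_bg = design.Wa[:, qtl] @ a
    gb = design.Wa[:, big]
    a_big = np.sqrt(0.25 / 0.75 * np.var(g_bg) / np.var(gb))
    g = g_bg + gb * a_big
    y = g + rng.normal(0, np.sqrt(np.var(g) * (1 - 0.6) / 0.6), len(g))
    spec = ModelSpec(model="ADE", prior="BayesB", n_iter=n_iter,
                     burn_in=n_iter // 2, thin=3, seed=_sub(seed, 6))
    samples = fit_model(spec, y, design=design, kernels=kernels)
    windows = make_windows(geno.chrom, geno.pos)
    zeta = regional_variance(samples, design, windows, "additive")
    w = wppa(zeta)
    iq = next(
        i for i, win in enumerate(windows)
        if win.chrom == geno.chrom[big] and win.start <= geno.pos[big] <= win.end
    )
    background = np.delete(w, iq)
    return {
        "qtl_window_wppa": float(w[iq]),
        "background_median_wppa": float(np.median(background)),
        "qtl_variance_share": float(np.var(gb * a_big) / np.var(g)),
        "n": geno.n_individuals,
    }


# ---------------------------------------------------------------------------
# Cross-validated prediction


def cv_model_ordering(seed: int, n_reps: int = 20, n_iter: int = 2000) -> dict:
    """Fivefold CV of A vs ADE on a non-additive and a purely additive trait.

    n=500, L=150, H2=0.5; the non-additive trait carries ~half its genetic
    variance in dominance + first-order epistasis.
    """
    geno, _ = _population(seed, n_families=125, n_chrom=5, markers_per_chrom=30)
    design = noia_coding(geno)
    kernels = build_kernels(geno, with_gk=False)
    specs = [
        ModelSpec(model="A", prior="BRR", n_iter=n_iter, burn_in=n_iter // 2, thin=2),
        ModelSpec(model="ADE", prior="BRR", n_iter=n_iter, burn_in=n_iter // 2, thin=2),
    ]
    rng = np.random.default_rng(_sub(seed, 4))

    arch = simdata.simulate_trait_architecture(
        geno, n_qtl=40, dominance_degree=0.8,
        n_epi_pairs={"aa": 10, "ad": 10, "dd": 10}, epi_scale=1.0,
        target_h2=0.5, seed=_sub(seed, 5),
    )
    arch = simdata.scale_to_variance_shares(
        geno, arch, {"a": 0.45, "d": 0.3, "epi": 0.25}
    )
    vals = simdata.genotypic_values(geno, arch)
    g = vals["g_total"].to_numpy()
    nonadd_share = float(1 - np.var(vals["g_a"]) / np.var(g))
    y = g + rng.normal(0, np.sqrt(np.var(g)), len(g))
    res_na = crossvalidate(y, specs, design=design, kernels=kernels,
                           n_reps=n_reps, seed=_sub(seed, 6))
    mean_z_na = res_na.mean_z()

    arch2 = simdata.simulate_trait_architecture(
        geno, n_qtl=40, dominance_degree=0.0, target_h2=0.5, seed=_sub(seed, 7)
    )
    vals2 = simdata.genotypic_values(geno, arch2)
    g2 = vals2["g_total"].to_numpy()
    y2 = g2 + rng.normal(0, np.sqrt(np.var(g2)), len(g2))
    res_add = crossvalidate(y2, specs, design=design, kernels=kernels,
                            n_reps=n_reps, seed=_sub(seed, 8))
    letters = compare_models(res_add, alpha=0.01)
    return {
        "nonadditive_share": nonadd_share,
        "mean_z_a_nonadditive": float(mean_z_na["A-BRR"]),
        "mean_z_ade_nonadditive": float(mean_z_na["ADE-BRR"]),
        "additive_trait_shared_letter": float(letters.letters.nunique() == 1),
        "n": geno.n_individuals,
    }


# ---------------------------------------------------------------------------
# Simulator calibration


def simulator_heterozygosity_band(seed: int, n_runs: int = 20,
                                  band=(0.20, 0.40)) -> dict:
    """Count runs of the default plan with every group mean inside the band."""
    from .markers import heterozygosity_by_group

    in_band = 0
    for k in range(n_runs):
        panel = simdata.simulate_founders(seed=_sub(seed, 10 + 3 * k))
        plan = simdata.default_plan(panel, seed=_sub(seed, 11 + 3 * k))
        geno, _ = simdata.simulate_breeding_population(
            panel, plan, seed=_sub(seed, 12 + 3 * k)
        )
        het = heterozygosity_by_group(geno)
        in_band += bool(het.min() >= band[0] and het.max() <= band[1])
    return {"runs_in_band": int(in_band), "n": n_runs}


# ---------------------------------------------------------------------------
# Kernel normalization


def kernel_normalization(seed: int) -> dict:
    """Trace errors of all relationship matrices and the GK diagonal."""
    geno, _ = _population(seed, n_families=40, n_chrom=4, markers_per_chrom=30)
    ks = build_kernels(geno, with_gk=True)
    n = geno.n_individuals
    errs = [abs(np.trace(getattr(ks, m)) - n)
            for m in ("A", "D", "Vaa", "Vad", "Vdd")]
    return {
        "max_trace_error": float(max(errs)),
        "gk_diag_max_deviation": float(np.abs(np.diag(ks.K) - 1.0).max()),
        "n": n,
    }


# ---------------------------------------------------------------------------
# Adjustment-model oracle


def adjustment_oracle(seed: int) -> dict:
    """Mixed-model adjusted values vs a brute-force GLS/BLUP solve.

    A 10-observation toy: 2 checks replicated across 2 blocks plus 6
    unreplicated candidates; both solutions use the REML variance
    components, so the comparison isolates the solver.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for c in ("c1", "c2"):
        base = rng.normal(0, 1)
        for b, be in (("B1", 0.4), ("B2", -0.4)):
            rows.append((c, b, "t", 10 + base + be + rng.normal(0, 0.5), True))
    for i in range(6):
        b = "B1" if i % 2 == 0 else "B2"
        be = 0.4 if b == "B1" else -0.4
        rows.append((f"g{i}", b, "t",
                     10 + rng.normal(0, 1) + be + rng.normal(0, 0.5), False))
    df = pd.DataFrame(rows, columns=["genotype_id", "block", "trait", "value",
                                     "is_check"])
    fit = adjust_single_trait(df)

    gid = df.genotype_id.to_numpy()
    blocks = df.block.to_numpy()
    is_check = df.is_check.to_numpy()
    yv = df.value.to_numpy()
    checks = ["c1", "c2"]
    cands = [f"g{i}" for i in range(6)]
    X = np.column_stack([np.ones(len(df))]
                        + [(gid == c).astype(float) for c in checks])
    Zg = np.column_stack([(gid == c).astype(float) for c in cands])
    Zg[is_check] = 0.0
    Zb = np.column_stack([(blocks == b).astype(float) for b in ("B1", "B2")])
    V = (fit.sigma2_g * Zg @ Zg.T + fit.sigma2_b * Zb @ Zb.T
         + fit.sigma2_e * np.eye(len(df)))
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ yv)
    u = fit.sigma2_g * Zg.T @ Vi @ (yv - X @ beta)
    ref = {c: beta[0] + beta[1 + j] for j, c in enumerate(checks)}
    ref.update({c: beta[0] + u[j] for j, c in enumerate(cands)})
    err = max(abs(fit.adjusted[k] - v) for k, v in ref.items())
    return {"max_abs_error": float(err), "n": len(df)}
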