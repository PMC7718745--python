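"""Synthetic breeding populations with known genetic architecture.

Emulates a three-generation intercross design for a hybrid-sorghum style
program: a handful of fully inbred founders are intercrossed to F1 hybrids,
F1s are intercrossed into segregating second-generation families, and sibs
from different families are intercrossed again into a large set of non-inbred
(S0) full-sib families. Meiosis uses the Haldane model (no interference):
crossover counts are Poisson with mean equal to the chromosome length in
Morgans and crossover positions are uniform on the genetic map.

Traits are built on the same NOIA additive/dominance codings the analysis
models use, so the simulated truth decomposes exactly into the components the
fitted models estimate. Ground truth (per-individual component values,
pedigree, realized heritability) is recorded for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import GenotypeMatrix


class PlanError(ValueError):
    """A breeding plan references unknown parents or is malformed."""


# ---------------------------------------------------------------------------
# Founders


@dataclass
class FounderPanel:
    """Fully homozygous founder lines over a shared marker map.

    ``haplotypes`` has shape ``(n_founders, 2, L)`` with identical haplotype
    pairs (founders are inbred). The map carries both the physical position
    (bp, 1-based) and the genetic position (cM); the default map uses the
    1 cM = 1 Mb equivalence.
    """

    haplotypes: np.ndarray
    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n_founders, 2, L)")
        if not np.array_equal(self.haplotypes[:, 0], self.haplotypes[:, 1]):
            raise ValueError("founders must be homozygous at every locus")
        for c in pd.unique(np.asarray(self.chrom)):
            sel = np.asarray(self.chrom) == c
            if np.any(np.diff(np.asarray(self.pos)[sel]) <= 0):
                raise ValueError(f"positions not strictly increasing on {c!r}")

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]


def simulate_founders(
    n_founders: int = 13,
    n_chrom: int = 10,
    chrom_length_cm: float = 100.0,
    markers_per_chrom: int = 50,
    freq_range: tuple[float, float] = (0.1, 0.9),
    seed: int | None = None,
) -> FounderPanel:
    """Draw inbred founders at markers placed uniformly along each chromosome.

    Per-marker alternate-allele frequencies are drawn from
    ``Uniform(freq_range)`` and each founder is homozygous for the alternate
    allele with that probability, independently across loci and founders.
    """
    if n_founders < 2:
        raise ValueError(f"need at least 2 founders, got {n_founders}")
    if n_chrom < 1 or markers_per_chrom < 2:
        raise ValueError("need >= 1 chromosome with >= 2 markers each")
    rng = np.random.default_rng(seed)
    chroms, pos, cm = [], [], []
    for c in range(n_chrom):
        cm_pos = np.sort(rng.uniform(0.0, chrom_length_cm, size=markers_per_chrom))
        bp = np.unique(np.round(cm_pos * 1e6).astype(np.int64) + 1)
        while len(bp) < markers_per_chrom:  # collision-free physical positions
            extra = rng.integers(1, int(chrom_length_cm * 1e6), size=markers_per_chrom)
            bp = np.unique(np.concatenate([bp, extra]))[:markers_per_chrom]
        cm_pos = (bp - 1) / 1e6
        chroms.extend([f"chr{c + 1:02d}"] * markers_per_chrom)
        pos.extend(bp.tolist())
        cm.extend(cm_pos.tolist())
    L = n_chrom * markers_per_chrom
    freqs = rng.uniform(freq_range[0], freq_range[1], size=L)
    alleles = (rng.random((n_founders, L)) < freqs).astype(np.int8)
    haplotypes = np.repeat(alleles[:, None, :], 2, axis=1)
    ids = np.array([f"F{i + 1:02d}" for i in range(n_founders)])
    return FounderPanel(haplotypes, ids, np.array(chroms), np.array(pos), np.array(cm))


# ---------------------------------------------------------------------------
# Breeding plan


@dataclass
class Cross:
    mother: str
    father: str
    n_offspring: int
    family: str
    group: str | None = None

    @property
    def is_selfing(self) -> bool:
        return self.mother == self.father


@dataclass
class BreedingPlan:
    """Ordered generations of crosses; parents must exist upstream."""

    generations: list[list[Cross]]

    def validate(self, panel: FounderPanel) -> None:
        known = set(map(str, panel.ids))
        for g, crosses in enumerate(self.generations):
            new: set[str] = set()
            for cr in crosses:
                if cr.n_offspring < 1:
                    raise PlanError(f"cross {cr.family}: n_offspring < 1")
                for parent in (cr.mother, cr.father):
                    if parent not in known:
                        raise PlanError(
                            f"generation {g + 1}: unknown parent {parent!r}"
                        )
                new.update(offspring_ids(cr))
            known |= new


def offspring_ids(cross: Cross) -> list[str]:
    return [f"{cross.family}_{k + 1}" for k in range(cross.n_offspring)]


def default_plan(
    panel: FounderPanel,
    n_f1: int = 9,
    n_gen2_families: int = 5,
    gen2_sibs: int = 8,
    n_families: int = 60,
    sibs_per_family: int = 4,
    seed: int | None = None,
) -> BreedingPlan:
    """Scaled-down three-generation intercross plan.

    Mirrors the topology of the emulated hybrid program at roughly quarter
    scale: founder pairs -> F1 hybrids; F1 pairs -> segregating
    2nd-generation families; sibs from two different 2nd-generation families
    -> S0 full-sib families. As in the real program, where candidates were
    only intercrossed with material selected on the same male-sterile
    tester, crossing is confined to two subpopulations drawn from partially
    overlapping founder pools (~1/3 and ~2/3 of the founders, one founder
    shared); the minority subpopulation contributes ~20% of S0 families.
    This concentration of ancestry is what keeps S0 marker heterozygosity in
    the observed 20-40% range rather than at the unrelated-parent
    expectation. S0 families sharing the same pair of 2nd-generation parent
    families form a group (the analogue of ancestry-defined breeding
    groups).
    """
    rng = np.random.default_rng(seed)
    founders = list(map(str, panel.ids))
    nf = len(founders)
    # two tester-specific founder pools sharing one founder
    n_pool_a = max(2, nf // 3)
    perm = rng.permutation(nf)
    pool_a = [founders[i] for i in perm[:n_pool_a]]
    pool_b = [founders[i] for i in perm[n_pool_a - 1:]]  # one shared founder
    n_f1_a = max(2, round(n_f1 / 3))
    n_f1_b = max(2, n_f1 - n_f1_a)
    n_g2_a = max(1, round(n_gen2_families / 3))
    n_g2_b = max(2, n_gen2_families - n_g2_a)
    n_fam_a = max(1, round(0.2 * n_families))

    gen1: list[Cross] = []
    f1_pool: dict[str, list[str]] = {"A": [], "B": []}
    for pool_name, pool, count in (("A", pool_a, n_f1_a), ("B", pool_b, n_f1_b)):
        for _ in range(count):
            m, f = rng.choice(len(pool), size=2, replace=False)
            cr = Cross(pool[m], pool[f], 1, f"F1H{len(gen1) + 1:02d}")
            gen1.append(cr)
            f1_pool[pool_name].append(offspring_ids(cr)[0])

    # 2nd-generation crosses cycle over a small selected subset of each
    # pool's F1s (cross i uses F1s i and i+1 mod k), so every pair of
    # families within a pool shares an F1 parent — the analogue of
    # repeatedly reusing the few best-performing hybrids; surplus F1s are
    # discarded as unselected
    gen2: list[Cross] = []
    g2_pool: dict[str, list[int]] = {"A": [], "B": []}
    for pool_name, count in (("A", n_g2_a), ("B", n_g2_b)):
        f1s = f1_pool[pool_name]
        k = min(len(f1s), count if count >= 3 else count + 1)
        for i in range(count):
            if k >= 2:
                parents = (f1s[i % k], f1s[(i + 1) % k])
            else:  # degenerate scale: self the lone F1
                parents = (f1s[0], f1s[0])
            g2_pool[pool_name].append(len(gen2))
            gen2.append(
                Cross(parents[0], parents[1], gen2_sibs, f"G2F{len(gen2) + 1:02d}")
            )

    gen3: list[Cross] = []
    group_of_pair: dict[tuple[int, int], str] = {}
    for i in range(n_families):
        pool_name = "A" if i < n_fam_a else "B"
        fams = g2_pool[pool_name]
        if len(fams) >= 2:
            a, b = rng.choice(len(fams), size=2, replace=False)
            fam_a, fam_b = sorted((fams[a], fams[b]))
        else:
            fam_a = fam_b = fams[0]
        pair = (int(fam_a), int(fam_b))
        if pair not in group_of_pair:
            group_of_pair[pair] = f"G{len(group_of_pair) + 1:02d}"
        mother = str(rng.choice(offspring_ids(gen2[fam_a])))
        father = str(rng.choice(offspring_ids(gen2[fam_b])))
        while father == mother:
            father = str(rng.choice(offspring_ids(gen2[fam_b])))
        gen3.append(
            Cross(mother, father, sibs_per_family, f"S0F{i + 1:03d}", group_of_pair[pair])
        )
    return BreedingPlan([gen1, gen2, gen3])


# ---------------------------------------------------------------------------
# Meiosis


def _chromosome_slices(chrom: np.ndarray) -> list[tuple[int, int]]:
    out = []
    start = 0
    for i in range(1, len(chrom) + 1):
        if i == len(chrom) or chrom[i] != chrom[start]:
            out.append((start, i))
            start = i
    return out


def _gamete(
    hap: np.ndarray,
    slices: list[tuple[int, int]],
    cm: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete under the Haldane model."""
    out = np.empty(hap.shape[1], dtype=np.int8)
    for s, e in slices:
        seg_cm = cm[s:e]
        length_m = (seg_cm[-1] - seg_cm[0]) / 100.0
        n_co = rng.poisson(length_m)
        phase0 = rng.integers(0, 2)
        if n_co == 0:
            out[s:e] = hap[phase0, s:e]
            continue
        co = np.sort(rng.uniform(seg_cm[0], seg_cm[-1], size=n_co))
        phase = (phase0 + np.searchsorted(co, seg_cm, side="right")) % 2
        out[s:e] = hap[phase, np.arange(s, e)]
    return out


def simulate_breeding_population(
    panel: FounderPanel,
    plan: BreedingPlan,
    seed: int | None = None,
    return_haplotypes: bool = False,
):
    """Run the plan through meiosis; genotype the final generation.

    Returns ``(GenotypeMatrix, pedigree)`` where the pedigree is a DataFrame
    over every simulated individual (id, sire, dam, generation, family,
    group). With ``return_haplotypes=True`` a dict ``id -> (2, L)`` haplotype
    array is appended, which lets tests assert Mendelian consistency
    locus-by-locus.
    """
    plan.validate(panel)
    rng = np.random.default_rng(seed)
    slices = _chromosome_slices(panel.chrom)
    cm = np.asarray(panel.cm, dtype=float)

    haps: dict[str, np.ndarray] = {
        str(panel.ids[i]): panel.haplotypes[i] for i in range(panel.n_founders)
    }
    rows = [
        {"id": str(i), "sire": None, "dam": None, "generation": 0, "family": None,
         "group": None}
        for i in panel.ids
    ]
    last_ids: list[str] = []
    last_groups: list[str] = []
    for g, crosses in enumerate(plan.generations, start=1):
        final = g == len(plan.generations)
        for cr in crosses:
            hm, hf = haps[cr.mother], haps[cr.father]
            for oid in offspring_ids(cr):
                child = np.stack(
                    [_gamete(hm, slices, cm, rng), _gamete(hf, slices, cm, rng)]
                )
                haps[oid] = child
                rows.append(
                    {"id": oid, "sire": cr.father, "dam": cr.mother,
                     "generation": g, "family": cr.family, "group": cr.group}
                )
                if final:
                    last_ids.append(oid)
                    last_groups.append(cr.group if cr.group else cr.family)
    pedigree = pd.DataFrame(rows)
    codes = np.stack([haps[i].sum(axis=0) for i in last_ids]).astype(np.int8)
    gm = GenotypeMatrix(
        codes, panel.chrom.copy(), panel.pos.copy(), np.array(last_ids),
        groups=np.array(last_groups),
    )
    if return_haplotypes:
        return gm, pedigree, haps
    return gm, pedigree


# ---------------------------------------------------------------------------
# Trait architecture


@dataclass
class TraitArchitecture:
    """QTL positions and effects on the NOIA coding scale.

    ``epi_pairs`` rows are ``(z, w, kind, effect)`` with kind in
    {"aa", "ad", "dd"}; the phenotypic contribution of a pair is
    ``effect * coef_z * coef_w`` with the additive (Wa) or dominance (Wd)
    NOIA coefficient at each locus, so simulated truth and the fitted
    additive-dominance-epistasis model share one definition of each term.
    """

    qtl_indices: np.ndarray
    a_effects: np.ndarray
    d_effects: np.ndarray
    epi_pairs: list[tuple[int, int, str, float]] = field(default_factory=list)
    target_h2: float = 0.5
    block_sd: float = 0.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_h2 < 1.0:
            raise ValueError(f"target_h2 must be in [0, 1), got {self.target_h2}")


def simulate_trait_architecture(
    genotypes: GenotypeMatrix,
    n_qtl: int,
    seed: int | None = None,
    additive_law: str = "normal",
    additive_scale: float = 1.0,
    dominance_degree: float = 0.0,
    n_epi_pairs: dict[str, int] | None = None,
    epi_scale: float = 1.0,
    target_h2: float = 0.5,
    block_sd: float = 0.0,
    mu: float = 0.0,
) -> TraitArchitecture:
    """Sample a trait architecture on the marker panel.

    Additive effects are i.i.d. from the chosen law (``normal`` or
    ``laplace`` for sparse, heavy-tailed architectures) scaled to standard
    deviation ``additive_scale``; dominance effects are
    ``dominance_degree * |a|``; epistatic pairs are sampled without
    replacement among the QTL.
    """
    poly = np.where(
        [len(np.unique(genotypes.codes[:, z][genotypes.codes[:, z] >= 0])) > 1
         for z in range(genotypes.n_markers)]
    )[0]
    if n_qtl > len(poly):
        raise ValueError(
            f"requested {n_qtl} QTL but only {len(poly)} polymorphic markers"
        )
    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(poly, size=n_qtl, replace=False))
    if additive_law == "normal":
        a = rng.normal(0.0, additive_scale, size=n_qtl)
    elif additive_law == "laplace":
        a = rng.laplace(0.0, additive_scale / np.sqrt(2.0), size=n_qtl)
    else:
        raise ValueError(f"unknown additive_law {additive_law!r}")
    d = dominance_degree * np.abs(a)

    epi_pairs: list[tuple[int, int, str, float]] = []
    if n_epi_pairs:
        all_pairs = [(int(qtl[i]), int(qtl[j]))
                     for i in range(n_qtl) for j in range(i + 1, n_qtl)]
        for kind, count in n_epi_pairs.items():
            if kind not in ("aa", "ad", "dd"):
                raise ValueError(f"unknown epistasis kind {kind!r}")
            if count > len(all_pairs):
                raise ValueError("more epistatic pairs requested than available")
            chosen = rng.choice(len(all_pairs), size=count, replace=False)
            for c in chosen:
                z, w = all_pairs[c]
                epi_pairs.append((z, w, kind, float(rng.normal(0.0, epi_scale))))
    return TraitArchitecture(
        qtl_indices=qtl, a_effects=a, d_effects=d, epi_pairs=epi_pairs,
        target_h2=target_h2, block_sd=block_sd, mu=mu,
    )


def genotypic_values(
    genotypes: GenotypeMatrix, arch: TraitArchitecture
) -> pd.DataFrame:
    """True per-individual genetic values, split by component.

    Uses the NOIA coding of the realized population, so the additive /
    dominance / epistatic split is exactly the one the analysis models
    estimate. Returns columns g_a, g_d, g_aa, g_ad, g_dd, g_total.
    """
    from .noia import noia_coding

    design = noia_coding(genotypes)
    qtl = arch.qtl_indices
    g_a = design.Wa[:, qtl] @ arch.a_effects
    g_d = design.Wd[:, qtl] @ arch.d_effects
    n = genotypes.n_individuals
    g_epi = {"aa": np.zeros(n), "ad": np.zeros(n), "dd": np.zeros(n)}
    for z, w, kind, eff in arch.epi_pairs:
        if kind == "aa":
            coef = design.Wa[:, z] * design.Wa[:, w]
        elif kind == "ad":
            coef = design.Wa[:, z] * design.Wd[:, w]
        else:
            coef = design.Wd[:, z] * design.Wd[:, w]
        g_epi[kind] = g_epi[kind] + eff * coef
    out = pd.DataFrame(
        {
            "id": genotypes.ids,
            "g_a": g_a,
            "g_d": g_d,
            "g_aa": g_epi["aa"],
            "g_ad": g_epi["ad"],
            "g_dd": g_epi["dd"],
        }
    )
    out["g_total"] = out[["g_a", "g_d", "g_aa", "g_ad", "g_dd"]].sum(axis=1)
    return out


def scale_to_variance_shares(
    genotypes: GenotypeMatrix,
    arch: TraitArchitecture,
    shares: dict[str, float],
) -> TraitArchitecture:
    """Rescale effect blocks so realized component variances hit given shares.

    ``shares`` maps component names (``a``, ``d``, ``epi``) to the desired
    proportions of total genetic variance; components are rescaled on the
    realized population (population variance of each true component value).
    Useful for constructing study conditions like "30% dominance variance".
    """
    vals = genotypic_values(genotypes, arch)
    var_a = float(np.var(vals["g_a"]))
    var_d = float(np.var(vals["g_d"]))
    var_e = float(np.var(vals[["g_aa", "g_ad", "g_dd"]].sum(axis=1)))
    total = sum(shares.values())
    sf = {}
    for key, var in (("a", var_a), ("d", var_d), ("epi", var_e)):
        want = shares.get(key, 0.0) / total
        if want > 0 and var <= 0:
            raise ValueError(f"component {key!r} has zero realized variance")
        sf[key] = np.sqrt(want / var) if var > 0 else 0.0
    new_pairs = [
        (z, w, kind, eff * sf["epi"]) for (z, w, kind, eff) in arch.epi_pairs
    ]
    return TraitArchitecture(
        qtl_indices=arch.qtl_indices,
        a_effects=arch.a_effects * sf["a"],
        d_effects=arch.d_effects * sf["d"],
        epi_pairs=new_pairs,
        target_h2=arch.target_h2,
        block_sd=arch.block_sd,
        mu=arch.mu,
    )


# ---------------------------------------------------------------------------
# Field trial


@dataclass
class SimTruth:
    """Ground truth from one simulated field trial."""

    values: pd.DataFrame  # id, g_a, g_d, g_aa, g_ad, g_dd, g_total
    pedigree: pd.DataFrame | None
    realized_h2: float
    residual_sd: float


def simulate_field_trial(
    genotypes: GenotypeMatrix,
    arch: TraitArchitecture,
    n_blocks: int = 2,
    n_checks: int = 5,
    trait: str = "trait",
    seed: int | None = None,
    pedigree: pd.DataFrame | None = None,
    residual_sd: float | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Phenotype an unreplicated-candidates + replicated-checks trial.

    Candidates (the genotyped population) each appear once, in a random
    block; ``n_checks`` check genotypes appear in every block. Check genetic
    values are drawn from the candidate genetic-value distribution (checks
    stand in for ancestral accessions and are excluded from genomic
    analysis). The residual SD is set from ``arch.target_h2`` against the
    realized genetic variance: sigma_e^2 = var(g) * (1 - H2) / H2. An explicit
    ``residual_sd`` (e.g. 0 for a noise-free trial) overrides the derivation.
    """
    if n_blocks < 1:
        raise ValueError("need at least one block")
    rng = np.random.default_rng(seed)
    vals = genotypic_values(genotypes, arch)
    g = vals["g_total"].to_numpy()
    var_g = float(np.var(g))
    h2 = arch.target_h2
    if residual_sd is not None:
        if residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        residual_sd = float(residual_sd)
    elif h2 == 0.0:
        residual_sd = 1.0 if var_g == 0 else float(np.sqrt(var_g))
    else:
        residual_sd = float(np.sqrt(var_g * (1.0 - h2) / h2))
    block_effects = rng.normal(0.0, arch.block_sd, size=n_blocks)

    recs = []
    blocks = rng.integers(0, n_blocks, size=genotypes.n_individuals)
    e = rng.normal(0.0, residual_sd, size=genotypes.n_individuals)
    for i, gid in enumerate(genotypes.ids):
        recs.append(
            {
                "genotype_id": str(gid),
                "block": f"B{blocks[i] + 1}",
                "trait": trait,
                "value": arch.mu + g[i] + block_effects[blocks[i]] + e[i],
                "is_check": False,
            }
        )
    g_sd = np.std(g) if var_g > 0 else 1.0
    check_g = rng.normal(0.0, g_sd, size=n_checks)
    for c in range(n_checks):
        for b in range(n_blocks):
            recs.append(
                {
                    "genotype_id": f"CHK{c + 1:02d}",
                    "block": f"B{b + 1}",
                    "trait": trait,
                    "value": arch.mu + check_g[c] + block_effects[b]
                    + rng.normal(0.0, residual_sd),
                    "is_check": True,
                }
            )
    pheno = pd.DataFrame(recs)
    var_y = var_g + residual_sd**2
    truth = SimTruth(
        values=vals,
        pedigree=pedigree,
        realized_h2=var_g / var_y if var_y > 0 else 0.0,
        residual_sd=residual_sd,
    )
    return pheno, truth
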