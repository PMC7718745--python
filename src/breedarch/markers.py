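"""Diploid genotype matrices: I/O, QC filtering, LD pruning, PCA, heterozygosity.

Genotypes are stored as counts of the alternate allele (0, 1, 2) with -1 for
missing calls, alongside a physical marker map (chromosome, 1-based bp
position). This is the substrate every downstream step (NOIA coding, kernels,
GWAS windows) operates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x markers alternate-allele counts plus a marker map.

    Parameters
    ----------
    codes
        ``(n_individuals, n_markers)`` int8 array with entries in
        ``{0, 1, 2}`` and ``-1`` for missing.
    chrom
        Chromosome label per marker.
    pos
        1-based bp position per marker, non-decreasing within chromosome.
    ids
        Individual labels.
    groups
        Optional group label per individual (e.g. breeding group).
    """

    codes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ids: np.ndarray
    groups: np.ndarray | None = None
    marker_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ids = np.asarray(self.ids)
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
        if self.marker_ids is None:
            self.marker_ids = np.array(
                [f"{c}_{p}" for c, p in zip(self.chrom, self.pos)]
            )
        else:
            self.marker_ids = np.asarray(self.marker_ids)
        n, L = self.codes.shape
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} genotype rows")
        if not (len(self.chrom) == len(self.pos) == L):
            raise ValueError("marker map length does not match genotype columns")
        if self.groups is not None and len(self.groups) != n:
            raise ValueError("group labels do not match individual count")
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError(
                f"genotype codes outside {{0,1,2,missing}}: "
                f"found {np.unique(self.codes[bad])}"
            )
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions decrease within chromosome {c!r}")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given marker indices (order preserved)."""
        return replace(
            self,
            codes=self.codes[:, index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            marker_ids=self.marker_ids[index],
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            codes=self.codes[index],
            ids=self.ids[index],
            groups=None if self.groups is None else self.groups[index],
        )

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker over non-missing calls."""
        c = np.ma.masked_equal(self.codes, MISSING)
        return np.asarray(c.mean(axis=0).filled(np.nan)) / 2.0

    def missing_rate(self) -> np.ndarray:
        return (self.codes == MISSING).mean(axis=0)

    def het_rate(self) -> np.ndarray:
        """Per-marker heterozygote fraction among non-missing calls."""
        obs = self.codes != MISSING
        denom = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, (self.codes == 1).sum(axis=0) / denom, np.nan)

    def imputed(self) -> np.ndarray:
        """Float codes with missing cells filled by the per-marker mean."""
        x = self.codes.astype(np.float64)
        x[self.codes == MISSING] = np.nan
        mu = np.nanmean(x, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        idx = np.where(np.isnan(x))
        x[idx] = mu[idx[1]]
        return x


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`filter_markers`."""

    n_input: int
    n_retained: int
    removed_maf: int
    removed_missing: int
    removed_het: int
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed_maf": self.removed_maf,
            "removed_missing": self.removed_missing,
            "removed_het": self.removed_het,
            "thresholds": self.thresholds,
        }


# ---------------------------------------------------------------------------
# I/O


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF or a TSV genotype matrix.

    Only bi-allelic SNP records are kept from VCF input; indels and
    multi-allelic sites are skipped with a logged count.
    """
    path = Path(path)
    if fmt is None:
        name = path.name.lower()
        fmt = "vcf" if (".vcf" in name) else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = rec.gt_types
        col = np.full(len(ids), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        rows.append(col)
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-bi-allelic-SNP records in %s", n_skipped, path)
    if not rows:
        raise ValueError(f"no bi-allelic SNP records in {path}")
    codes = np.column_stack(rows)
    return GenotypeMatrix(codes, np.array(chroms), np.array(positions), ids)


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"marker", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"TSV genotype matrix must have columns {sorted(required)}")
    sample_cols = [c for c in df.columns if c not in required]
    codes = df[sample_cols].to_numpy(dtype=float).T
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    return GenotypeMatrix(
        codes,
        df["chrom"].to_numpy(),
        df["pos"].to_numpy(),
        np.array(sample_cols),
        marker_ids=df["marker"].to_numpy(),
    )


def write_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Markers-as-rows TSV: marker, chrom, pos, one column per individual."""
    codes = g.codes.astype(float)
    codes[g.codes == MISSING] = np.nan
    df = pd.concat(
        [
            pd.DataFrame({"marker": g.marker_ids, "chrom": g.chrom, "pos": g.pos}),
            pd.DataFrame(codes.T, columns=[str(s) for s in g.ids]),
        ],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.0f")


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as a minimal VCF 4.2 with unphased GT calls."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(g.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.ids))
            + "\n"
        )
        for z in range(g.n_markers):
            calls = "\t".join(gt_str[int(c)] for c in g.codes[:, z])
            fh.write(
                f"{g.chrom[z]}\t{g.pos[z]}\t{g.marker_ids[z]}\tA\tT\t.\tPASS\t.\tGT\t"
                + calls
                + "\n"
            )


# ---------------------------------------------------------------------------
# QC


def filter_markers(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.05,
    het_max: float | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove markers failing MAF / missingness / (optional) heterozygosity rules.

    ``het_max`` targets inbred panels where residual heterozygous calls flag
    genotyping artefacts; leave it ``None`` for segregating populations.
    """
    for name, t in (("maf_min", maf_min), ("missing_max", missing_max)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    if het_max is not None and not 0.0 <= het_max <= 1.0:
        raise ValueError(f"het_max must be in [0, 1], got {het_max}")

    p = g.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    fail_maf = ~(maf >= maf_min)  # NaN freq (all-missing) fails too
    fail_missing = g.missing_rate() > missing_max
    if het_max is not None:
        fail_het = g.het_rate() > het_max
    else:
        fail_het = np.zeros(g.n_markers, dtype=bool)

    keep = ~(fail_maf | fail_missing | fail_het)
    report = FilterReport(
        n_input=g.n_markers,
        n_retained=int(keep.sum()),
        removed_maf=int(fail_maf.sum()),
        removed_missing=int(fail_missing.sum()),
        removed_het=int(fail_het.sum()),
        thresholds={
            "maf_min": maf_min,
            "missing_max": missing_max,
            "het_max": het_max,
        },
    )
    if report.n_retained == 0:
        logger.warning("all %d markers removed by QC filters", g.n_markers)
    return g.take_markers(np.where(keep)[0]), report


def ld_prune(g: GenotypeMatrix, r2_max: float = 0.95) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning within chromosomes.

    Scanning markers in map order, a marker is dropped when its squared
    Pearson correlation (on 0/1/2 codes, individuals complete for both
    markers) with any already-retained marker on the same chromosome reaches
    ``r2_max``. Markers on different chromosomes are never compared;
    monomorphic markers (undefined r^2) are retained and logged.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError(f"r2_max must be in (0, 1], got {r2_max}")
    keep = np.zeros(g.n_markers, dtype=bool)
    n_mono = 0
    codes = g.codes
    for c in pd.unique(g.chrom):
        idx = np.where(g.chrom == c)[0]
        retained: list[int] = []
        for z in idx:
            xz = codes[:, z]
            if _is_monomorphic(xz):
                n_mono += 1
                keep[z] = True
                retained.append(z)
                continue
            linked = False
            for w in retained:
                r2 = _pairwise_r2(xz, codes[:, w])
                if r2 is not None and r2 >= r2_max:
                    linked = True
                    break
            if not linked:
                keep[z] = True
                retained.append(z)
    if n_mono:
        logger.info("ld_prune: %d monomorphic markers retained as unlinked", n_mono)
    return g.take_markers(np.where(keep)[0])


def _is_monomorphic(x: np.ndarray) -> bool:
    obs = x[x != MISSING]
    return obs.size == 0 or np.all(obs == obs[0])


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return None
    xo = x[ok].astype(float)
    yo = y[ok].astype(float)
    sx = xo.std()
    sy = yo.std()
    if sx == 0.0 or sy == 0.0:
        return None
    r = np.mean((xo - xo.mean()) * (yo - yo.mean())) / (sx * sy)
    return float(r * r)


# ---------------------------------------------------------------------------
# Summaries


def heterozygosity_by_individual(g: GenotypeMatrix) -> np.ndarray:
    """Per individual: fraction of non-missing markers called heterozygous."""
    obs = g.codes != MISSING
    denom = obs.sum(axis=1).astype(float)
    if np.any(denom == 0):
        raise ValueError("individual with no observed genotypes")
    return (g.codes == 1).sum(axis=1) / denom


def heterozygosity_by_group(g: GenotypeMatrix) -> pd.Series:
    """Mean individual heterozygosity per group label."""
    if g.groups is None:
        raise ValueError("GenotypeMatrix has no group labels")
    het = heterozygosity_by_individual(g)
    s = pd.Series(het, index=pd.Index(g.groups, name="group"), name="heterozygosity")
    out = s.groupby(level="group").mean()
    if (s.groupby(level="group").size() == 0).any():
        raise ValueError("group with zero individuals")
    return out


def pca_markers(g: GenotypeMatrix, n_components: int = 10):
    """PCA of the column-centered (mean-imputed) code matrix.

    Returns
    -------
    scores : ndarray (n_individuals, n_components)
    var_explained : ndarray (n_components,)
        Fraction of total variance per component; non-increasing.
    """
    n, L = g.codes.shape
    if n_components > min(n, L):
        raise ValueError(
            f"n_components={n_components} exceeds min(n, L)={min(n, L)}"
        )
    x = g.imputed()
    x -= x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = (s**2).sum()
    var_explained = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    scores = u[:, :n_components] * s[:n_components]
    return scores, var_explained
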