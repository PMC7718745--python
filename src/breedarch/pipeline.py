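"""End-to-end orchestration: simulate -> QC -> adjust -> fit -> summaries.

A single YAML/dict config drives every stage; per-stage seeds are derived
deterministically from the master seed (hash of seed and stage name) so a
rerun with the same config reproduces every stochastic stage exactly. All
intermediate artifacts are files under the run directory and each output is
hashed into ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes, cveval, gwas, markers, noia, pheno, posterior, simdata

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Config failed schema validation; the message names the field."""


_REQUIRED = [
    "seed",
    "mcmc.n_iter",
    "mcmc.burn_in",
    "mcmc.thin",
    "models",
]

_DEFAULTS = {
    "simulation.n_founders": 13,
    "simulation.n_chrom": 10,
    "simulation.chrom_length_cm": 100.0,
    "simulation.markers_per_chrom": 50,
    "simulation.n_f1": 10,
    "simulation.n_gen2_families": 6,
    "simulation.gen2_sibs": 8,
    "simulation.n_families": 60,
    "simulation.sibs_per_family": 4,
    "simulation.n_blocks": 2,
    "simulation.n_checks": 5,
    "simulation.trait.n_qtl": 30,
    "simulation.trait.dominance_degree": 0.0,
    "simulation.trait.target_h2": 0.5,
    "simulation.trait.block_sd": 0.0,
    "qc.maf_min": 0.05,
    "qc.missing_max": 0.05,
    "qc.ld_r2_max": 0.95,
    "gwas.window_size": 1_000_000,
    "gwas.threshold": 0.01,
    "cv.enabled": False,
    "cv.n_folds": 5,
    "cv.n_reps": 5,
}


def _get(cfg: dict, dotted: str, default=KeyError):
    cur = cfg
    for part in dotted.split("."):
        if not isinstance(cur, dict) or part not in cur:
            if default is KeyError:
                raise ConfigError(f"config is missing required field {dotted!r}")
            return default
        cur = cur[part]
    return cur


def validate_config(cfg: dict) -> dict:
    """Check required fields; fill defaults; return a flat accessor dict."""
    for key in _REQUIRED:
        _get(cfg, key)
    flat = {k: _get(cfg, k, v) for k, v in _DEFAULTS.items()}
    flat.update({k: _get(cfg, k) for k in _REQUIRED if k != "models"})
    models = _get(cfg, "models")
    if not isinstance(models, list) or not models:
        raise ConfigError("config field 'models' must be a non-empty list")
    specs = []
    for m in models:
        if "model" not in m:
            raise ConfigError("each entry of 'models' needs a 'model' field")
        specs.append(
            bayes.ModelSpec(
                model=m["model"],
                prior=m.get("prior", "BRR"),
                n_iter=int(flat["mcmc.n_iter"]),
                burn_in=int(flat["mcmc.burn_in"]),
                thin=int(flat["mcmc.thin"]),
            )
        )
    flat["specs"] = specs
    return flat


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed; avoids collisions across stages."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute every configured stage in dependency order.

    Returns the run directory, which contains the stage outputs, a plain
    text log and ``manifest.json`` with a sha256 per output file.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    log_path = out / "run.log"
    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        log_lines.append(f"{stamp} {msg}")
        logger.info(msg)

    outputs: list[Path] = []

    def stage(name):
        def deco(fn):
            log(f"stage {name}: start")
            try:
                fn()
            except Exception as err:
                log(f"stage {name}: FAILED ({err})")
                (out / "run.log").write_text("\n".join(log_lines) + "\n")
                raise RuntimeError(f"stage {name!r} failed: {err}") from err
            log(f"stage {name}: done")

        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        s = cfg
        panel = simdata.simulate_founders(
            n_founders=int(s["simulation.n_founders"]),
            n_chrom=int(s["simulation.n_chrom"]),
            chrom_length_cm=float(s["simulation.chrom_length_cm"]),
            markers_per_chrom=int(s["simulation.markers_per_chrom"]),
            seed=stage_seed(master, "founders"),
        )
        plan = simdata.default_plan(
            panel,
            n_f1=int(s["simulation.n_f1"]),
            n_gen2_families=int(s["simulation.n_gen2_families"]),
            gen2_sibs=int(s["simulation.gen2_sibs"]),
            n_families=int(s["simulation.n_families"]),
            sibs_per_family=int(s["simulation.sibs_per_family"]),
            seed=stage_seed(master, "plan"),
        )
        geno, ped = simdata.simulate_breeding_population(
            panel, plan, seed=stage_seed(master, "meiosis")
        )
        arch = simdata.simulate_trait_architecture(
            geno,
            n_qtl=int(s["simulation.trait.n_qtl"]),
            dominance_degree=float(s["simulation.trait.dominance_degree"]),
            target_h2=float(s["simulation.trait.target_h2"]),
            block_sd=float(s["simulation.trait.block_sd"]),
            seed=stage_seed(master, "architecture"),
        )
        phen, truth = simdata.simulate_field_trial(
            geno, arch,
            n_blocks=int(s["simulation.n_blocks"]),
            n_checks=int(s["simulation.n_checks"]),
            seed=stage_seed(master, "trial"),
            pedigree=ped,
        )
        markers.write_vcf(geno, out / "genotypes.vcf")
        markers.write_tsv(geno, out / "genotypes.tsv")
        phen.to_csv(out / "phenotypes.csv", index=False, float_format="%.8g")
        truth.values.to_csv(out / "sim_truth.csv", index=False, float_format="%.8g")
        ped.to_csv(out / "pedigree.csv", index=False)
        outputs.extend(out / f for f in
                       ["genotypes.vcf", "genotypes.tsv", "phenotypes.csv",
                        "sim_truth.csv", "pedigree.csv"])
        state["geno"], state["pheno"] = geno, phen

    @stage("qc")
    def _qc():
        g, report = markers.filter_markers(
            state["geno"],
            maf_min=float(cfg["qc.maf_min"]),
            missing_max=float(cfg["qc.missing_max"]),
        )
        g = markers.ld_prune(g, r2_max=float(cfg["qc.ld_r2_max"]))
        markers.write_tsv(g, out / "genotypes_qc.tsv")
        (out / "filter_report.json").write_text(
            json.dumps(report.to_dict(), indent=2) + "\n"
        )
        outputs.extend([out / "genotypes_qc.tsv", out / "filter_report.json"])
        state["geno_qc"] = g

    @stage("adjust")
    def _adjust():
        fits = pheno.adjust_phenotypes(state["pheno"])
        rows = []
        for trait, fit in fits.items():
            for gid, val in fit.adjusted.items():
                rows.append({"genotype_id": gid, "trait": trait, "adjusted": val,
                             "is_check": bool(fit.is_check[gid])})
        df = pd.DataFrame(rows)
        df.to_csv(out / "adjusted.csv", index=False, float_format="%.8g")
        outputs.append(out / "adjusted.csv")
        state["adjusted"] = fits

    @stage("fit")
    def _fit():
        g = state["geno_qc"]
        design = noia.noia_coding(g)
        kernels = noia.build_kernels(g)
        trait = next(iter(state["adjusted"]))
        fit = state["adjusted"][trait]
        ids = [str(i) for i in g.ids]
        y = fit.adjusted.reindex(ids).to_numpy()
        state.update(design=design, kernels=kernels, y=y, trait=trait)
        for spec in cfg["specs"]:
            spec.seed = stage_seed(master, f"fit:{spec.label}")
            samples = bayes.fit_model(spec, y, design=design, kernels=kernels)
            path = out / f"fit_{spec.label}.npz"
            samples.save(path)
            outputs.append(path)
            state.setdefault("samples", {})[spec.label] = samples

    @stage("varcomp")
    def _varcomp():
        for label, samples in state["samples"].items():
            vd = posterior.variance_components(samples, state["design"])
            path = out / f"varcomp_{label}.csv"
            vd.summary.to_csv(path, float_format="%.8g")
            outputs.append(path)

    @stage("gwas")
    def _gwas():
        g = state["geno_qc"]
        windows = gwas.make_windows(g.chrom, g.pos,
                                    size=int(cfg["gwas.window_size"]))
        for label, samples in state["samples"].items():
            if samples.a is None:
                continue
            table = gwas.window_associations(
                samples, state["design"], windows,
                threshold=float(cfg["gwas.threshold"]),
            )
            path = out / f"gwas_{label}.tsv"
            table.to_csv(path, sep="\t", index=False, float_format="%.8g")
            outputs.append(path)

    if cfg["cv.enabled"]:
        @stage("cv")
        def _cv():
            res = cveval.crossvalidate(
                state["y"], cfg["specs"], design=state["design"],
                kernels=state["kernels"],
                n_folds=int(cfg["cv.n_folds"]),
                n_reps=int(cfg["cv.n_reps"]),
                seed=stage_seed(master, "cv"),
            )
            res.records.to_csv(out / "cv.csv", index=False, float_format="%.8g")
            outputs.append(out / "cv.csv")
            if res.records["spec"].nunique() >= 2:
                letters = cveval.compare_models(res)
                letters.to_csv(out / "cv_letters.csv", index=False,
                               float_format="%.8g")
                outputs.append(out / "cv_letters.csv")

    manifest = {
        "config": config,
        "master_seed": master,
        "files": {p.name: _sha256(p) for p in sorted(set(outputs))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
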