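"""End-to-end orchestration: QC -> transform -> PMM -> KSI -> shift-OU -> figures.

A run is driven by a single declarative YAML config; every stage writes its
tables (CSV) or figures plus a machine-readable summary, and a top-level
manifest lists all outputs with SHA-256 hashes so reruns can be compared
file-by-file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from phylomilk import core, ksi, phylospace, pmm, shifts, simulate, transforms

log = logging.getLogger("phylomilk")


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    tree: str
    traits: str
    covariates: str | None = None
    outdir: str = "phylomilk_run"
    seed: int = 0
    scale_tree: bool = True
    center_covariates: bool = True
    stages: dict = field(default_factory=lambda: {
        "qc": True, "pmm": True, "ksi": True, "shifts": True, "figures": True,
    })
    qc: dict = field(default_factory=lambda: {"threshold": 3.0, "use_sugar": True})
    pmm: dict = field(default_factory=lambda: {"backend": "ml", "n_boot": 0})
    ksi: dict = field(default_factory=lambda: {
        "ranks": 5, "min_clade": 4, "nodeset_frac": 0.95, "sets": None,
    })
    shifts: dict = field(default_factory=lambda: {"k_max": 8, "n_restarts": 2})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        for name in ("stages", "qc", "pmm", "ksi", "shifts"):
            merged = dict(getattr(cls, "__dataclass_fields__")[name].default_factory())
            merged.update(raw.get(name) or {})
            setattr(cfg, name, merged)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    logging.basicConfig(level=logging.INFO)

    tree = core.read_newick(config.tree)
    if config.scale_tree:
        tree = core.scale_tree_height(tree)
    traits = core.read_traits(config.traits)
    covs = core.read_covariates(config.covariates) if config.covariates else None
    if covs is not None and config.center_covariates and not covs.centered:
        covs = transforms.center_log_predictors(covs)
    data = core.trim_and_align(tree, traits, covs)
    log.info("aligned dataset: %d species", data.n)

    outputs: list[Path] = []
    summary: dict = {"n_species": data.n, "stages": {}}

    def _stage(name):
        enabled = bool(config.stages.get(name, False))
        if enabled:
            log.info("stage %s: start", name)
        return enabled

    if _stage("qc"):
        t0 = time.time()
        report = transforms.dry_matter_check(
            data.traits, use_sugar=config.qc["use_sugar"],
            threshold=config.qc["threshold"])
        report.to_csv(out / "qc_report.csv")
        outputs.append(out / "qc_report.csv")
        summary["stages"]["qc"] = {
            "flagged": report.flagged, "r_squared": report.r_squared,
            "seconds": round(time.time() - t0, 3),
        }

    logit_traits = data.traits.to_logit()
    logit_data = core.AlignedDataset(tree=data.tree, traits=logit_traits,
                                     covariates=data.covariates)

    if _stage("pmm"):
        t0 = time.time()
        fit = pmm.fit_pmm(logit_data, backend=config.pmm["backend"],
                          seed=config.seed, n_boot=config.pmm.get("n_boot", 0))
        coef_table, cov_table = pmm.summarize_pmm(fit)
        coef_table.to_csv(out / "pmm_coefficients.csv")
        cov_table.to_csv(out / "pmm_covariance_summary.csv")
        with open(out / "pmm_fit.json", "w") as fh:
            json.dump({
                "loglik": fit.loglik, "backend": fit.backend,
                "n_species": fit.n_species,
                "h2": fit.h2.to_dict(),
                "intervals": {k: list(v) for k, v in fit.intervals.items()},
                "diagnostics": fit.diagnostics,
            }, fh, indent=1)
        outputs += [out / "pmm_coefficients.csv", out / "pmm_covariance_summary.csv",
                    out / "pmm_fit.json"]
        summary["stages"]["pmm"] = {"loglik": fit.loglik,
                                    "h2": fit.h2.round(4).to_dict(),
                                    "seconds": round(time.time() - t0, 3)}

    if _stage("ksi"):
        t0 = time.time()
        sets = config.ksi.get("sets") or ksi.DEFAULT_TRAIT_SETS
        results = [
            ksi.ksi_search(data.tree, logit_traits, trait_set=s,
                           n_ranks=config.ksi["ranks"],
                           min_clade=config.ksi["min_clade"],
                           nodeset_frac=config.ksi["nodeset_frac"])
            for s in sets
        ]
        table = ksi.ksi_table(results)
        table.to_csv(out / "ksi_table.csv", index=False)
        outputs.append(out / "ksi_table.csv")
        summary["stages"]["ksi"] = {
            "blocks": len(results),
            "top": {"-".join(r.trait_set): (r.ranks[0].name if r.ranks else None)
                    for r in results},
            "seconds": round(time.time() - t0, 3),
        }

    shift_fit = None
    if _stage("shifts"):
        t0 = time.time()
        shift_fit = shifts.select_K(
            logit_traits.data.reindex(data.tree.tip_labels), data.tree,
            K_max=config.shifts["k_max"], seed=config.seed,
            n_restarts=config.shifts["n_restarts"])
        shift_fit.optima_percent.to_csv(out / "regimes.csv")
        shift_fit.criterion_curve.to_csv(out / "criterion.csv", index=False)
        shift_fit.imputed.dropna(how="all").to_csv(out / "imputed.csv")
        with open(out / "shifts.json", "w") as fh:
            json.dump({
                "K": shift_fit.K,
                "alpha": shift_fit.alpha,
                "half_life": shift_fit.phylo_half_life,
                "loglik": shift_fit.loglik,
                "shift_edges": list(shift_fit.shift_edges),
                "shift_clades": [sorted(c) for c in shift_fit.shift_clades],
                "equivalent_solutions": [list(s) for s in shift_fit.equivalence],
            }, fh, indent=1)
        outputs += [out / "regimes.csv", out / "criterion.csv",
                    out / "imputed.csv", out / "shifts.json"]
        summary["stages"]["shifts"] = {"K": shift_fit.K, "alpha": shift_fit.alpha,
                                       "seconds": round(time.time() - t0, 3)}

    if _stage("figures"):
        t0 = time.time()
        complete = logit_traits.data.dropna()
        if shift_fit is not None and shift_fit.imputed.notna().any().any():
            completed = logit_traits.data.fillna(shift_fit.imputed)
        else:
            completed = logit_traits.data
        keep = completed.dropna().index
        sub = core.trim_and_align(data.tree, data.traits.restrict(list(keep)))
        aquatic = data.covariates.data["aquatic"] if data.covariates is not None else None
        raw = sub.traits.g100g if sub.traits.g100g is not None else None
        phylospace.plot_phylomorphospace(
            sub.tree, completed.reindex(sub.tree.tip_labels), pair=("protein", "fat"),
            aquatic=aquatic, path=out / "phylomorphospace.svg")
        renorm = transforms.renormalize_composition(
            _completed_traits(sub, completed))
        phylospace.plot_mixture_triangle(renorm, path=out / "mixture_triangle.svg")
        outputs += [out / "phylomorphospace.svg", out / "mixture_triangle.svg"]
        summary["stages"]["figures"] = {"seconds": round(time.time() - t0, 3)}

    manifest = {
        "outputs": {p.name: _sha256(p) for p in outputs},
        "summary": summary,
        "seed": config.seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("run complete: %s", out)
    return out


def _completed_traits(sub, completed_logit):
    from phylomilk.core import TraitMatrix
    from phylomilk.transforms import inverse_logit

    tm = TraitMatrix.__new__(TraitMatrix)
    df = completed_logit.reindex(sub.tree.tip_labels)
    tm.data = df
    tm.scale = "logit"
    tm.dry_matter = None
    tm.g100g = inverse_logit(df) * 100.0
    return tm


def make_demo_dataset(preset: str, seed: int, outdir) -> Path:
    """Write a synthetic input set (tree + traits + covariates + truth)."""
    ds = simulate.make_preset(preset, seed=seed)
    out = Path(outdir)
    ds.write(out)
    return out
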