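"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` chains the stages — synthetic-data generation (or loading),
the four preprocessing recipes, replicate QC, PCA and consensus PCA, PLSR
calibration with bioreplicate validation, band-intensity ratios, and the
ANOVA variance decomposition — writing every intermediate table plus a
machine-readable JSON summary.  One seed governs the whole run; rerunning
with the same configuration reproduces the summary byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova_decomp import decompose_all_strains
from .errors import MycospecError
from .factor_models import fit_cpca, fit_pca
from .preprocess import average_technical_replicates, fit_apply_recipe, make_recipe
from .qc_replicates import replicate_pcc
from .regression import RATIO_PRESETS, band_ratio, validate_bioreplicate
from .spectra_io import SpectraSet, read_spectra_matrix, write_spectra_matrix
from .synthetic_data import DesignEffects, synth_dataset

log = logging.getLogger("mycospec")

MUCOR_STRAINS = ("Mc1", "Mc2", "Mr")
MC_STRAINS = ("Mc1", "Mc2")


@dataclass
class PLSRJob:
    """One calibration task: analyte × strain subset × block × recipe."""

    name: str
    response: str
    block: str
    recipe: str
    strains: tuple[str, ...] = ()


def default_plsr_jobs() -> list[PLSRJob]:
    """The calibration grid of the study design."""
    jobs = []
    for recipe, tag in (("raman_nonderiv", "nonderiv"), ("raman_deriv", "deriv")):
        jobs += [
            PLSRJob(f"lipids_6strains_{tag}", "lipid_pct_dw", "raman", recipe),
            PLSRJob(f"lipids_mucor_{tag}", "lipid_pct_dw", "raman", recipe, MUCOR_STRAINS),
            PLSRJob(f"phosphorus_6strains_{tag}", "phosphorus_pct_dw", "raman", recipe),
            PLSRJob(f"phosphorus_mucor_{tag}", "phosphorus_pct_dw", "raman", recipe, MUCOR_STRAINS),
            PLSRJob(f"carotenoids_mc_{tag}", "carotenoid_ug_per_g", "raman", recipe, MC_STRAINS),
        ]
    # FTIR counterparts, incl. the carotenoid contrast (expected to fail)
    jobs += [
        PLSRJob("lipids_6strains_ftir", "lipid_pct_dw", "ftir", "ftir_nonderiv"),
        PLSRJob("phosphorus_6strains_ftir", "phosphorus_pct_dw", "ftir", "ftir_nonderiv"),
        PLSRJob("carotenoids_mc_ftir", "carotenoid_ug_per_g", "ftir", "ftir_nonderiv", MC_STRAINS),
    ]
    return jobs


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips through YAML."""

    seed: int = 0
    out_dir: str = "mycospec_run"
    #: paths to pre-existing wide-CSV blocks; when empty, data is synthesized
    raman_path: str = ""
    ftir_path: str = ""
    blocks: tuple[str, ...] = ("raman", "ftir")
    n_pca_components: int = 5
    n_cpca_components: int = 3
    max_plsr_components: int = 10
    aopt_rule: str = "relative"
    aopt_tol: float = 0.05
    train_bio_rep: int = 1
    write_intermediates: bool = True

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "blocks" in data:
            data["blocks"] = tuple(data["blocks"])
        return cls(**data)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig, effects: DesignEffects | None = None) -> dict:
    """Run every stage of the workflow; return the summary dict.

    Stages whose inputs are unavailable (e.g. CPCA without the FTIR block)
    are skipped with a logged notice recorded in the summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "skipped": [],
    }
    notices: list[str] = []

    # -- stage: data -------------------------------------------------------
    raw: dict[str, SpectraSet] = {}
    if config.raman_path or config.ftir_path:
        if "raman" in config.blocks and config.raman_path:
            raw["raman"] = read_spectra_matrix(config.raman_path)
        if "ftir" in config.blocks and config.ftir_path:
            raw["ftir"] = read_spectra_matrix(config.ftir_path)
        summary["data_source"] = "files"
    else:
        log.info("simulate: generating synthetic dataset (seed=%d)", config.seed)
        raman, ftir, chem = synth_dataset(effects, seed=config.seed)
        if "raman" in config.blocks:
            raw["raman"] = raman
        if "ftir" in config.blocks:
            raw["ftir"] = ftir
        summary["data_source"] = "synthetic"
        if config.write_intermediates:
            chem.to_csv(out / "chemistry.csv", index=False)
            for name, sset in raw.items():
                write_spectra_matrix(sset, out / f"{name}_raw.csv")
    summary["n_spectra"] = {k: v.n_samples for k, v in raw.items()}

    # -- stage: preprocess -------------------------------------------------
    log.info("preprocess: applying recipes")
    pp: dict[str, SpectraSet] = {}
    for block, sset in raw.items():
        for kind in ("nonderiv", "deriv"):
            name = f"{block}_{kind}"
            pp[name], _ = fit_apply_recipe(sset, make_recipe(name))
            if config.write_intermediates:
                write_spectra_matrix(pp[name], out / f"pp_{name}.csv")
    avg = {name: average_technical_replicates(s) for name, s in pp.items()}

    # -- stage: qc ---------------------------------------------------------
    if "raman_nonderiv" in pp:
        log.info("qc: replicate 1-PCC variability")
        qc = replicate_pcc(pp["raman_nonderiv"])
        if config.write_intermediates:
            qc.to_csv(out / "variability.csv", index=False)
        flagged = qc["laser_power_mw"] == 200.0
        summary["qc"] = {
            "n_samples": int(len(qc)),
            "median_variability": float(qc["variability"].median()),
            "median_variability_reduced_power": float(qc.loc[flagged, "variability"].median())
            if flagged.any()
            else None,
            "median_variability_full_power": float(qc.loc[~flagged, "variability"].median()),
            "most_variable_sample": str(qc["sample_id"].iloc[0]),
        }
    else:
        summary["skipped"].append("qc")
        log.info("qc: skipped (no raman block)")

    # -- stage: pca --------------------------------------------------------
    if "raman_nonderiv" in avg:
        log.info("pca: raman non-derivative block")
        pca = fit_pca(avg["raman_nonderiv"], config.n_pca_components)
        summary["pca"] = {
            "block": "raman_nonderiv",
            "explained_variance_pct": pca.explained_variance_pct.tolist(),
        }
        if config.write_intermediates:
            scores = pd.DataFrame(
                pca.scores, columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])]
            )
            scores.insert(0, "sample_id", avg["raman_nonderiv"].meta["sample_id"])
            scores.to_csv(out / "pca_scores.csv", index=False)
            np.savetxt(out / "pca_loadings.csv", pca.loadings, delimiter=",")
    else:
        summary["skipped"].append("pca")

    # -- stage: cpca -------------------------------------------------------
    if "raman_deriv" in avg and "ftir_deriv" in avg:
        log.info("cpca: consensus of derivative raman + ftir blocks")
        cpca = fit_cpca(
            [avg["raman_deriv"], avg["ftir_deriv"]],
            config.n_cpca_components,
            labels=["raman", "ftir"],
        )
        summary["cpca"] = {
            "explained_variance_pct": cpca.explained_variance_pct.tolist(),
            "block_contrib_pct": {
                lab: cpca.block_contrib_pct[:, i].tolist()
                for i, lab in enumerate(cpca.block_labels)
            },
        }
        if config.write_intermediates:
            gs = pd.DataFrame(
                cpca.global_scores,
                columns=[f"PC{i+1}" for i in range(cpca.global_scores.shape[1])],
            )
            gs.insert(0, "sample_id", avg["raman_deriv"].meta["sample_id"])
            gs.to_csv(out / "cpca_global_scores.csv", index=False)
    else:
        summary["skipped"].append("cpca")
        log.info("cpca: skipped (needs both derivative blocks)")

    # -- stage: plsr -------------------------------------------------------
    plsr_summaries = {}
    for job in default_plsr_jobs():
        if job.block not in raw:
            summary["skipped"].append(f"plsr:{job.name}")
            log.info("plsr %s: skipped (block %s absent)", job.name, job.block)
            continue
        sset = raw[job.block]
        if job.strains:
            sset = sset.select_strains(job.strains)
        is_train = (sset.meta["bio_rep"] == config.train_bio_rep).to_numpy()
        report = validate_bioreplicate(
            sset.select(is_train),
            sset.select(~is_train),
            response=job.response,
            max_components=config.max_plsr_components,
            recipe=make_recipe(job.recipe),
            aopt_rule=config.aopt_rule,
            aopt_tol=config.aopt_tol,
        )
        report.pop("model")
        plsr_summaries[job.name] = report
        log.info(
            "plsr %s: AOpt=%d R2val=%.3f RMSEval=%.3g",
            job.name, report["aopt"], report["r2_val"], report["rmse_val"],
        )
    summary["plsr"] = plsr_summaries
    if config.write_intermediates and plsr_summaries:
        (out / "plsr_reports.json").write_text(
            json.dumps(_round_floats(plsr_summaries), indent=2, sort_keys=True)
        )

    # -- stage: band ratios ------------------------------------------------
    if "raman_nonderiv" in pp:
        log.info("ratio: presets on raman non-derivative data")
        ratio_summary = {}
        for preset in sorted(RATIO_PRESETS):
            tbl = band_ratio(pp["raman_nonderiv"], preset=preset)
            if config.write_intermediates:
                tbl.to_csv(out / f"ratio_{preset}.csv", index=False)
            cond = (
                tbl.groupby(["strain", "pi_level", "ca_level"])["ratio"].mean().reset_index()
            )
            ratio_summary[preset] = {
                f"{r.strain}-Pi{r.pi_level:g}-Ca{int(r.ca_level)}": float(r.ratio)
                for r in cond.itertuples()
            }
        summary["band_ratios"] = ratio_summary
    else:
        summary["skipped"].append("ratio")

    # -- stage: anova ------------------------------------------------------
    if "raman_deriv" in avg and "ftir_deriv" in avg:
        log.info("anova: per-strain variance decomposition")
        table = decompose_all_strains(avg["raman_deriv"], avg["ftir_deriv"])
        if config.write_intermediates:
            table.to_csv(out / "anova_contributions.csv", index=False)
        summary["anova"] = {
            "recipe": "derivative",
            "n_rows": int(len(table)),
            "rows": _round_floats(table.to_dict(orient="records")),
        }
    elif "raman_deriv" in avg:
        sub = avg["raman_deriv"]
        table = decompose_all_strains(sub, sub).query("block == 'raman'")
        if config.write_intermediates:
            table.to_csv(out / "anova_contributions.csv", index=False)
        summary["anova"] = {
            "recipe": "derivative",
            "n_rows": int(len(table)),
            "rows": _round_floats(table.to_dict(orient="records")),
        }
        summary["skipped"].append("anova:ftir")
        log.info("anova: ftir block skipped")
    else:
        summary["skipped"].append("anova")

    summary["notices"] = notices
    summary = _round_floats(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("pipeline complete: %s", out / "summary.json")
    return summary
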