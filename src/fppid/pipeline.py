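"""End-to-end orchestration: simulate/load data, model, design, report.

The pipeline mirrors the development workflow: build (or load) a material
library, select a representative working set, arrange the blocked
granulation design crossed with tableting forces, assemble the tablet
observation table, fit the full (M1) and reduced (M2) latent-variable
process models, and run the four-step formulation-process co-design with
the reduced model. Every stage draws its randomness from a stage-specific
seed derived from one base seed, so stages are independently reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import design_engine as de
from . import granulation, latent, materials, synthetic

log = logging.getLogger("fppid.pipeline")

#: Stage-name -> offset used to derive per-stage seeds from the base seed.
_STAGE_OFFSETS = {
    "library": 11, "design": 23, "observations": 37,
    "formulation": 53, "process": 71, "cv": 89, "sa": 97,
}


def stage_seed(base_seed: int, stage: str) -> int:
    return (int(base_seed) * 1009 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


def default_config(seed: int = 0) -> dict:
    """The study-shaped default configuration."""
    return {
        "seed": int(seed),
        "library": {"n_materials": 30, "n_latent_factors": 3, "noise_sd": 0.7},
        "representatives": {"n_boundary": 5, "n_center": 2, "n_fill": 3},
        "design": {"runs_per_block": 3,
                   "rpm_levels": [400, 600, 800],
                   "wt_levels": [180, 240, 300],
                   "force_levels": [1, 3, 5, 7, 9, 11]},
        "observations": {"replicates": 4, "noise_sd": 0.1},
        "model": {"n_components": 6, "folds": 7},
        "formulation": {"s": 15, "m": 0.30, "b": 1566, "max_excipients": 5},
        "grids": {"rpm": [400, 500, 600, 700, 800],
                  "liquid_mL": [30, 60, 90, 120, 150, 180, 210, 240],
                  "wt_s": [180, 210, 240, 270, 300],
                  "force_kN": [1, 3, 5, 7, 9, 11]},
        "targets": {"ts_min": 2.0, "sf_range": [0.705, 0.995],
                    "t2_alpha": 0.05, "spe_alpha": 0.05},
        "constants": {"bowl_diameter": granulation.DEFAULT_BOWL_DIAMETER,
                      "batch_mass": 300.0},
        "sensitivity": {"n": 1000},
    }


def _merge(base: dict, override: dict | None) -> dict:
    if not override:
        return base
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def subset_library(lib: materials.MaterialLibrary,
                   ids: list[str]) -> materials.MaterialLibrary:
    mask = lib.table["material_id"].isin(ids)
    missing = set(ids) - set(lib.material_ids)
    if missing:
        raise KeyError(f"unknown material id(s): {sorted(missing)}")
    return materials.MaterialLibrary(lib.table[mask].reset_index(drop=True))


def run_pipeline(config: dict | None = None, outdir=None,
                 materials_path=None) -> dict:
    """Run the full workflow; returns a report dict of models, tables and
    counts, writing CSV/JSON artifacts when ``outdir`` is given."""
    cfg = _merge(default_config(), config or {})
    seed = int(cfg["seed"])
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # 1. material library ------------------------------------------------
    if materials_path is not None:
        if not Path(materials_path).exists():
            raise FileNotFoundError(f"materials file not found: {materials_path}")
        lib = materials.load_library(materials_path)
    else:
        spec = synthetic.GeneratorSpec(seed=stage_seed(seed, "library"),
                                       **cfg["library"])
        lib = synthetic.generate_library(spec)
    log.info("library: %d materials", len(lib))

    # 2. representative working set --------------------------------------
    rep = materials.select_representatives(lib, **cfg["representatives"])
    working_ids = rep["boundary"] + rep["center"] + rep["fill"]
    working = subset_library(lib, working_ids)
    log.info("working set: %s", working_ids)

    # 3. hybrid design ----------------------------------------------------
    dcfg = cfg["design"]
    design = granulation.build_design(
        working,
        runs_per_block=dcfg["runs_per_block"],
        rpm_levels=tuple(dcfg["rpm_levels"]),
        wt_levels=tuple(dcfg["wt_levels"]),
        force_levels=tuple(dcfg["force_levels"]),
        seed=stage_seed(seed, "design"),
    )
    log.info("design: %d granulation runs, %d tableting runs",
             len(design.granulation), len(design.runs))

    # 4. observation table ------------------------------------------------
    obs, truth = synthetic.generate_hswgt_observations(
        working, design,
        noise_sd=cfg["observations"]["noise_sd"],
        replicates=cfg["observations"]["replicates"],
        seed=stage_seed(seed, "observations"),
        bowl_diameter=cfg["constants"]["bowl_diameter"],
    )
    Y = obs[["TS", "SF"]].to_numpy()

    # 5. process models ---------------------------------------------------
    A = cfg["model"]["n_components"]
    folds = cfg["model"]["folds"]
    feats_m2 = materials.REDUCED_FEATURES + materials.PROCESS_COLUMNS
    m2 = latent.fit_pls(obs[feats_m2].to_numpy(), Y, A,
                        feature_names=feats_m2, response_names=["TS", "SF"])
    met2 = latent.metrics(m2, obs[feats_m2].to_numpy(), Y, folds=folds)
    vip2 = latent.vip(m2)
    log.info("M2: R2X %.3f R2Y %.3f Q2 %.3f", met2.r2x_cum, met2.r2y_cum,
             met2.q2_cum)

    # 6. formulation simulation -------------------------------------------
    fcfg = cfg["formulation"]
    excipients = [i for i, c in zip(lib.material_ids, lib.table["category"])
                  if c == "excipient"]
    s = min(fcfg["s"], len(excipients))
    excipients = excipients[:s]
    npps = [i for i, c in zip(lib.material_ids, lib.table["category"])
            if c == "natural_product_powder"]
    drug_id = npps[0] if npps else lib.material_ids[0]
    comp = subset_library(lib, [drug_id] + excipients)
    # preserve requested order (drug first)
    order = [comp.material_ids.index(i) for i in [drug_id] + excipients]
    I28 = comp.feature_matrix(materials.MODEL_FEATURES)[order]
    formulation = de.sample_formulations(
        s=s, m=fcfg["m"], b=fcfg["b"],
        max_excipients=fcfg["max_excipients"],
        seed=stage_seed(seed, "formulation"),
        excipient_names=excipients, drug_name=drug_id)
    AI28 = pd.DataFrame(de.ideal_mixing(formulation, I28),
                        columns=materials.MODEL_FEATURES)

    # 7. wetting-agent matching + process draw -----------------------------
    matcher = de.WettingAgentMatcher(n_pcs=3).fit(lib)
    matches = matcher.match(AI28.to_numpy())
    grids = de.ProcessGrids(**{k: tuple(v) for k, v in cfg["grids"].items()})
    R = de.sample_process(matches, AI28[["Da", "Dc", "Dt"]], grids,
                          batch_mass=cfg["constants"]["batch_mass"],
                          bowl_diameter=cfg["constants"]["bowl_diameter"],
                          seed=stage_seed(seed, "process"))

    # 8. solution generation ----------------------------------------------
    tcfg = cfg["targets"]
    targets = de.DesignTargets(ts_min=tcfg["ts_min"],
                               sf_range=tuple(tcfg["sf_range"]),
                               t2_alpha=tcfg["t2_alpha"],
                               spe_alpha=tcfg["spe_alpha"])
    AI25 = AI28[materials.REDUCED_FEATURES]
    solutions = de.generate_solutions(m2, AI25, R, targets)

    # 9. sensitivity analysis for the drug material ------------------------
    drug_feats = comp.feature_matrix(materials.REDUCED_FEATURES)[order[0]]
    drug_row = lib.record(drug_id)
    rho_l = granulation.LIQUID_DENSITY[drug_row["wetting_agent"]]
    ls_lo, ls_hi = float(drug_row["ls_min"]), float(drug_row["ls_max"])
    fr_lo = granulation.froude_number(min(grids.rpm),
                                      cfg["constants"]["bowl_diameter"])
    fr_hi = granulation.froude_number(max(grids.rpm),
                                      cfg["constants"]["bowl_diameter"])
    smax = lambda ls: granulation.max_pore_saturation(
        ls, drug_row["Da"], rho_l, min(drug_row["Dc"], 0.99 * drug_row["Dt"]),
        drug_row["Dt"])
    ranges = {
        "LS": (ls_lo, ls_hi),
        "WT": (min(grids.wt_s), max(grids.wt_s)),
        "Fr": (fr_lo, fr_hi),
        "Smax": (smax(ls_lo), smax(ls_hi)),
        "P": (float(np.min(grids.force_kN)) * 12.732395447351628,
              float(np.max(grids.force_kN)) * 12.732395447351628),
    }
    sa = de.sensitivity_analysis(drug_feats, m2, ranges,
                                 n=cfg["sensitivity"]["n"],
                                 seed=stage_seed(seed, "sa"))

    report = {
        "config": cfg,
        "library": lib,
        "representatives": rep,
        "working": working,
        "design": design,
        "observations": obs,
        "truth": truth,
        "model": m2,
        "metrics": met2,
        "vip": pd.Series(vip2, index=feats_m2),
        "formulation": formulation,
        "AI": AI28,
        "matches": matches,
        "R": R,
        "solutions": solutions,
        "sensitivity": sa,
    }

    if out is not None:
        lib.to_csv(out / "materials.csv")
        design.to_csv(out / "design.csv")
        obs.to_csv(out / "observations.csv", index=False, lineterminator="\n")
        latent.save_model(m2, out / "model.json")
        pd.DataFrame({
            "metric": ["R2X_cum", "R2Y_cum", "Q2_cum",
                       "RMSEE_TS", "RMSEE_SF", "RMSECV_TS", "RMSECV_SF"],
            "value": [met2.r2x_cum, met2.r2y_cum, met2.q2_cum,
                      met2.rmsee["TS"], met2.rmsee["SF"],
                      met2.rmsecv["TS"], met2.rmsecv["SF"]],
        }).to_csv(out / "metrics.csv", index=False, lineterminator="\n")
        report["vip"].rename("VIP").to_csv(out / "vip.csv",
                                           lineterminator="\n")
        solutions.table.to_csv(out / "solutions_all.csv", index=False,
                               lineterminator="\n")
        solutions.solutions.to_csv(out / "solutions.csv", index=False,
                                   lineterminator="\n")
        sa.pear.to_csv(out / "sensitivity.csv", lineterminator="\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh)
        with open(out / "counts.json", "w") as fh:
            json.dump(solutions.counts, fh)
    return report
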