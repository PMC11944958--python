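"""High-shear wet granulation process descriptors and the hybrid design.

Two dimensionless regime-map descriptors characterize granulation
conditions: the Froude number (agitation intensity) and the maximum pore
saturation (fraction of the minimum attainable void volume filled by the
wetting liquid, with tapped density standing in for envelope density).

The hybrid experimental design blocks on material: within each block a
small number of (L/S level, impeller speed, wet massing time) combinations
is chosen from a full candidate grid by a Fedorov-style determinant
exchange for a main-effects model, and each granulation run is then crossed
with a list of tableting force levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .materials import MaterialLibrary

__all__ = [
    "GRAVITY",
    "LIQUID_DENSITY",
    "froude_number",
    "rpm_for_froude",
    "max_pore_saturation",
    "DesignTable",
    "build_design",
]

GRAVITY = 9.81  # m/s^2

#: Wetting-agent densities, g/mL at 20 C (95% v/v ethanol from standard
#: ethanol-water density tables); overridable wherever consumed.
LIQUID_DENSITY = {"water": 1.000, "alcohol95": 0.8114}

DEFAULT_BOWL_DIAMETER = 0.14  # m, 2 L high-shear granulation pot

LS_LEVELS = ("low", "mid", "high")


def froude_number(impeller_rpm, bowl_diameter: float = DEFAULT_BOWL_DIAMETER):
    """Froude number Fr = omega^2 * (2R) / g of a high-shear granulator.

    ``omega`` is the impeller speed in revolutions per second and ``2R`` the
    bowl inner diameter in metres. With the 0.14 m default bowl, 400 rpm
    gives Fr = 0.63 and 800 rpm gives 2.54.
    """
    rpm = np.asarray(impeller_rpm, float)
    if np.any(rpm < 0):
        raise ValueError("impeller speed must be non-negative")
    if bowl_diameter <= 0:
        raise ValueError("bowl diameter must be positive")
    out = (rpm / 60.0) ** 2 * bowl_diameter / GRAVITY
    return out.item() if out.ndim == 0 else out


def rpm_for_froude(fr, bowl_diameter: float = DEFAULT_BOWL_DIAMETER):
    """Impeller speed (rpm) that realizes a target Froude number."""
    fr = np.asarray(fr, float)
    if np.any(fr < 0):
        raise ValueError("Froude number must be non-negative")
    out = 60.0 * np.sqrt(fr * GRAVITY / bowl_diameter)
    return out.item() if out.ndim == 0 else out


def max_pore_saturation(w, rho_bulk_solid, rho_liquid, rho_tapped, rho_true):
    """Maximum pore saturation S'max = w*rho_s*(1-eps_min)/(rho_l*eps_min).

    ``w`` is the liquid-to-solid mass ratio (g/g); ``eps_min`` is the
    minimum porosity 1 - rho_tapped/rho_true, using the tapped density in
    place of the (unknown) envelope density.
    """
    w = np.asarray(w, float)
    rho_s = np.asarray(rho_bulk_solid, float)
    rho_l = np.asarray(rho_liquid, float)
    rho_c = np.asarray(rho_tapped, float)
    rho_t = np.asarray(rho_true, float)
    if np.any(w < 0):
        raise ValueError("liquid-to-solid ratio must be non-negative")
    if np.any(rho_s <= 0) or np.any(rho_l <= 0) or np.any(rho_c <= 0) or np.any(rho_t <= 0):
        raise ValueError("densities must be positive")
    eps_min = 1.0 - rho_c / rho_t
    if np.any(eps_min <= 0):
        raise ValueError(
            "zero or negative minimum porosity (tapped density >= true density)"
        )
    out = w * rho_s * (1.0 - eps_min) / (rho_l * eps_min)
    return out.item() if out.ndim == 0 else out


@dataclass
class DesignTable:
    """Blocked granulation runs crossed with tableting force levels.

    ``granulation`` has one row per granulation run (run_id, material_id,
    block, ls_level, ls_actual, rpm, wt_s, wetting_agent); ``runs`` crosses
    each with the force levels (adding force_kN).
    """

    granulation: pd.DataFrame
    runs: pd.DataFrame
    force_levels: tuple[float, ...]

    def __post_init__(self) -> None:
        pairs = self.runs[["run_id", "force_kN"]]
        if pairs.duplicated().any():
            raise ValueError("duplicate (run, force) pair in design")

    def __len__(self) -> int:
        return len(self.runs)

    def to_csv(self, path) -> None:
        self.runs.to_csv(path, index=False, lineterminator="\n")


def _main_effects_row(ls_idx: int, rpm: float, wt: float,
                      rpm_range, wt_range) -> list[float]:
    # intercept, 2 dummies for the 3-level categorical, 2 coded numerics
    code = lambda x, lo, hi: (2.0 * x - (lo + hi)) / (hi - lo)
    return [
        1.0,
        1.0 if ls_idx == 1 else 0.0,
        1.0 if ls_idx == 2 else 0.0,
        code(rpm, *rpm_range),
        code(wt, *wt_range),
    ]


def _design_objective(X: np.ndarray) -> float:
    """log-det D-optimality surrogate: det(X X^T) when runs < parameters
    (the p x p information matrix is then singular for every subset),
    det(X^T X) otherwise."""
    n, p = X.shape
    M = X @ X.T if n < p else X.T @ X
    sign, logdet = np.linalg.slogdet(M)
    return logdet if sign > 0 else -np.inf


def _exchange_select(candidates: np.ndarray, n_runs: int,
                     rng: np.random.Generator, n_restarts: int = 50) -> list[int]:
    """Fedorov-style exchange: from a random start, repeatedly swap one
    selected row for one candidate row whenever the swap increases the
    determinant objective; best over seeded restarts, ties toward the
    lexicographically smallest sorted index set."""
    n_cand = candidates.shape[0]
    best_obj, best_set = -np.inf, None
    for _ in range(n_restarts):
        sel = list(rng.choice(n_cand, size=n_runs, replace=False))
        obj = _design_objective(candidates[sel])
        improved = True
        while improved:
            improved = False
            for pos in range(n_runs):
                for j in range(n_cand):
                    if j in sel:
                        continue
                    trial = sel.copy()
                    trial[pos] = j
                    t_obj = _design_objective(candidates[trial])
                    if t_obj > obj + 1e-12:
                        sel, obj = trial, t_obj
                        improved = True
        key = tuple(sorted(sel))
        if obj > best_obj + 1e-12 or (
            abs(obj - best_obj) <= 1e-12 and best_set is not None
            and key < tuple(sorted(best_set))
        ):
            best_obj, best_set = obj, sel
    return sorted(best_set)


def build_design(
    lib: MaterialLibrary,
    runs_per_block: int = 3,
    rpm_levels: tuple[float, ...] = (400.0, 600.0, 800.0),
    wt_levels: tuple[float, ...] = (180.0, 240.0, 300.0),
    force_levels: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0, 9.0, 11.0),
    seed: int = 0,
    n_restarts: int = 50,
) -> DesignTable:
    """Build the blocked, exchange-selected, force-crossed hybrid design.

    One block per library material; within each block ``runs_per_block``
    combinations of (L/S level, impeller speed, wet massing time) are chosen
    from the full candidate grid by determinant exchange, then crossed with
    ``force_levels``. L/S levels low/mid/high map to the material's
    (ls_min, midpoint, ls_max).
    """
    if len(lib) == 0:
        raise ValueError("empty material library")
    grid = [
        (li, rpm, wt)
        for li in range(len(LS_LEVELS))
        for rpm in rpm_levels
        for wt in wt_levels
    ]
    if runs_per_block > len(grid):
        raise ValueError(
            f"runs_per_block={runs_per_block} exceeds candidate grid size {len(grid)}"
        )
    rpm_range = (min(rpm_levels), max(rpm_levels))
    wt_range = (min(wt_levels), max(wt_levels))
    X_cand = np.array(
        [_main_effects_row(li, rpm, wt, rpm_range, wt_range) for li, rpm, wt in grid]
    )
    rng = np.random.default_rng(seed)

    rows = []
    for block, mid in enumerate(lib.material_ids, start=1):
        ls_min, ls_max = lib.ls_range(mid)
        if not np.isfinite([ls_min, ls_max]).all():
            raise ValueError(f"material {mid!r} lacks an L/S range")
        ls_values = {"low": ls_min, "mid": (ls_min + ls_max) / 2.0, "high": ls_max}
        agent = lib.record(mid)["wetting_agent"]
        if runs_per_block == len(grid):
            sel = list(range(len(grid)))
        else:
            sel = _exchange_select(X_cand, runs_per_block, rng, n_restarts)
        for k, idx in enumerate(sel, start=1):
            li, rpm, wt = grid[idx]
            level = LS_LEVELS[li]
            rows.append({
                "run_id": f"{mid}-{k}",
                "material_id": mid,
                "block": block,
                "ls_level": level,
                "ls_actual": ls_values[level],
                "rpm": rpm,
                "wt_s": wt,
                "wetting_agent": agent,
            })
    gran = pd.DataFrame(rows)
    crossed = gran.loc[gran.index.repeat(len(force_levels))].reset_index(drop=True)
    crossed["force_kN"] = list(force_levels) * len(gran)
    return DesignTable(granulation=gran, runs=crossed,
                       force_levels=tuple(force_levels))
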