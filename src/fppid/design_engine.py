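"""Formulation-process-product integrated design and sensitivity analysis.

The four-step in-silico design loop:

1. **Targets** - minimum tablet tensile strength, acceptable solid-fraction
   window, and diagnostic significance levels.
2. **Formulation simulation** - random drug/excipient recipes on the
   simplex (drug fraction fixed at 1-m, excipient support size bounded),
   with mixture properties from the ideal mixing rule AI = A x I.
3. **Process simulation** - per-recipe wetting-agent assignment by
   nearest-centroid matching in PCA score space of the material library,
   liquid-to-solid range inherited from the nearest library powder, and
   random draws of process levels on practical grids with derived
   dimensionless descriptors (Froude number, maximum pore saturation).
4. **Solution generation** - predict tensile strength and solid fraction
   with the latent-variable process model and keep rows satisfying the
   targets inside the model's validity region (Hotelling T2 and SPE below
   their limits).

A Monte Carlo sensitivity analysis reports Pearson correlations (PEAR)
between uniformly sampled process parameters and the model-predicted
responses for a fixed material.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compaction import force_to_pressure
from .granulation import (DEFAULT_BOWL_DIAMETER, LIQUID_DENSITY,
                          froude_number, max_pore_saturation)
from .latent import PCAUV, PLSNipals, spe_limit, t2_limit
from .materials import (MODEL_FEATURES, PROCESS_COLUMNS, REDUCED_FEATURES,
                        MaterialLibrary, SchemaError)

__all__ = [
    "DesignTargets",
    "FormulationMatrix",
    "sample_formulations",
    "ideal_mixing",
    "WettingAgentMatcher",
    "match_wetting_agent",
    "ProcessGrids",
    "sample_process",
    "SolutionSet",
    "generate_solutions",
    "sensitivity_analysis",
    "SensitivityReport",
]

log = logging.getLogger("fppid.design")


@dataclass
class DesignTargets:
    """Tablet quality targets and diagnostic significance levels."""

    ts_min: float = 2.0          # MPa
    sf_range: tuple[float, float] = (0.80, 0.90)
    t2_alpha: float = 0.05
    spe_alpha: float = 0.05
    spe_method: str = "jackson-mudholkar"

    def __post_init__(self) -> None:
        if self.ts_min <= 0:
            raise ValueError("ts_min must be positive")
        lo, hi = self.sf_range
        if not (0 < lo < hi <= 1.05):
            raise ValueError("sf_range must satisfy 0 < lo < hi <= 1.05")
        for a in (self.t2_alpha, self.spe_alpha):
            if not (0 < a < 1):
                raise ValueError("significance levels must lie in (0, 1)")


@dataclass
class FormulationMatrix:
    """Candidate recipes: column 0 is the drug fraction (1-m), the rest are
    excipient weight fractions. Every row sums to 1."""

    matrix: np.ndarray
    drug_name: str
    excipient_names: list[str]
    max_excipients: int

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix, float)
        if A.ndim != 2 or A.shape[1] != 1 + len(self.excipient_names):
            raise ValueError("formulation matrix shape mismatch with names")
        if np.any(A < 0):
            raise ValueError("weight fractions must be non-negative")
        if not np.allclose(A.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("every recipe row must sum to 1")
        support = (A[:, 1:] > 0).sum(axis=1)
        if np.any(support > self.max_excipients):
            raise ValueError("a recipe exceeds the excipient-count bound")
        self.matrix = A

    def __len__(self) -> int:
        return len(self.matrix)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix,
                            columns=[self.drug_name] + self.excipient_names)


def sample_formulations(
    s: int,
    m: float,
    b: int,
    max_excipients: int = 5,
    seed: int = 0,
    excipient_names: list[str] | None = None,
    drug_name: str = "drug",
) -> FormulationMatrix:
    """Draw ``b`` random recipes with ``s`` candidate excipients summing to
    total excipient fraction ``m``.

    Per recipe the excipient support size k is uniform on {1..max_excipients},
    the support is a uniform k-subset, and the weights are a flat Dirichlet
    over the support scaled to m. The drug fraction is fixed at 1-m. This
    samples the bounded-support constraint directly instead of
    generate-then-filter, so the row count is exactly ``b``.
    """
    if not (0 < m < 1):
        raise ValueError("total excipient fraction m must lie in (0, 1)")
    if s < 1 or b < 1:
        raise ValueError("s and b must be positive")
    if max_excipients > s:
        log.warning("max_excipients=%d clipped to s=%d", max_excipients, s)
        max_excipients = s
    if excipient_names is None:
        excipient_names = [f"excipient_{j + 1}" for j in range(s)]
    if len(excipient_names) != s:
        raise ValueError("excipient_names length must equal s")
    rng = np.random.default_rng(seed)
    A = np.zeros((b, 1 + s))
    A[:, 0] = 1.0 - m
    for i in range(b):
        k = int(rng.integers(1, max_excipients + 1))
        support = rng.choice(s, size=k, replace=False)
        w = rng.dirichlet(np.ones(k))
        A[i, 1 + support] = m * w
    # exact row sums despite floating Dirichlet rounding
    A[:, 0] = 1.0 - A[:, 1:].sum(axis=1)
    return FormulationMatrix(A, drug_name, list(excipient_names), max_excipients)


def ideal_mixing(A, I) -> np.ndarray:
    """Mixture properties by the ideal mixing rule AI = A x I.

    ``A`` is a (c, 1+s) formulation matrix (or :class:`FormulationMatrix`);
    ``I`` a (1+s, q) component property matrix whose row order matches A's
    column order. Each mixture property is a convex combination of the
    component properties.
    """
    if isinstance(A, FormulationMatrix):
        A = A.matrix
    A = np.asarray(A, float)
    I = np.asarray(I, float)
    if A.ndim != 2 or I.ndim != 2 or A.shape[1] != I.shape[0]:
        raise SchemaError(
            f"ideal mixing dimension mismatch: A is {A.shape}, I is {I.shape}"
        )
    return A @ I


class WettingAgentMatcher:
    """Nearest-centroid wetting-agent assignment in PCA score space.

    Fit a UV-scaled PCA on the library's 28-feature block, locate the
    centroids of the water-granulated and alcohol-granulated powders in
    ``n_pcs``-dimensional score space, and assign each new mixture to the
    nearer centroid; the liquid-to-solid range is inherited from the single
    nearest library powder.
    """

    def __init__(self, n_pcs: int = 3):
        self.n_pcs = n_pcs

    def fit(self, lib: MaterialLibrary) -> "WettingAgentMatcher":
        agents = lib.table["wetting_agent"].to_numpy()
        for agent in ("water", "alcohol95"):
            if not np.any(agents == agent):
                raise ValueError(
                    f"library has no material with wetting agent {agent!r}"
                )
        self.pca_ = PCAUV(n_components=self.n_pcs).fit(
            lib.feature_matrix(MODEL_FEATURES), feature_names=MODEL_FEATURES)
        self.scores_ = self.pca_.scores_
        self.material_ids_ = lib.material_ids
        self.agents_ = agents
        self.ls_ranges_ = lib.table[["ls_min", "ls_max"]].to_numpy(float)
        self.centroids_ = {
            agent: self.scores_[agents == agent].mean(axis=0)
            for agent in ("water", "alcohol95")
        }
        return self

    def match(self, mixture_rows: np.ndarray) -> pd.DataFrame:
        """Match each 28-feature mixture row; returns a DataFrame with
        agent, ls_min/ls_max, nearest material and centroid distances."""
        X = np.atleast_2d(np.asarray(mixture_rows, float))
        if X.shape[1] != len(MODEL_FEATURES):
            raise SchemaError(
                f"mixture rows must have {len(MODEL_FEATURES)} features"
            )
        t = self.pca_.transform(X)
        d_water = np.linalg.norm(t - self.centroids_["water"], axis=1)
        d_alcohol = np.linalg.norm(t - self.centroids_["alcohol95"], axis=1)
        agent = np.where(d_water <= d_alcohol, "water", "alcohol95")
        d_all = np.linalg.norm(t[:, None, :] - self.scores_[None], axis=2)
        nearest = d_all.argmin(axis=1)
        return pd.DataFrame({
            "wetting_agent": agent,
            "dist_water": d_water,
            "dist_alcohol": d_alcohol,
            "nearest_material_id": [self.material_ids_[i] for i in nearest],
            "nearest_distance": d_all[np.arange(len(X)), nearest],
            "ls_min": self.ls_ranges_[nearest, 0],
            "ls_max": self.ls_ranges_[nearest, 1],
        })


def match_wetting_agent(mixture_row, lib: MaterialLibrary, n_pcs: int = 3):
    """One-shot wrapper around :class:`WettingAgentMatcher` for a single
    mixture property row (28 features)."""
    return WettingAgentMatcher(n_pcs=n_pcs).fit(lib).match(mixture_row).iloc[0]


@dataclass
class ProcessGrids:
    """Practical level grids for the process draw."""

    rpm: tuple[float, ...] = (400, 500, 600, 700, 800)
    liquid_mL: tuple[float, ...] = (30, 60, 90, 120, 150, 180, 210, 240)
    wt_s: tuple[float, ...] = (180, 210, 240, 270, 300)
    force_kN: tuple[float, ...] = (1, 3, 5, 7, 9, 11)

    def __post_init__(self) -> None:
        for name in ("rpm", "liquid_mL", "wt_s", "force_kN"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"empty grid {name!r}")


def sample_process(
    matches: pd.DataFrame,
    mixture_densities: pd.DataFrame,
    grids: ProcessGrids | None = None,
    batch_mass: float = 300.0,
    bowl_diameter: float = DEFAULT_BOWL_DIAMETER,
    liquid_density: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw one process condition per formulation row.

    ``matches`` carries the per-row wetting agent and inherited L/S range;
    ``mixture_densities`` the ideal-mixing bulk/tapped/true densities
    (columns Da, Dc, Dt). For each row one level is drawn per grid; the
    liquid volume is drawn among the levels whose implied L/S ratio
    (volume x liquid density / batch mass) falls inside the row's L/S
    range. Rows with no feasible liquid level are flagged infeasible.

    Returns a DataFrame with columns LS, WT, Fr, Smax, P (plus rpm,
    liquid_mL, force_kN bookkeeping and a ``feasible`` flag).
    """
    if grids is None:
        grids = ProcessGrids()
    if liquid_density is None:
        liquid_density = LIQUID_DENSITY
    rng = np.random.default_rng(seed)
    n = len(matches)
    if len(mixture_densities) != n:
        raise SchemaError("matches and mixture_densities row counts differ")
    rows = []
    n_infeasible = 0
    for i in range(n):
        agent = matches["wetting_agent"].iloc[i]
        rho_l = liquid_density[agent]
        lo, hi = matches["ls_min"].iloc[i], matches["ls_max"].iloc[i]
        feasible = [v for v in grids.liquid_mL
                    if lo <= v * rho_l / batch_mass <= hi]
        rpm = float(rng.choice(grids.rpm))
        wt = float(rng.choice(grids.wt_s))
        force = float(rng.choice(grids.force_kN))
        if not feasible:
            n_infeasible += 1
            rows.append({"LS": np.nan, "WT": wt, "Fr": np.nan,
                         "Smax": np.nan, "P": np.nan, "rpm": rpm,
                         "liquid_mL": np.nan, "force_kN": force,
                         "feasible": False})
            continue
        vol = float(rng.choice(feasible))
        ls = vol * rho_l / batch_mass
        da = float(mixture_densities["Da"].iloc[i])
        dc = float(mixture_densities["Dc"].iloc[i])
        dt = float(mixture_densities["Dt"].iloc[i])
        rows.append({
            "LS": ls,
            "WT": wt,
            "Fr": froude_number(rpm, bowl_diameter),
            "Smax": max_pore_saturation(ls, da, rho_l, min(dc, 0.99 * dt), dt),
            "P": force_to_pressure(force),
            "rpm": rpm, "liquid_mL": vol, "force_kN": force,
            "feasible": True,
        })
    if n_infeasible:
        log.info("sample_process: %d of %d rows had no feasible liquid level",
                 n_infeasible, n)
    return pd.DataFrame(rows)


@dataclass
class SolutionSet:
    """Rows surviving the four design constraints, with predictions and
    diagnostics for every simulated row and per-stage counts."""

    table: pd.DataFrame = field(repr=False)
    surviving: np.ndarray
    counts: dict[str, int]
    t2_limit: float
    spe_limit: float
    targets: DesignTargets

    def __len__(self) -> int:
        return len(self.surviving)

    @property
    def solutions(self) -> pd.DataFrame:
        return self.table.loc[self.surviving]


def generate_solutions(
    model: PLSNipals,
    AI: pd.DataFrame,
    R: pd.DataFrame,
    targets: DesignTargets | None = None,
) -> SolutionSet:
    """Step 4: predict, diagnose, and filter the simulated candidates.

    ``AI`` holds the mixture properties (reduced 25-feature layout) and
    ``R`` the process draw; their concatenation is reordered to the model's
    training feature order. Rows survive when predicted TS >= ts_min, SF
    inside sf_range, Hotelling T2 below its limit and SPE below its limit.
    """
    if targets is None:
        targets = DesignTargets()
    if len(AI) != len(R):
        raise SchemaError("AI and R row counts differ")
    air = pd.concat([AI.reset_index(drop=True), R.reset_index(drop=True)],
                    axis=1)
    names = model.feature_names_
    if names is None:
        raise SchemaError("model lacks feature names; cannot align AIR columns")
    missing = [c for c in names if c not in air.columns]
    if missing:
        raise SchemaError(f"AIR lacks model feature column(s): {missing}")
    feasible = R["feasible"].to_numpy(bool) if "feasible" in R else np.ones(len(R), bool)
    X = air[names].to_numpy(float)

    pred = np.full((len(X), 2), np.nan)
    t2 = np.full(len(X), np.nan)
    q = np.full(len(X), np.nan)
    if feasible.any():
        Xf = X[feasible]
        pred[feasible] = model.predict(Xf)
        t2[feasible] = model.hotelling_t2(Xf)
        q[feasible] = model.spe(Xf)
    rnames = model.response_names_ or ["TS", "SF"]
    out = air.copy()
    out[f"{rnames[0]}_pred"] = pred[:, 0]
    out[f"{rnames[1]}_pred"] = pred[:, 1]
    out["T2"] = t2
    out["SPE"] = q

    t2_lim = t2_limit(model.n_components, model.n_train_, targets.t2_alpha)
    spe_lim = spe_limit(model._x_residual_train_, targets.spe_alpha,
                        method=targets.spe_method)
    lo, hi = targets.sf_range
    with np.errstate(invalid="ignore"):
        pass_ts = feasible & (pred[:, 0] >= targets.ts_min)
        pass_sf = feasible & (pred[:, 1] >= lo) & (pred[:, 1] <= hi)
        pass_t2 = feasible & (t2 < t2_lim)
        pass_spe = feasible & (q < spe_lim)
    out["pass_ts"] = pass_ts
    out["pass_sf"] = pass_sf
    out["pass_t2"] = pass_t2
    out["pass_spe"] = pass_spe
    survive = pass_ts & pass_sf & pass_t2 & pass_spe
    counts = {
        "simulated": len(X),
        "feasible": int(feasible.sum()),
        "pass_ts": int(pass_ts.sum()),
        "pass_sf": int(pass_sf.sum()),
        "pass_t2": int(pass_t2.sum()),
        "pass_spe": int(pass_spe.sum()),
        "surviving": int(survive.sum()),
    }
    log.info("solution generation: %s", counts)
    return SolutionSet(table=out, surviving=np.flatnonzero(survive),
                       counts=counts, t2_limit=t2_lim, spe_limit=spe_lim,
                       targets=targets)


@dataclass
class SensitivityReport:
    """Pearson correlations between process parameters and predicted
    responses under uniform Monte Carlo sampling."""

    pear: pd.DataFrame
    zero_variance: list[str]
    n_samples: int
    seed: int


def sensitivity_analysis(
    material_features: np.ndarray,
    model: PLSNipals,
    ranges: dict[str, tuple[float, float]],
    n: int = 1000,
    seed: int = 0,
) -> SensitivityReport:
    """Monte Carlo sensitivity of predicted TS/SF to the process parameters.

    ``material_features`` is the fixed 25-feature property vector;
    ``ranges`` maps each process column (LS, WT, Fr, Smax, P) to a uniform
    sampling interval (degenerate intervals allowed - their PEAR is
    recorded as 0 with a flag). PEAR is computed on model *predictions*,
    so it characterizes the fitted response surface.
    """
    if n < 3:
        raise ValueError("need at least 3 Monte Carlo samples")
    missing = [c for c in PROCESS_COLUMNS if c not in ranges]
    if missing:
        raise ValueError(f"ranges missing process parameter(s): {missing}")
    feats = np.asarray(material_features, float).ravel()
    if len(feats) != len(REDUCED_FEATURES):
        raise SchemaError(
            f"material feature vector must have {len(REDUCED_FEATURES)} entries"
        )
    rng = np.random.default_rng(seed)
    draws = np.column_stack([
        rng.uniform(*sorted(ranges[c]), size=n) for c in PROCESS_COLUMNS
    ])
    X = np.column_stack([np.tile(feats, (n, 1)), draws])
    names = model.feature_names_ or (REDUCED_FEATURES + PROCESS_COLUMNS)
    order = [names.index(c) if c in names else None for c in REDUCED_FEATURES + PROCESS_COLUMNS]
    if any(o is None for o in order):
        raise SchemaError("model feature names do not match the canonical layout")
    X_model = np.empty_like(X)
    X_model[:, order] = X
    pred = model.predict(X_model)
    rnames = model.response_names_ or ["TS", "SF"]
    pear = np.zeros((len(PROCESS_COLUMNS), pred.shape[1]))
    flagged = []
    for i, c in enumerate(PROCESS_COLUMNS):
        x = draws[:, i]
        if x.std() == 0:
            flagged.append(c)
            continue
        for k in range(pred.shape[1]):
            y = pred[:, k]
            pear[i, k] = 0.0 if y.std() == 0 else float(np.corrcoef(x, y)[0, 1])
    return SensitivityReport(
        pear=pd.DataFrame(pear, index=PROCESS_COLUMNS, columns=rnames),
        zero_variance=flagged, n_samples=n, seed=seed)
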