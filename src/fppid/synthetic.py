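"""Seeded synthetic-data generators with planted, recoverable structure.

Three generators feed the rest of the package:

* :func:`generate_library` - a correlated material-property library whose
  28 features are driven by a small number of latent factors, with the
  correlation signs observed in real powder libraries (densities
  anticorrelated with tabletability, particle size anticorrelated with
  flow time, Heckel yield pressure anticorrelated with Kawakita ``a``);
* :func:`generate_hswgt_observations` - a tablet-response table over a
  granulation/tableting design, with tensile strength and solid fraction
  generated from a planted linear model on UV-scaled inputs plus Gaussian
  noise, so a latent-variable regression can recover the coefficients;
* :func:`generate_compression_curves` - porosity-pressure and
  strength-pressure series from a chosen compression equation with
  multiplicative lognormal noise, for closed-loop fit recovery.

Every generator is a pure function of its spec and seed.

The planted response model is calibrated so its default noise level
reproduces the predictive regime of material-library tablet datasets: the
standardized linear predictor is scaled by ``signal_scale`` (default 0.19)
before adding N(0, ``noise_sd``) noise, giving a theoretical
cross-validated Q2 of signal^2/(signal^2+noise^2) ~ 0.78 at the default
``noise_sd`` = 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compaction import CompressionSeries, force_to_pressure
from .granulation import (DEFAULT_BOWL_DIAMETER, LIQUID_DENSITY, DesignTable,
                          froude_number, max_pore_saturation)
from .materials import (MODEL_FEATURES, PROCESS_COLUMNS, REDUCED_FEATURES,
                        MaterialLibrary)

__all__ = [
    "GeneratorSpec",
    "generate_library",
    "default_planted_coefficients",
    "generate_hswgt_observations",
    "generate_compression_curves",
]


@dataclass
class GeneratorSpec:
    """Parameters of the material-library generator.

    ``noise_sd`` is the standard deviation of the independent per-feature
    disturbance relative to the latent-factor contribution (a fraction of
    one standardized latent unit).
    """

    seed: int
    n_materials: int = 30
    n_latent_factors: int = 3
    noise_sd: float = 0.7
    npp_fraction: float = 0.2
    ls_lo_range: tuple[float, float] = (0.15, 0.7)
    ls_width_range: tuple[float, float] = (0.1, 0.8)

    def __post_init__(self) -> None:
        if self.n_materials < 2:
            raise ValueError("need at least 2 materials")
        if self.n_latent_factors < 1:
            raise ValueError("need at least 1 latent factor")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.npp_fraction <= 1):
            raise ValueError("npp_fraction must lie in [0, 1]")


def _driver(spec: GeneratorSpec, factors: np.ndarray, loadings,
            rng: np.random.Generator) -> np.ndarray:
    """Standardized latent driver: affine image of the factors plus
    independent noise, normalized to unit theoretical variance."""
    lam = np.zeros(factors.shape[1])
    for k, v in enumerate(loadings[: factors.shape[1]]):
        lam[k] = v
    raw = factors @ lam + spec.noise_sd * rng.standard_normal(len(factors))
    denom = np.sqrt(float(lam @ lam) + spec.noise_sd**2)
    if denom == 0:
        return np.zeros(len(factors))
    return raw / denom


def generate_library(spec: GeneratorSpec) -> MaterialLibrary:
    """Generate a correlated powder library satisfying all schema invariants.

    Latent factor 1 drives density/compaction-resistance features (and,
    with opposite sign, tabletability), factor 2 drives particle size and
    flow, factor 3 drives cohesion/plasticity/moisture. The wetting agent
    is assigned by thresholding factor 1 (dense, hard-to-wet powders get
    95% alcohol).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_materials
    F = rng.standard_normal((n, spec.n_latent_factors))

    d = lambda loads: _driver(spec, F, loads, rng)

    Dt = np.clip(1.55 + 0.28 * d([1.0, 0.1, -0.1]), 1.1, 2.9)
    SF_p = np.clip(0.38 + 0.07 * d([0.8, 0.2, -0.3]), 0.18, 0.72)
    eps_p = 1.0 - SF_p
    Da = SF_p * Dt
    IH_raw = np.clip(1.28 + 0.12 * d([0.3, -0.8, 0.3]), 1.05, 1.8)
    Dc = np.minimum(Da * IH_raw, 0.97 * Dt)
    IH = Dc / Da
    IC = (Dc - Da) / Dc * 100.0
    Ie = (Dc - Da) / (Dc * Da)

    D50 = np.exp(np.clip(4.1 + 0.55 * d([0.2, 1.0, 0.1]), 2.3, 6.2))
    r10 = np.clip(0.30 + 0.06 * d([0.0, 0.5, 0.3]), 0.10, 0.60)
    r90 = np.clip(2.40 + 0.35 * d([0.0, -0.6, 0.4]), 1.40, 4.00)
    D10, D90 = r10 * D50, r90 * D50
    Span = (D90 - D10) / D50

    t_dprime = np.clip(11.0 - 3.0 * d([0.1, 0.9, -0.2]), 1.0, 30.0)
    AOR = np.clip(36.0 - 3.5 * d([0.2, 0.8, -0.4]), 20.0, 55.0)
    pctHR = np.clip(3.5 + 1.2 * d([-0.2, 0.1, 0.9]), 0.1, 12.0)
    pctH = np.clip(2.5 + 1.0 * d([-0.1, 0.0, 1.0]), 0.05, 15.0)
    pctpf = np.clip(30.0 - 11.0 * d([0.1, 0.9, 0.2]), 0.5, 95.0)
    Itheta = np.clip(0.008 + 0.004 * d([0.2, -0.5, 0.6]), 0.0005, 0.05)
    Icd = np.clip(160.0 + 45.0 * d([-0.3, -0.2, 0.9]), 20.0, 400.0)

    kaw_a = np.clip(0.56 + 0.09 * d([-0.4, 0.1, 0.8]), 0.25, 0.90)
    b_inv = np.clip(16.0 + 5.0 * d([0.3, 0.8, -0.2]), 3.0, 60.0)
    kaw_ab = kaw_a / b_inv
    Py = np.clip(130.0 - 35.0 * d([-0.5, 0.0, 0.8]), 35.0, 400.0)
    f = np.clip(0.11 + 0.04 * d([-0.4, 0.2, 0.8]), 0.01, 0.50)
    K = np.clip(8.5 + 1.8 * d([0.9, 0.1, -0.2]), 2.0, 20.0)
    kb = np.clip(6.5 + 1.4 * d([0.9, -0.1, -0.3]), 1.5, 15.0)
    power_d = np.exp(np.clip(-2.2 - 0.45 * d([0.9, -0.2, 0.2]), -4.5, -0.5))
    power_g = np.clip(0.95 + 0.14 * d([-0.2, 0.8, 0.3]), 0.50, 1.60)

    agent = np.where(F[:, 0] > 0, "alcohol95", "water")
    ls_lo = rng.uniform(*spec.ls_lo_range, size=n)
    ls_hi = np.minimum(ls_lo + rng.uniform(*spec.ls_width_range, size=n), 1.5)
    n_npp = int(round(spec.npp_fraction * n))
    category = np.array(["excipient"] * n, dtype=object)
    if n_npp:
        category[rng.choice(n, size=n_npp, replace=False)] = "natural_product_powder"

    table = pd.DataFrame({
        "material_id": [f"M{i + 1:02d}" for i in range(n)],
        "name": [f"synthetic material {i + 1}" for i in range(n)],
        "category": category,
        "wetting_agent": agent,
        "ls_min": ls_lo,
        "ls_max": ls_hi,
        "Dt": Dt, "D10": D10, "D50": D50, "D90": D90, "Da": Da, "Dc": Dc,
        "eps_p": eps_p, "SF_p": SF_p, "Ie": Ie, "IC": IC, "Icd": Icd,
        "IH": IH, "AOR": AOR, "t_dprime": t_dprime, "pctHR": pctHR,
        "pctH": pctH, "pctpf": pctpf, "Itheta": Itheta, "Span": Span,
        "kawakita_a": kaw_a, "kawakita_b_inv": b_inv, "kawakita_ab": kaw_ab,
        "heckel_Py": Py, "shapiro_f": f, "gurnham_K": K, "rd_kb": kb,
        "power_d": power_d, "power_g": power_g,
    })
    return MaterialLibrary(table)


def default_planted_coefficients() -> dict[str, np.ndarray]:
    """Planted standardized coefficients of the tablet-response truth.

    Signs follow the structure reported for high-shear wet granulation and
    tableting data: tableting pressure acts positively on both responses,
    the liquid-to-solid ratio negatively on both; densities and the
    compression-resistance / bonding descriptors (Gurnham K, R-D kb) act
    negatively on tensile strength; the yield pressure Py acts negatively
    and the Kawakita ``a`` positively on solid fraction. Exactly
    collinearity-consistent: features that are anticorrelated by
    construction (eps_p vs SF_p) carry opposite-signed coefficients.
    Order: the 25 reduced material features then LS, WT, Fr, Smax, P.
    """
    cols = REDUCED_FEATURES + PROCESS_COLUMNS
    ts = dict.fromkeys(cols, 0.0)
    sf = dict.fromkeys(cols, 0.0)
    ts.update({
        "Dt": -0.25, "Da": -0.25, "Dc": -0.22, "D10": 0.22,
        "eps_p": 0.05, "SF_p": -0.05, "t_dprime": -0.03,
        "kawakita_a": 0.10, "heckel_Py": -0.10, "gurnham_K": -0.28,
        "rd_kb": -0.35, "power_d": 0.30,
        "LS": -0.35, "WT": 0.03, "Fr": 0.05, "Smax": -0.05, "P": 0.55,
    })
    sf.update({
        "Dt": 0.15, "Da": 0.10, "eps_p": -0.10, "SF_p": 0.10,
        "kawakita_a": 0.30, "heckel_Py": -0.35, "gurnham_K": 0.05,
        "power_d": 0.05,
        "LS": -0.35, "WT": 0.02, "Fr": 0.04, "Smax": -0.05, "P": 0.60,
    })
    return {
        "TS": np.array([ts[c] for c in cols]),
        "SF": np.array([sf[c] for c in cols]),
    }


def generate_hswgt_observations(
    lib: MaterialLibrary,
    design: DesignTable,
    planted: dict[str, np.ndarray] | None = None,
    noise_sd: float = 0.1,
    signal_scale: float = 0.19,
    replicates: int = 4,
    seed: int = 0,
    bowl_diameter: float = DEFAULT_BOWL_DIAMETER,
    force_jitter_sd: float = 0.15,
    ts_loc: float = 4.5, ts_span: float = 7.0,
    sf_loc: float = 0.80, sf_span: float = 0.30,
) -> tuple[pd.DataFrame, dict]:
    """One row per tablet: 25 material features + 5 process columns + TS/SF.

    Each (granulation run, force level) pair yields ``replicates`` tablets
    whose compression force is jittered (the press realizes force only
    within a tolerance band). The responses are planted linear truths on
    the UV-scaled input block: each standardized predictor is scaled by
    ``signal_scale`` and perturbed by N(0, noise_sd), then mapped affinely
    to physical units (TS floored at 0.05 MPa, SF clipped to (0.3, 1.0)).

    Returns ``(table, truth)`` where ``truth`` records the planted
    coefficients and scaling actually used.
    """
    if planted is None:
        planted = default_planted_coefficients()
    p_expected = len(REDUCED_FEATURES) + len(PROCESS_COLUMNS)
    for key in ("TS", "SF"):
        if len(planted[key]) != p_expected:
            raise ValueError(
                f"planted[{key!r}] must have length {p_expected}"
            )
    rng = np.random.default_rng(seed)
    rows = []
    for _, run in design.runs.iterrows():
        rec = lib.record(run["material_id"])
        rho_l = LIQUID_DENSITY[rec["wetting_agent"]]
        feats = {c: float(rec[c]) for c in REDUCED_FEATURES}
        for rep in range(replicates):
            force = float(run["force_kN"]) + force_jitter_sd * rng.standard_normal()
            force = max(force, 0.2)
            ls = float(run["ls_actual"])
            row = dict(feats)
            row.update({
                "material_id": run["material_id"],
                "run_id": run["run_id"],
                "replicate": rep + 1,
                "LS": ls,
                "WT": float(run["wt_s"]),
                "Fr": froude_number(float(run["rpm"]), bowl_diameter),
                "Smax": max_pore_saturation(ls, feats["Da"], rho_l,
                                            feats["Dc"], feats["Dt"]),
                "P": force_to_pressure(force),
            })
            rows.append(row)
    table = pd.DataFrame(rows)

    cols = REDUCED_FEATURES + PROCESS_COLUMNS
    X = table[cols].to_numpy(float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    out = {}
    for key, (loc, span) in (("TS", (ts_loc, ts_span)),
                             ("SF", (sf_loc, sf_span))):
        eta = Z @ planted[key]
        eta_sd = eta.std(ddof=1)
        if eta_sd > 0:
            eta = eta / eta_sd
        r = signal_scale * eta + noise_sd * rng.standard_normal(len(eta))
        out[key] = loc + span * r
    table["TS"] = np.maximum(out["TS"], 0.05)
    table["SF"] = np.clip(out["SF"], 0.3, 1.0)
    truth = {
        "planted": {k: v.tolist() for k, v in planted.items()},
        "columns": cols,
        "noise_sd": noise_sd,
        "signal_scale": signal_scale,
        "scaling": {"TS": (ts_loc, ts_span), "SF": (sf_loc, sf_span)},
    }
    return table, truth


_POROSITY_MODELS = ("kawakita", "heckel", "shapiro", "gurnham")
_STRENGTH_MODELS = ("rd", "power")


def _porosity_from(model_id: str, params: dict, P: np.ndarray) -> np.ndarray:
    if model_id == "kawakita":
        a, b_inv, eps0 = params["a"], params["b_inv"], params["eps0"]
        if not (0 < a < 1) or b_inv <= 0 or not (0 < eps0 < 1):
            raise ValueError("kawakita requires 0<a<1, b_inv>0, 0<eps0<1")
        C = a * P / (b_inv + P)
        return 1.0 - (1.0 - eps0) / (1.0 - C)
    if model_id == "heckel":
        K, A = params["K"], params["A"]
        if K <= 0:
            raise ValueError("heckel requires K > 0")
        return np.exp(-(A + K * P))
    if model_id == "shapiro":
        eps0, k, f = params["eps0"], params["k"], params["f"]
        if not (0 < eps0 < 1):
            raise ValueError("shapiro requires 0 < eps0 < 1")
        return eps0 * np.exp(-k * P - f * np.sqrt(P))
    if model_id == "gurnham":
        K, P0 = params["K"], params["P0"]
        if K <= 0 or P0 <= 0:
            raise ValueError("gurnham requires K > 0 and P0 > 0")
        return -np.log(P / P0) / K
    raise ValueError(f"unknown porosity model {model_id!r}")


def generate_compression_curves(
    model_id: str,
    params: dict,
    pressures: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    porosity_for_strength: np.ndarray | None = None,
) -> tuple[CompressionSeries, dict]:
    """Evaluate one compression equation exactly, then apply multiplicative
    lognormal noise; returns the series and a truth record.

    For the porosity models the series carries porosity (and
    ``initial_porosity`` for Kawakita/Shapiro, taken from ``params``). For
    the strength models the series carries tensile strength; the
    Ryshkewitch-Duckworth model additionally needs a porosity series
    (``porosity_for_strength``).
    """
    P = np.sort(np.asarray(pressures, float))
    if len(np.unique(P)) < 2:
        raise ValueError("degenerate pressure grid: all pressures equal")
    rng = np.random.default_rng(seed)
    noise = lambda size: np.exp(noise_sd * rng.standard_normal(size)
                                - noise_sd**2 / 2.0)
    porosity = tensile = None
    eps0 = None
    if model_id in _POROSITY_MODELS:
        eps = _porosity_from(model_id, params, P)
        if np.any((eps <= 0) | (eps >= 1)):
            raise ValueError(
                f"{model_id} parameters give porosity outside (0, 1) on this grid"
            )
        porosity = np.clip(eps * noise(len(P)), 1e-4, 0.95)
        eps0 = params.get("eps0")
    elif model_id in _STRENGTH_MODELS:
        if model_id == "power":
            d, g = params["d"], params["g"]
            if d <= 0:
                raise ValueError("power requires d > 0")
            ts = d * P**g
        else:
            if porosity_for_strength is None:
                raise ValueError("rd requires a porosity series")
            porosity = np.asarray(porosity_for_strength, float)
            ts = params["TS0"] * np.exp(-params["kb"] * porosity)
        tensile = ts * noise(len(P))
    else:
        raise ValueError(f"unknown model {model_id!r}")
    series = CompressionSeries(pressure=P, porosity=porosity,
                               tensile_strength=tensile,
                               initial_porosity=eps0)
    truth = {"model_id": model_id, "params": dict(params),
             "noise_sd": noise_sd, "seed": seed}
    return series, truth


def generate_cbcs_series(
    kawakita_params: dict | None = None,
    power_params: dict | None = None,
    pressures: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[CompressionSeries, dict]:
    """A complete porosity + tensile-strength series for CBCS profiling.

    Porosity follows a Kawakita truth and tensile strength a power-law
    truth (the two descriptor families the series parameterizes exactly);
    the remaining four equations are then fitted approximations, as for
    real powders. Default pressures: the six 1-11 kN force levels
    converted to MPa, repeated four times (tablet replicates).
    """
    if kawakita_params is None:
        kawakita_params = {"a": 0.60, "b_inv": 25.0, "eps0": 0.65}
    if power_params is None:
        power_params = {"d": 0.05, "g": 0.9}
    if pressures is None:
        forces = np.repeat([1.0, 3.0, 5.0, 7.0, 9.0, 11.0], 4)
        pressures = force_to_pressure(forces)
    P = np.sort(np.asarray(pressures, float))
    rng = np.random.default_rng(seed)
    s1, s2 = rng.integers(0, 2**31 - 1, size=2)
    poro_series, _ = generate_compression_curves(
        "kawakita", kawakita_params, P, noise_sd, int(s1))
    ts_series, _ = generate_compression_curves(
        "power", power_params, P, noise_sd, int(s2))
    series = CompressionSeries(
        pressure=P, porosity=poro_series.porosity,
        tensile_strength=ts_series.tensile_strength,
        initial_porosity=kawakita_params["eps0"])
    truth = {"kawakita": dict(kawakita_params), "power": dict(power_params),
             "noise_sd": noise_sd, "seed": seed}
    return series, truth
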