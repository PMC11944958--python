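"""Tablet-level metrics and the compression behavior classification system.

Implements the diametral tensile strength and solid-fraction formulas for
flat-faced cylindrical tablets, and least-squares fits of six compression
equations whose parameters form the nine-descriptor compression behavior
classification system (CBCS):

========  =====================================  ====================
model     linearized fit                          descriptors
========  =====================================  ====================
kawakita  P/C = 1/(ab) + P/a                      a, b^-1, ab
heckel    ln(1/eps) = K*P + A                     Py = 1/K
shapiro   ln(eps) = ln(eps0) - k*P - f*sqrt(P)    f
gurnham   eps = -(1/K)*ln(P/P0)                   K
rd        ln(TS) = ln(TS0) - kb*eps               kb  (Ryshkewitch-Duckworth)
power     ln(TS) = ln(d) + g*ln(P)                d, g
========  =====================================  ====================

All fits are ordinary least squares on the linearized coordinates; R^2 and
RMSE are reported on the linearized response scale. Pressures are in MPa
throughout; tableting forces in kN convert via :func:`force_to_pressure`
with full-precision pi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FitError",
    "CompressionSeries",
    "FitResult",
    "tensile_strength",
    "solid_fraction",
    "force_to_pressure",
    "fit_compressibility",
    "fit_strength",
    "cbcs_profile",
    "CBCS_MODELS",
]

CBCS_MODELS = ("kawakita", "heckel", "shapiro", "gurnham", "rd", "power")

_PARAM_NAMES = {
    "kawakita": ("a", "b_inv", "ab"),
    "heckel": ("K", "A", "Py"),
    "shapiro": ("ln_eps0", "k", "f"),
    "gurnham": ("K", "P0"),
    "rd": ("TS0", "kb"),
    "power": ("d", "g"),
}


class FitError(ValueError):
    """A compression-equation fit is infeasible or degenerate."""


def tensile_strength(force_N: float, diameter_mm: float, thickness_mm: float) -> float:
    """Diametral tensile strength TS = 2F/(pi*D*H) of a flat-faced tablet.

    With F in N and D, H in mm the result is in N/mm^2 = MPa.
    """
    F = np.asarray(force_N, float)
    D = np.asarray(diameter_mm, float)
    H = np.asarray(thickness_mm, float)
    if np.any(F < 0) or np.any(D <= 0) or np.any(H <= 0):
        raise ValueError("tensile_strength requires F >= 0 and D, H > 0")
    out = 2.0 * F / (math.pi * D * H)
    return out.item() if out.ndim == 0 else out


def solid_fraction(mass_g, diameter_mm, thickness_mm, true_density):
    """Tablet solid fraction and porosity from mass, dimensions, true density.

    The apparent density is rho_app = m / (pi*D^2*H/4) (converted to g/cm^3);
    SF = rho_app/rho_true and porosity = 1 - SF. SF slightly above 1 can
    occur through measurement noise; values above 1.02 indicate inconsistent
    inputs and raise.

    Returns ``(SF, porosity)``.
    """
    m = np.asarray(mass_g, float)
    D = np.asarray(diameter_mm, float)
    H = np.asarray(thickness_mm, float)
    rho = np.asarray(true_density, float)
    if np.any(m <= 0) or np.any(D <= 0) or np.any(H <= 0) or np.any(rho <= 0):
        raise ValueError("solid_fraction requires all positive inputs")
    volume_cm3 = math.pi * D**2 * H / 4.0 / 1000.0  # mm^3 -> cm^3
    sf = m / volume_cm3 / rho
    if np.any(sf > 1.02):
        raise ValueError(
            "solid fraction exceeds 1.02; check mass/dimension/density units"
        )
    eps = 1.0 - sf
    if sf.ndim == 0:
        return sf.item(), eps.item()
    return sf, eps


def force_to_pressure(force_kN, punch_diameter_mm: float = 10.0):
    """Compaction pressure in MPa from force in kN on a circular flat punch.

    P = F / (pi*d^2/4); 1 kN on a 10 mm punch gives 12.73 MPa at full pi
    precision.
    """
    F = np.asarray(force_kN, float)
    if np.any(F <= 0) or punch_diameter_mm <= 0:
        raise ValueError("force and punch diameter must be positive")
    area_mm2 = math.pi * punch_diameter_mm**2 / 4.0
    out = F * 1000.0 / area_mm2
    return out.item() if out.ndim == 0 else out


@dataclass
class CompressionSeries:
    """Paired pressure/porosity/tensile-strength observations for one powder
    or granule batch, with the initial (loose) porosity used by the Kawakita
    and Shapiro fits and the Gurnham reference pressure."""

    pressure: np.ndarray
    porosity: np.ndarray | None = None
    tensile_strength: np.ndarray | None = None
    initial_porosity: float | None = None

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, float)
        if self.pressure.ndim != 1 or len(self.pressure) < 4:
            raise ValueError("pressure array must be 1-D with >= 4 points")
        if np.any(self.pressure <= 0):
            raise ValueError("pressures must be strictly positive")
        if np.any(np.diff(self.pressure) < 0):
            raise ValueError("pressures must be sorted ascending")
        for name in ("porosity", "tensile_strength"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, float)
                if arr.shape != self.pressure.shape:
                    raise ValueError(f"{name} length mismatch with pressure")
                setattr(self, name, arr)
        if self.porosity is not None and np.any(
            (self.porosity <= 0) | (self.porosity >= 1)
        ):
            raise ValueError("porosity values must lie in (0, 1)")
        if self.initial_porosity is not None and not (
            0 < self.initial_porosity < 1
        ):
            raise ValueError("initial porosity must lie in (0, 1)")


@dataclass
class FitResult:
    """Least-squares fit of one compression equation."""

    model_id: str
    parameters: dict[str, float]
    r_squared: float
    rmse: float
    response_scale: str = field(default="linearized")

    def __post_init__(self) -> None:
        expected = set(_PARAM_NAMES[self.model_id])
        if set(self.parameters) != expected:
            raise ValueError(
                f"parameters for {self.model_id} must be {sorted(expected)}"
            )


def _ols(design: np.ndarray, y: np.ndarray, model_id: str) -> tuple[np.ndarray, float, float]:
    n, p = design.shape
    if n < p + 1:
        raise FitError(f"{model_id}: {n} points cannot support {p} parameters")
    if np.linalg.matrix_rank(design) < p:
        raise FitError(f"{model_id}: degenerate design (collinear predictors)")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise FitError(f"{model_id}: response has zero variance")
    r2 = 1.0 - ss_res / ss_tot
    rmse = math.sqrt(ss_res / n)
    return beta, r2, rmse


def fit_compressibility(series: CompressionSeries, model_id: str) -> FitResult:
    """Fit one of the four porosity-pressure compression equations.

    Kawakita uses the degree of compression C = 1 - (1-eps0)/(1-eps), which
    follows from volume per unit solid mass V = 1/(rho_true*(1-eps)) with
    eps0 the loose (bulk) porosity from ``series.initial_porosity``.
    """
    if model_id not in ("kawakita", "heckel", "shapiro", "gurnham"):
        raise ValueError(f"unknown compressibility model {model_id!r}")
    if series.porosity is None:
        raise FitError(f"{model_id}: series has no porosity data")
    P = series.pressure
    eps = series.porosity

    if model_id == "kawakita":
        if series.initial_porosity is None:
            raise FitError("kawakita: initial porosity (from bulk density) required")
        eps0 = series.initial_porosity
        C = 1.0 - (1.0 - eps0) / (1.0 - eps)
        # a noisy point with porosity above eps0 implies negative compression,
        # which is unphysical: trim it rather than abort the whole fit
        valid = C > 0
        if valid.sum() < 3:
            bad = np.flatnonzero(~valid).tolist()
            raise FitError(
                f"kawakita: non-positive compression degree at points {bad}"
            )
        y = (P / C)[valid]
        P_fit = P[valid]
        X = np.column_stack([np.ones_like(P_fit), P_fit])
        beta, r2, rmse = _ols(X, y, model_id)
        intercept, slope = beta  # intercept = 1/(ab), slope = 1/a
        if slope <= 0 or intercept <= 0:
            raise FitError("kawakita: fitted slope/intercept non-positive")
        a = 1.0 / slope
        ab = 1.0 / intercept
        params = {"a": a, "ab": ab, "b_inv": a / ab}
    elif model_id == "heckel":
        y = np.log(1.0 / eps)
        X = np.column_stack([np.ones_like(P), P])
        beta, r2, rmse = _ols(X, y, model_id)
        A, K = beta
        if K <= 0:
            raise FitError("heckel: non-positive slope, yield pressure undefined")
        params = {"K": K, "A": A, "Py": 1.0 / K}
    elif model_id == "shapiro":
        y = np.log(eps)
        X = np.column_stack([np.ones_like(P), P, np.sqrt(P)])
        beta, r2, rmse = _ols(X, y, model_id)
        ln_eps0, neg_k, neg_f = beta
        params = {"ln_eps0": ln_eps0, "k": -neg_k, "f": -neg_f}
    else:  # gurnham: eps = -(1/K) ln(P/P0)
        y = eps
        X = np.column_stack([np.ones_like(P), np.log(P)])
        beta, r2, rmse = _ols(X, y, model_id)
        intercept, slope = beta
        if slope >= 0:
            raise FitError("gurnham: non-negative slope, resistance undefined")
        K = -1.0 / slope
        params = {"K": K, "P0": math.exp(K * intercept)}
    return FitResult(model_id, params, r2, rmse)


def fit_strength(series: CompressionSeries, model_id: str) -> FitResult:
    """Fit a tensile-strength equation (Ryshkewitch-Duckworth or power law)."""
    if model_id not in ("rd", "power"):
        raise ValueError(f"unknown strength model {model_id!r}")
    if series.tensile_strength is None:
        raise FitError(f"{model_id}: series has no tensile strength data")
    TS = series.tensile_strength
    if np.any(TS <= 0):
        bad = np.flatnonzero(TS <= 0).tolist()
        raise FitError(f"{model_id}: non-positive tensile strength at points {bad}")
    y = np.log(TS)
    if model_id == "rd":
        if series.porosity is None:
            raise FitError("rd: series has no porosity data")
        X = np.column_stack([np.ones_like(y), series.porosity])
        beta, r2, rmse = _ols(X, y, model_id)
        ln_ts0, neg_kb = beta
        params = {"TS0": math.exp(ln_ts0), "kb": -neg_kb}
    else:
        X = np.column_stack([np.ones_like(y), np.log(series.pressure)])
        beta, r2, rmse = _ols(X, y, model_id)
        ln_d, g = beta
        params = {"d": math.exp(ln_d), "g": g}
    return FitResult(model_id, params, r2, rmse)


def cbcs_profile(
    series: CompressionSeries, r2_gate: float = 0.9
) -> tuple[dict[str, float], list[FitResult], list[str]]:
    """Run all six fits and assemble the nine CBCS descriptors.

    Returns ``(descriptors, fits, flagged)`` where ``descriptors`` maps the
    canonical descriptor names (kawakita_a, kawakita_b_inv, kawakita_ab,
    heckel_Py, shapiro_f, gurnham_K, rd_kb, power_d, power_g) to values and
    ``flagged`` lists model ids whose R^2 fell below ``r2_gate``.
    """
    fits: list[FitResult] = []
    errors: list[str] = []
    for mid in ("kawakita", "heckel", "shapiro", "gurnham"):
        try:
            fits.append(fit_compressibility(series, mid))
        except FitError as exc:
            errors.append(f"{mid}: {exc}")
    for mid in ("rd", "power"):
        try:
            fits.append(fit_strength(series, mid))
        except FitError as exc:
            errors.append(f"{mid}: {exc}")
    if errors:
        raise FitError("unfittable model(s): " + "; ".join(errors))
    by_id = {f.model_id: f for f in fits}
    descriptors = {
        "kawakita_a": by_id["kawakita"].parameters["a"],
        "kawakita_b_inv": by_id["kawakita"].parameters["b_inv"],
        "kawakita_ab": by_id["kawakita"].parameters["ab"],
        "heckel_Py": by_id["heckel"].parameters["Py"],
        "shapiro_f": by_id["shapiro"].parameters["f"],
        "gurnham_K": by_id["gurnham"].parameters["K"],
        "rd_kb": by_id["rd"].parameters["kb"],
        "power_d": by_id["power"].parameters["d"],
        "power_g": by_id["power"].parameters["g"],
    }
    flagged = [f.model_id for f in fits if f.r_squared < r2_gate]
    return descriptors, fits, flagged
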