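"""Powder material library: schema, CSV I/O, and representative selection.

A material record carries 19 physical property parameters (true/bulk/tapped
density, particle sizes, porosity, flowability, stability and homogeneity
indexes), 9 compression-behavior descriptors obtained by fitting six
compression equations (see :mod:`fppid.compaction`), and wetting-agent
metadata (agent type and feasible liquid-to-solid ratio range for high-shear
wet granulation).

Representative materials are selected in a 2-D principal-component score
space of the full feature block: boundary materials by a farthest-point /
max-min criterion, center materials nearest the score centroid, and fill
materials by greedy max-min coverage of the remaining cloud.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PHYSICAL_FEATURES",
    "CBCS_FEATURES",
    "MODEL_FEATURES",
    "RETAINED_CBCS_FEATURES",
    "REDUCED_FEATURES",
    "PROCESS_COLUMNS",
    "META_COLUMNS",
    "OPTIONAL_INDEX_COLUMNS",
    "SchemaError",
    "MaterialLibrary",
    "load_library",
    "save_library",
    "select_representatives",
]

#: The 19 physical property parameters, in canonical column order.
PHYSICAL_FEATURES: list[str] = [
    "Dt",       # true density, g/cm^3
    "D10", "D50", "D90",  # percentile particle sizes, um
    "Da",       # bulk density, g/mL
    "Dc",       # tapped density, g/mL
    "eps_p",    # powder porosity, fraction
    "SF_p",     # powder solid fraction, fraction
    "Ie",       # inter-particle porosity
    "IC",       # Carr's index
    "Icd",      # cohesion index
    "IH",       # Hausner ratio
    "AOR",      # angle of repose, degrees
    "t_dprime",  # flow time, s
    "pctHR",    # moisture content, %
    "pctH",     # hygroscopicity, %
    "pctpf",    # fraction of particles < 50 um, %
    "Itheta",   # homogeneity index
    "Span",     # particle size distribution span
]

#: The 9 compression-behavior descriptors (CBCS), in canonical column order.
CBCS_FEATURES: list[str] = [
    "kawakita_a",
    "kawakita_b_inv",
    "kawakita_ab",
    "heckel_Py",
    "shapiro_f",
    "gurnham_K",
    "rd_kb",
    "power_d",
    "power_g",
]

#: The 28 modeling features: 19 physical then 9 CBCS.
MODEL_FEATURES: list[str] = PHYSICAL_FEATURES + CBCS_FEATURES

#: CBCS descriptors retained after VIP pruning of {ab, f, g}.
RETAINED_CBCS_FEATURES: list[str] = [
    "kawakita_a",
    "kawakita_b_inv",
    "heckel_Py",
    "gurnham_K",
    "rd_kb",
    "power_d",
]

#: The 25 material features of the pruned process model.
REDUCED_FEATURES: list[str] = PHYSICAL_FEATURES + RETAINED_CBCS_FEATURES

#: Process columns appended to material features in the process model, in
#: canonical order: liquid/solid ratio (g/g), wet massing time (s), Froude
#: number, maximum pore saturation, tableting pressure (MPa).
PROCESS_COLUMNS: list[str] = ["LS", "WT", "Fr", "Smax", "P"]

META_COLUMNS: list[str] = [
    "material_id", "name", "category", "wetting_agent", "ls_min", "ls_max",
]

#: Optional tabletability-change indexes (reworking potential and relative
#: change in tabletability); participate in representative selection when
#: present but not in process modeling.
OPTIONAL_INDEX_COLUMNS: list[str] = ["rework_potential", "tabletability_change"]

CATEGORIES = {"excipient", "natural_product_powder", "drug"}
WETTING_AGENTS = {"water", "alcohol95", "unknown"}

_CSV_FLOAT_FMT = "%.10g"


class SchemaError(ValueError):
    """A CSV or matrix does not conform to the material-library schema."""


def _uv_scale(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise SchemaError(f"zero-variance feature column at index {bad}")
    return (X - mu) / sd


def _pca_scores_2d(X: np.ndarray) -> np.ndarray:
    """First two PC scores of UV-scaled X, sign-fixed so each loading's
    largest-magnitude element is positive."""
    Z = _uv_scale(X)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    k = min(2, Vt.shape[0])
    scores = np.empty((X.shape[0], k))
    for a in range(k):
        v = Vt[a]
        sign = 1.0 if v[np.argmax(np.abs(v))] >= 0 else -1.0
        scores[:, a] = sign * U[:, a] * s[a]
    return scores


@dataclass
class MaterialLibrary:
    """An ordered collection of material records backed by a DataFrame.

    Column order is canonical (metadata, 19 physical, 9 CBCS, optional
    tabletability indexes) and preserved across save/load round-trips.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "MaterialLibrary":
        try:
            raw = pd.read_csv(path, dtype={"material_id": str, "name": str})
        except FileNotFoundError:
            raise
        required = META_COLUMNS + MODEL_FEATURES
        missing = [c for c in required if c not in raw.columns]
        if missing:
            raise SchemaError(
                f"materials CSV missing required column(s): {', '.join(missing)}"
            )
        cols = list(required)
        cols += [c for c in OPTIONAL_INDEX_COLUMNS if c in raw.columns]
        table = raw[cols].copy()
        numeric = [c for c in cols if c not in ("material_id", "name",
                                                "category", "wetting_agent")]
        for c in numeric:
            try:
                table[c] = pd.to_numeric(table[c], errors="raise")
            except (ValueError, TypeError) as exc:
                bad = pd.to_numeric(table[c], errors="coerce")
                row = int(bad.index[bad.isna() & table[c].notna()][0])
                raise SchemaError(
                    f"non-numeric value in column {c!r}, row {row}"
                ) from exc
        return cls(table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format=_CSV_FLOAT_FMT,
                          lineterminator="\n")

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        t = self.table
        if t["material_id"].duplicated().any():
            dup = t["material_id"][t["material_id"].duplicated()].iloc[0]
            raise SchemaError(f"duplicate material_id {dup!r}")
        bad_cat = set(t["category"]) - CATEGORIES
        if bad_cat:
            raise SchemaError(f"unknown category value(s): {sorted(bad_cat)}")
        bad_agent = set(t["wetting_agent"]) - WETTING_AGENTS
        if bad_agent:
            raise SchemaError(f"unknown wetting_agent value(s): {sorted(bad_agent)}")
        F = t[MODEL_FEATURES].to_numpy(float)
        if not np.isfinite(F).all():
            i, j = np.argwhere(~np.isfinite(F))[0]
            raise SchemaError(
                f"missing/non-finite feature {MODEL_FEATURES[j]!r} for "
                f"material {t['material_id'].iloc[i]!r}"
            )
        ls = t[["ls_min", "ls_max"]].to_numpy(float)
        present = np.isfinite(ls).all(axis=1)
        if np.any((ls[present, 0] <= 0) | (ls[present, 0] > ls[present, 1])):
            raise SchemaError("ls_range must satisfy 0 < ls_min <= ls_max")
        if np.any((F[:, MODEL_FEATURES.index("D10")] > F[:, MODEL_FEATURES.index("D50")])
                  | (F[:, MODEL_FEATURES.index("D50")] > F[:, MODEL_FEATURES.index("D90")])):
            raise SchemaError("particle sizes must satisfy D10 <= D50 <= D90")
        eps = F[:, MODEL_FEATURES.index("eps_p")]
        sf = F[:, MODEL_FEATURES.index("SF_p")]
        if np.any((eps < 0) | (eps >= 1)) or np.any((sf <= 0) | (sf > 1)):
            raise SchemaError("porosity/solid-fraction out of (0, 1) bounds")
        for c in ("Dt", "Da", "Dc"):
            if np.any(F[:, MODEL_FEATURES.index(c)] <= 0):
                raise SchemaError(f"density column {c!r} must be positive")

    # -- accessors --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def material_ids(self) -> list[str]:
        return list(self.table["material_id"])

    def feature_matrix(self, features: list[str] | None = None) -> np.ndarray:
        """Numeric feature block in canonical order (default: 28 modeling
        features plus any optional tabletability indexes present)."""
        if features is None:
            features = MODEL_FEATURES + [
                c for c in OPTIONAL_INDEX_COLUMNS if c in self.table.columns
            ]
        missing = [c for c in features if c not in self.table.columns]
        if missing:
            raise SchemaError(f"library lacks feature column(s): {missing}")
        return self.table[features].to_numpy(float)

    def record(self, material_id: str) -> pd.Series:
        hit = self.table[self.table["material_id"] == material_id]
        if hit.empty:
            raise KeyError(material_id)
        return hit.iloc[0]

    def ls_range(self, material_id: str) -> tuple[float, float]:
        r = self.record(material_id)
        return float(r["ls_min"]), float(r["ls_max"])


def load_library(path) -> MaterialLibrary:
    """Read ``materials.csv`` (canonical schema) into a library."""
    return MaterialLibrary.from_csv(path)


def save_library(lib: MaterialLibrary, path) -> None:
    lib.to_csv(path)


def select_representatives(
    lib: MaterialLibrary,
    n_boundary: int = 5,
    n_center: int = 2,
    n_fill: int = 3,
    seed: int | None = None,
) -> dict[str, list[str]]:
    """Pick boundary / center / fill materials in PC1-PC2 score space.

    Boundary points: start from the material farthest from the score
    centroid, then repeatedly add the material maximizing the minimum
    distance to those already picked. Center points: nearest the centroid.
    Fill points: greedy max-min coverage of the remainder, seeded by all
    points selected so far. Ties break toward the smaller row index, so the
    procedure is deterministic; ``seed`` is accepted for interface
    uniformity but unused.

    Returns a dict with keys ``boundary``, ``center``, ``fill`` mapping to
    disjoint lists of material ids.
    """
    n_total = n_boundary + n_center + n_fill
    if n_total > len(lib):
        raise ValueError(
            f"requested {n_total} representatives from a library of {len(lib)}"
        )
    scores = _pca_scores_2d(lib.feature_matrix())
    centroid = scores.mean(axis=0)
    ids = lib.material_ids
    remaining = list(range(len(ids)))

    def _pop_best(cands, key):
        # max by key; ties -> smallest index
        best = max(cands, key=lambda i: (key(i), -i))
        cands.remove(best)
        return best

    boundary: list[int] = []
    for _ in range(n_boundary):
        if not boundary:
            pick = _pop_best(remaining,
                             lambda i: np.linalg.norm(scores[i] - centroid))
        else:
            pick = _pop_best(
                remaining,
                lambda i: min(np.linalg.norm(scores[i] - scores[j])
                              for j in boundary),
            )
        boundary.append(pick)

    center: list[int] = []
    for _ in range(n_center):
        pick = max(remaining,
                   key=lambda i: (-np.linalg.norm(scores[i] - centroid), -i))
        remaining.remove(pick)
        center.append(pick)

    fill: list[int] = []
    anchors = boundary + center
    for _ in range(n_fill):
        pick = _pop_best(
            remaining,
            lambda i: min(np.linalg.norm(scores[i] - scores[j])
                          for j in anchors + fill),
        )
        fill.append(pick)

    return {
        "boundary": [ids[i] for i in boundary],
        "center": [ids[i] for i in center],
        "fill": [ids[i] for i in fill],
    }
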