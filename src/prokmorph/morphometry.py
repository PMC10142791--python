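"""Core trait computation: morphotype rules, biovolume, carbon, biomass.

The operational morphotype rules, applied in a fixed precedence:

1. L > 4.0 µm                 -> filamentous
2. S-shaped                   -> spirillae
3. C-shaped                   -> vibrios
4. curved (15° < turn <= 90°) -> curved rods
5. L >= 2 W                   -> rods
6. L - W < 0.10 µm            -> cocci
7. otherwise                  -> coccobacilli

Boundary conventions: a cell with L - W exactly 0.10 µm is a coccobacillus
("less than 0.10" is strict for cocci), L exactly 2W is a rod ("at least
two times"), L exactly 4.0 µm is not filamentous ("larger than" is strict).
The filament test precedes the curvature tests so a 5 µm bent cell is
filamentous; the published rules give no ordering, this one is configurable.

Biovolume uses the two-dimension capsule formula V = (π/4) W² (L − W/3),
which reduces exactly to the sphere (π/6) L³ at L = W — required for
consistency with round cells measured by a single diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import CURVATURE_CLASSES, MORPHOTYPES

FILAMENT_MIN_L_UM = 4.0
COCCI_MAX_DIFF_UM = 0.10
ROD_ASPECT = 2.0

#: volume size-class bin edges, µm³ (uniform 0.03-wide classes, open-topped)
VOLUME_CLASS_EDGES = (0.0, 0.02, 0.05, 0.08, 0.11, 0.14, 0.17, 0.20, math.inf)
LENGTH_CLASS_WIDTH_UM = 0.4


@dataclass(frozen=True)
class CellMeasure:
    """One measured cell: length, width (µm) and curvature descriptor."""

    L: float
    W: float
    curvature_class: str = "straight"

    def __post_init__(self):
        if not (self.L >= self.W > 0):
            raise ValueError(f"require L >= W > 0, got L={self.L}, W={self.W}")
        if self.curvature_class not in CURVATURE_CLASSES:
            raise ValueError(f"unknown curvature class {self.curvature_class!r}")


def classify_morphotype(cell, W=None, curvature_class="straight", *,
                        filament_min_L: float = FILAMENT_MIN_L_UM,
                        cocci_max_diff: float = COCCI_MAX_DIFF_UM,
                        rod_aspect: float = ROD_ASPECT) -> str:
    """Morphotype of one cell; accepts a CellMeasure or (L, W, curvature)."""
    if isinstance(cell, CellMeasure):
        L, W, curv = cell.L, cell.W, cell.curvature_class
    else:
        L, curv = float(cell), curvature_class
        if W is None:
            raise TypeError("W is required when L is passed as a scalar")
        CellMeasure(L, float(W), curv)  # validate invariants
        W = float(W)
    if L > filament_min_L:
        return "filamentous"
    if curv == "S":
        return "spirillae"
    if curv == "C":
        return "vibrios"
    if curv == "curved":
        return "curved_rods"
    if L >= rod_aspect * W:
        return "rods"
    if L - W < cocci_max_diff:
        return "cocci"
    return "coccobacilli"


def classify_table(df: pd.DataFrame, **thresholds) -> pd.Series:
    """Vectorised morphotype classification of a cell table.

    Expects columns ``L_um``, ``W_um`` and (optionally) ``curvature_class``.
    """
    L = df["L_um"].to_numpy(dtype=float)
    W = df["W_um"].to_numpy(dtype=float)
    if np.any(~(L >= W) | (W <= 0)):
        raise ValueError("table contains rows violating L >= W > 0")
    curv = (df["curvature_class"].to_numpy() if "curvature_class" in df
            else np.full(len(df), "straight"))
    fmin = thresholds.get("filament_min_L", FILAMENT_MIN_L_UM)
    cmax = thresholds.get("cocci_max_diff", COCCI_MAX_DIFF_UM)
    asp = thresholds.get("rod_aspect", ROD_ASPECT)
    out = np.where(L - W < cmax, "cocci", "coccobacilli")
    out = np.where(L >= asp * W, "rods", out)
    out = np.where(curv == "curved", "curved_rods", out)
    out = np.where(curv == "C", "vibrios", out)
    out = np.where(curv == "S", "spirillae", out)
    out = np.where(L > fmin, "filamentous", out)
    return pd.Series(out, index=df.index, name="morphotype")


def cell_volume(L, W):
    """Biovolume (µm³) of a capsule cell: V = (π/4) W² (L − W/3)."""
    L = np.asarray(L, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(L < W) or np.any(W <= 0):
        raise ValueError("require L >= W > 0")
    v = np.pi / 4.0 * W**2 * (L - W / 3.0)
    return float(v) if v.ndim == 0 else v


@dataclass(frozen=True)
class CarbonModel:
    """Volume-to-carbon conversion: flat (fg C µm⁻³) or allometric a·V^b."""

    kind: str = "flat"
    flat_factor: float = 350.0
    allo_a: float = 218.0
    allo_b: float = 0.86

    def __post_init__(self):
        if self.kind not in ("flat", "allometric"):
            raise ValueError(f"unknown carbon model kind {self.kind!r}")
        if min(self.flat_factor, self.allo_a, self.allo_b) <= 0:
            raise ValueError("carbon model parameters must be > 0")

    @classmethod
    def from_string(cls, spec: str) -> "CarbonModel":
        """Parse 'flat:350' or 'allometric:218:0.86'."""
        parts = spec.split(":")
        if parts[0] == "flat":
            return cls("flat", flat_factor=float(parts[1]) if len(parts) > 1 else 350.0)
        if parts[0] == "allometric":
            a = float(parts[1]) if len(parts) > 1 else 218.0
            b = float(parts[2]) if len(parts) > 2 else 0.86
            return cls("allometric", allo_a=a, allo_b=b)
        raise ValueError(f"cannot parse carbon model {spec!r}")


def cell_carbon(V, model: CarbonModel = CarbonModel()):
    """Cell carbon content (fg C) from biovolume (µm³); increasing in V."""
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("volume must be > 0")
    c = model.flat_factor * V if model.kind == "flat" else model.allo_a * V**model.allo_b
    return float(c) if c.ndim == 0 else c


def sample_biomass(PA: float, CCC_values) -> float:
    """Biomass PB (µg C/L) = PA (cells/mL) × mean CCC (fg C) × 10⁻⁶."""
    if PA < 0:
        raise ValueError("PA must be >= 0")
    if PA == 0:
        return 0.0
    ccc = np.asarray(CCC_values, dtype=float)
    if ccc.size == 0:
        raise ValueError("CCC values required when PA > 0")
    return float(PA * ccc.mean() * 1e-6)


def morphological_index(counts) -> float:
    """M = %rods / %cocci (the totals cancel); NaN when no cocci."""
    rods = float(counts.get("rods", 0))
    cocci = float(counts.get("cocci", 0))
    if cocci <= 0:
        return float("nan")
    return rods / cocci


def _volume_class_labels():
    labels = []
    edges = VOLUME_CLASS_EDGES
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f">{lo:.2f}" if math.isinf(hi) else f"{lo:.2f}-{hi:.2f}")
    return labels


def size_class_histogram(values, scheme: str = "volume") -> dict:
    """Fractional size spectrum over volume (µm³) or length (µm) classes.

    Volume classes are 0.03 µm³ wide between 0.02 and 0.20, open-topped;
    length classes are 0.4 µm wide from zero. Fractions sum to 1.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty input")
    if np.any(vals <= 0):
        raise ValueError("values must be positive")
    if scheme == "volume":
        edges = np.array(VOLUME_CLASS_EDGES)
        labels = _volume_class_labels()
    elif scheme == "length":
        n_bins = int(np.floor(vals.max() / LENGTH_CLASS_WIDTH_UM)) + 1
        edges = np.arange(n_bins + 1) * LENGTH_CLASS_WIDTH_UM
        labels = [f"{lo:.1f}-{hi:.1f}" for lo, hi in zip(edges[:-1], edges[1:])]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    hist, _ = np.histogram(vals, bins=edges)
    frac = hist / hist.sum()
    return dict(zip(labels, frac.tolist()))


@dataclass
class SampleSummary:
    """Per-sample community summary."""

    PA: float                # cells/mL
    mean_VOL: float          # µm³
    sd_VOL: float
    mean_CCC: float          # fg C/cell
    PB: float                # µg C/L
    morphotype_counts: dict
    M: float
    H_prime: float
    size_class_fractions: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"PA": self.PA, "mean_VOL": self.mean_VOL, "sd_VOL": self.sd_VOL,
               "mean_CCC": self.mean_CCC, "PB": self.PB, "M": self.M,
               "H_prime": self.H_prime}
        total = sum(self.morphotype_counts.values()) or 1
        for m in MORPHOTYPES:
            row[f"frac_{m}"] = self.morphotype_counts.get(m, 0) / total
        for label, frac in self.size_class_fractions.items():
            row[f"volclass_{label}"] = frac
        return row


def summarize_cells(cells: pd.DataFrame, PA: float,
                    carbon_model: CarbonModel = CarbonModel(),
                    shannon_base: float = 2.0) -> SampleSummary:
    """Traits and community statistics for one sample's cell table.

    ``cells`` needs columns ``L_um``, ``W_um`` and either ``morphotype`` or
    ``curvature_class`` (morphotypes are derived from the rules if absent).
    """
    from .community_stats import shannon_index

    df = cells.copy()
    if "morphotype" not in df.columns:
        df["morphotype"] = classify_table(df)
    vol = cell_volume(df["L_um"].to_numpy(), df["W_um"].to_numpy())
    ccc = cell_carbon(vol, carbon_model)
    counts = df["morphotype"].value_counts().to_dict()
    return SampleSummary(
        PA=float(PA),
        mean_VOL=float(np.mean(vol)),
        sd_VOL=float(np.std(vol)),
        mean_CCC=float(np.mean(ccc)),
        PB=sample_biomass(PA, ccc),
        morphotype_counts=counts,
        M=morphological_index(counts),
        H_prime=shannon_index(counts, base=shannon_base),
        size_class_fractions=size_class_histogram(vol, "volume"),
    )
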