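"""Synthetic cell populations and environmental covariates.

Cell dimensions are drawn per morphotype from bounded lognormals matched to
the per-cruise summary statistics (see :mod:`prokmorph._dist`). Width is
drawn conditionally on length so that every generated cell satisfies the
operational inequality that defines its own morphotype (a "coccobacillus"
with L >= 2W would be a rod by definition); the length marginal is exact,
the width marginal approximate for the constrained classes.

Curved morphotypes carry a ground-truth arc turning angle: curved rods turn
(15, 90] degrees, C-shaped vibrios (90, 270], S-shaped spirillae split
(120, 270] over two opposite arcs. For strongly curved cells the width is
additionally capped so the bent capsule does not self-intersect (curvature
radius >= ~0.55 width, end gap >= ~1.3 width), which is also a physical
constraint on real vibrio geometry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._dist import fit_bounded_lognormal
from .profiles import (ENV_TABLE, ENV_VARIABLES, MORPHOTYPE_CURVATURE,
                       CommunityProfile)

#: ground-truth arc turning ranges (degrees) per curvature class
TURNING_RANGES = {"curved": (15.0, 90.0), "C": (90.0, 270.0), "S": (120.0, 270.0)}

#: aspect-rule thresholds shared with the classifier
COCCI_MAX_DIFF_UM = 0.10
ROD_ASPECT = 2.0

CELL_COLUMNS = ("cell_id", "cruise", "station", "depth_m", "morphotype",
                "L_um", "W_um", "curvature_class", "arc_turning_deg")


def _max_feasible_width(L, turning_deg, curvature_class):
    """Upper width bound so a bent capsule of length L keeps an open lumen.

    Curvature radius >= width (inner radius >= W/2) and, for C shapes, an
    end-to-end gap of at least half a width — without these a strongly
    curled cell collapses into an unresolvable blob.
    """
    theta = np.radians(np.asarray(turning_deg, dtype=float))
    if curvature_class == "S":
        theta = theta / 2.0  # each arc of the S carries half the turning
    theta = np.maximum(theta, 1e-9)
    # (L - W)/theta >= W  ->  W <= L / (1 + theta)
    w_rad = L / (1.0 + theta)
    if curvature_class == "C":
        # chord 2 (L-W)/theta sin(theta/2) >= 1.5 W
        w_chord = L / (1.0 + 0.75 * theta / np.maximum(np.sin(theta / 2.0), 1e-9))
        return np.minimum(w_rad, w_chord)
    return w_rad


def _width_interval(morphotype, prof, L, turning_deg):
    """Per-cell [lo, hi] interval for W given L and the class-defining rules."""
    lo = np.full_like(L, prof.W_min)
    hi = np.minimum(prof.W_max, L)
    if morphotype == "coccobacilli":
        # not a rod (W > L/2) and not a coccus (L - W >= 0.10)
        lo = np.maximum(lo, L / ROD_ASPECT + 1e-9)
        hi = np.minimum(hi, L - COCCI_MAX_DIFF_UM)
    elif morphotype == "rods":
        hi = np.minimum(hi, L / ROD_ASPECT)
    elif morphotype in ("curved_rods", "vibrios", "spirillae"):
        hi = np.minimum(hi, _max_feasible_width(L, turning_deg,
                                                MORPHOTYPE_CURVATURE[morphotype]))
    return lo, hi


def sample_cells(profile: CommunityProfile, n: int, seed,
                 station: str = "synthetic", depth_m: float = 0.0) -> pd.DataFrame:
    """Draw ``n`` ground-truth cells from a community profile.

    Returns a DataFrame with one row per cell (columns ``CELL_COLUMNS``).
    Identical ``seed`` gives an identical table. Every cell satisfies
    L >= W and the per-morphotype dimension bounds.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    present = profile.present
    if not present:
        raise ValueError("composition has no morphotype with positive fraction")
    rng = np.random.default_rng(seed)
    fractions = np.array([profile.composition[m] for m in present])
    morphs = rng.choice(len(present), size=n, p=fractions / fractions.sum())

    out = {c: np.empty(n, dtype=object) for c in ("morphotype", "curvature_class")}
    L_all = np.empty(n)
    W_all = np.empty(n)
    turn_all = np.zeros(n)

    for j, m in enumerate(present):
        idx = np.flatnonzero(morphs == j)
        if idx.size == 0:
            continue
        prof = profile.profile(m)
        curv = MORPHOTYPE_CURVATURE[m]
        Ld = fit_bounded_lognormal(prof.L_mean, prof.L_sd, prof.L_min, prof.L_max)
        L = Ld.ppf(rng.random(idx.size))
        turning = np.zeros(idx.size)
        if curv in TURNING_RANGES:
            a, b = TURNING_RANGES[curv]
            turning = a + rng.random(idx.size) * (b - a)
        if m == "cocci":
            W = L.copy()
        else:
            Wd = fit_bounded_lognormal(prof.W_mean, prof.W_sd, prof.W_min, prof.W_max)
            W = np.full(idx.size, np.nan)
            todo = np.arange(idx.size)
            for _ in range(200):
                lo, hi = _width_interval(m, prof, L[todo], turning[todo])
                w = Wd.ppf_interval(rng.random(todo.size), lo, hi)
                ok = np.isfinite(w)
                W[todo[ok]] = w[ok]
                todo = todo[~ok]
                if todo.size == 0:
                    break
                # empty W interval for this L: redraw L (and turning)
                L[todo] = Ld.ppf(rng.random(todo.size))
                if curv in TURNING_RANGES:
                    a, b = TURNING_RANGES[curv]
                    turning[todo] = a + rng.random(todo.size) * (b - a)
            if todo.size:
                raise RuntimeError(
                    f"could not draw a consistent width for morphotype {m}")
        L_all[idx] = L
        W_all[idx] = np.minimum(W, L)
        turn_all[idx] = turning
        out["morphotype"][idx] = m
        out["curvature_class"][idx] = curv

    return pd.DataFrame({
        "cell_id": np.arange(n),
        "cruise": profile.cruise_label,
        "station": station,
        "depth_m": float(depth_m),
        "morphotype": out["morphotype"],
        "L_um": L_all,
        "W_um": W_all,
        "curvature_class": out["curvature_class"],
        "arc_turning_deg": turn_all,
    })


def sample_environment(cruise_label: str, n_records: int, seed,
                       depth_range=(0.0, 100.0)) -> pd.DataFrame:
    """Draw environmental covariate records for one cruise.

    Each variable follows a normal with the cruise's published mean/sd,
    truncated to the published range. Depth has no published distribution
    and is uniform on ``depth_range`` (m).
    """
    if cruise_label not in ENV_TABLE:
        raise KeyError(f"unknown cruise {cruise_label!r}")
    if n_records < 0:
        raise ValueError("n_records must be >= 0")
    rng = np.random.default_rng(seed)
    cols = {"cruise": np.repeat(cruise_label, n_records),
            "station": np.array([f"st{i + 1:03d}" for i in range(n_records)]),
            "depth_m": depth_range[0] + rng.random(n_records) * (depth_range[1] - depth_range[0])}
    for var in ENV_VARIABLES:
        mean, sd, lo, hi = ENV_TABLE[cruise_label][var]
        if sd <= 0 or hi <= lo:
            cols[var] = np.full(n_records, mean)
        else:
            a, b = (lo - mean) / sd, (hi - mean) / sd
            cols[var] = stats.truncnorm.ppf(rng.random(n_records), a, b,
                                            loc=mean, scale=sd)
    return pd.DataFrame(cols)
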