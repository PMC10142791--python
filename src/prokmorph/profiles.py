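"""Per-cruise morphotype profiles and environmental covariate ranges.

Three Mediterranean (Sicily Channel) cruises are bundled as builtin
fixtures: BANSIC-2012 and BANSIC-2013 (summer, stratified water column) and
NOVESAR-2013 (winter, mixed). Each carries per-morphotype length/width
summaries (mean, sd, min, max, µm) and per-cruise environmental covariate
ranges (temperature, salinity, oxygen, density, fluorescence, nutrients).

Morphotype relative abundances were not published; the builtin compositions
are a documented modelling choice constrained by the published morphological
index M = %rods/%cocci per cruise (0.5, 0.9 and 0.44) and by cocci, rods and
coccobacilli being the dominant classes. They are fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

MORPHOTYPES = (
    "cocci",
    "coccobacilli",
    "rods",
    "curved_rods",
    "vibrios",
    "spirillae",
    "filamentous",
)

CURVATURE_CLASSES = ("straight", "curved", "C", "S")

#: curvature class implied by each morphotype when generating cells
MORPHOTYPE_CURVATURE = {
    "cocci": "straight",
    "coccobacilli": "straight",
    "rods": "straight",
    "filamentous": "straight",
    "curved_rods": "curved",
    "vibrios": "C",
    "spirillae": "S",
}

CRUISES = ("BANSIC-2012", "NOVESAR-2013", "BANSIC-2013")


@dataclass(frozen=True)
class MorphotypeProfile:
    """Length/width summary statistics (µm) for one morphotype."""

    morphotype: str
    L_mean: float
    L_sd: float
    L_min: float
    L_max: float
    W_mean: float
    W_sd: float
    W_min: float
    W_max: float
    curvature_class: str = "straight"

    def __post_init__(self):
        if self.morphotype not in MORPHOTYPES:
            raise ValueError(f"unknown morphotype {self.morphotype!r}")
        if not (0 < self.L_min <= self.L_mean <= self.L_max):
            raise ValueError(f"{self.morphotype}: L bounds violate 0 < min <= mean <= max")
        if not (0 < self.W_min <= self.W_mean <= self.W_max):
            raise ValueError(f"{self.morphotype}: W bounds violate 0 < min <= mean <= max")
        if self.W_mean > self.L_mean:
            raise ValueError(f"{self.morphotype}: W_mean > L_mean")
        if self.L_sd < 0 or self.W_sd < 0:
            raise ValueError(f"{self.morphotype}: negative sd")


@dataclass(frozen=True)
class CommunityProfile:
    """A cruise-level community: composition plus per-morphotype profiles."""

    cruise_label: str
    composition: dict = field(default_factory=dict)  # morphotype -> fraction
    density: float = 1.0e6  # cells per mL
    profiles: tuple = ()

    def __post_init__(self):
        total = sum(self.composition.values())
        if any(v < 0 for v in self.composition.values()):
            raise ValueError("composition fractions must be >= 0")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {total}, not 1")
        if self.density <= 0:
            raise ValueError("density must be > 0")
        present = {p.morphotype for p in self.profiles}
        for m, frac in self.composition.items():
            if frac > 0 and m not in present:
                raise ValueError(f"morphotype {m} has fraction > 0 but no profile")

    def profile(self, morphotype: str) -> MorphotypeProfile:
        for p in self.profiles:
            if p.morphotype == morphotype:
                return p
        raise KeyError(morphotype)

    @property
    def present(self):
        return tuple(m for m in MORPHOTYPES if self.composition.get(m, 0) > 0)

    def restricted_to(self, morphotype: str) -> "CommunityProfile":
        """Single-morphotype community (fraction 1), keeping that profile."""
        comp = {m: (1.0 if m == morphotype else 0.0) for m in self.composition}
        comp[morphotype] = 1.0
        return replace(self, composition=comp,
                       profiles=tuple(p for p in self.profiles if p.morphotype == morphotype))


def _mp(name, Lm, Lsd, Llo, Lhi, Wm, Wsd, Wlo, Whi):
    return MorphotypeProfile(name, Lm, Lsd, Llo, Lhi, Wm, Wsd, Wlo, Whi,
                             MORPHOTYPE_CURVATURE[name])


# Per-cruise L/W summaries (µm). Cocci are round: a single diameter, W = L.
# BANSIC-2013 curved-rod W bounds are corrected to the neighbouring rods'
# range [0.15, 0.65]: the printed values duplicate the L column and are
# inconsistent with the printed W mean.
_TABLE = {
    "BANSIC-2012": [
        _mp("vibrios", 2.52, 0.57, 1.46, 4.06, 0.40, 0.11, 0.21, 0.64),
        _mp("spirillae", 2.90, 0.69, 1.39, 4.54, 0.35, 0.09, 0.21, 0.64),
        _mp("coccobacilli", 0.85, 0.19, 0.53, 1.68, 0.58, 0.12, 0.32, 1.05),
        _mp("cocci", 0.51, 0.15, 0.32, 1.38, 0.51, 0.15, 0.32, 1.38),
        _mp("rods", 1.68, 0.66, 0.64, 6.34, 0.41, 0.10, 0.21, 0.76),
        _mp("curved_rods", 1.99, 0.55, 1.07, 5.08, 0.38, 0.12, 0.21, 0.81),
    ],
    "NOVESAR-2013": [
        _mp("coccobacilli", 0.62, 0.17, 0.42, 1.70, 0.42, 0.08, 0.32, 0.95),
        _mp("cocci", 0.40, 0.09, 0.32, 0.95, 0.40, 0.09, 0.32, 0.95),
        _mp("rods", 1.01, 0.36, 0.42, 3.23, 0.32, 0.08, 0.15, 0.65),
        _mp("curved_rods", 1.38, 0.33, 0.74, 2.24, 0.26, 0.07, 0.15, 0.44),
    ],
    "BANSIC-2013": [
        _mp("vibrios", 2.23, 0.75, 1.14, 6.37, 0.36, 0.11, 0.15, 0.65),
        _mp("spirillae", 2.35, 0.73, 0.71, 3.94, 0.34, 0.09, 0.15, 0.53),
        _mp("coccobacilli", 0.69, 0.18, 0.28, 2.19, 0.46, 0.14, 0.21, 1.83),
        _mp("cocci", 0.48, 0.14, 0.30, 1.27, 0.48, 0.14, 0.30, 1.27),
        _mp("rods", 1.17, 0.43, 0.55, 2.86, 0.37, 0.11, 0.11, 0.65),
        _mp("curved_rods", 1.56, 0.50, 0.53, 3.59, 0.35, 0.10, 0.15, 0.65),
        _mp("filamentous", 3.37, 1.54, 2.04, 6.41, 0.24, 0.012, 0.21, 0.24),
    ],
}

#: published morphological index M = %rods/%cocci per cruise
_M_INDEX = {"BANSIC-2012": 0.5, "NOVESAR-2013": 0.9, "BANSIC-2013": 0.44}

# Relative weights for the non-rod, non-cocci morphotypes (cocci weight 1,
# rods weight M); chosen so cocci > rods > others and the dominant trio
# carries ~85-90% of cells. Absent morphotypes get weight 0.
_BASE_WEIGHTS = {
    "cocci": 1.0,
    "coccobacilli": 0.8,
    "curved_rods": 0.25,
    "vibrios": 0.08,
    "spirillae": 0.05,
    "filamentous": 0.04,
}


def _default_composition(cruise: str) -> dict:
    present = {p.morphotype for p in _TABLE[cruise]}
    w = {m: 0.0 for m in MORPHOTYPES}
    for m in present:
        w[m] = _M_INDEX[cruise] if m == "rods" else _BASE_WEIGHTS[m]
    total = sum(w.values())
    return {m: v / total for m, v in w.items()}


#: default cell densities (cells/mL): order 10^6, lowest in the winter
#: cruise and highest in BANSIC-2012, matching the published ordering
_DEFAULT_DENSITY = {"BANSIC-2012": 1.2e6, "NOVESAR-2013": 0.8e6, "BANSIC-2013": 1.0e6}


def builtin_cruise_profiles(density: float | None = None) -> dict:
    """The three builtin cruise communities, keyed by cruise label.

    Parameters
    ----------
    density:
        Cells per mL for every cruise; published only as an order of
        magnitude (10^6). ``None`` uses per-cruise defaults preserving the
        published ordering (BANSIC-2012 > BANSIC-2013 > NOVESAR-2013).
    """
    out = {}
    for cruise, profs in _TABLE.items():
        out[cruise] = CommunityProfile(
            cruise_label=cruise,
            composition=_default_composition(cruise),
            density=density if density is not None else _DEFAULT_DENSITY[cruise],
            profiles=tuple(profs),
        )
    return out


#: Environmental covariates: variable -> (mean, sd, min, max) per cruise.
ENV_TABLE = {
    "BANSIC-2012": {
        "T": (18.20, 4.40, 14.80, 26.90),
        "S": (38.3, 0.30, 37.3, 38.70),
        "DO": (7.30, 0.60, 6.30, 8.10),
        "DEN": (27.70, 1.29, 25.2, 28.80),
        "FLUO": (0.13, 0.11, 0.02, 0.39),
        "NO3": (0.45, 0.37, 0.13, 1.62),
        "PO4": (0.018, 0.02, 0.001, 0.070),
        "SiO4": (0.85, 0.36, 0.2, 1.58),
    },
    "NOVESAR-2013": {
        "T": (14.90, 0.08, 14.80, 15.10),
        "S": (38.4, 0.25, 38.0, 38.80),
        "DO": (7.70, 0.38, 6.90, 8.20),
        "DEN": (28.6, 0.18, 28.4, 28.90),
        "FLUO": (0.24, 0.12, 0.04, 0.38),
        "NO3": (1.26, 0.90, 0.15, 3.12),
        "PO4": (0.057, 0.042, 0.023, 0.127),
        "SiO4": (1.22, 0.37, 0.74, 1.952),
    },
    "BANSIC-2013": {
        "T": (19.65, 3.75, 14.43, 24.58),
        "S": (38.10, 0.42, 37.56, 38.71),
        "DO": (7.64, 0.46, 7.04, 8.25),
        "DEN": (27.08, 0.99, 25.50, 28.67),
        "FLUO": (0.07, 0.09, 0.01, 8.25),
        "NO3": (0.38, 0.62, 0.03, 2.43),
        "PO4": (0.02, 0.00, 0.02, 0.02),
        "SiO4": (0.81, 0.69, 0.32, 3.18),
    },
}

ENV_VARIABLES = ("T", "S", "DO", "DEN", "FLUO", "NO3", "PO4", "SiO4")
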