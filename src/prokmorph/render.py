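"""Rendering of DAPI-like epifluorescence micrographs with ground truth.

Cells are drawn as constant-width capsules around a centerline: a segment
for straight morphotypes, a single circular arc for curved rods and
C-shaped vibrios, two opposite-signed arcs for S-shaped spirillae. The
camera geometry defaults to the acquisition standard emulated here:
1300 x 1030 px at 0.106 µm/px. Pixel coverage is computed analytically
(distance to the densified centerline), the field is convolved with a
Gaussian PSF and Gaussian background noise is added.

Rendering never models cell clumping, uneven filtration, defocus or
photobleaching; cells are placed by rejection sampling with a hard
no-overlap constraint so each ground-truth record maps to one connected
component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class FieldSpec:
    """Camera field geometry and intensity model."""

    width_px: int = 1300
    height_px: int = 1030
    pixel_size: float = 0.106          # µm per px
    psf_sigma: float = 0.1             # µm; Gaussian PSF sigma
    background_level: float = 100.0    # camera offset, arbitrary units
    background_noise_sd: float = 50.0  # 5% of the default signal level
    signal_level: float = 1000.0
    border_margin: int = 10            # px kept clear of cell pixels

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("field dimensions must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")

    @property
    def field_area_mm2(self) -> float:
        return self.width_px * self.height_px * (self.pixel_size * 1e-3) ** 2

    def noise_free(self) -> "FieldSpec":
        """Copy with PSF and noise switched off (for closure checks)."""
        return FieldSpec(self.width_px, self.height_px, self.pixel_size,
                         0.0, self.background_level, 0.0,
                         self.signal_level, self.border_margin)


@dataclass(frozen=True)
class GroundTruthCell:
    id: int
    morphotype: str
    L_true: float
    W_true: float
    curvature_class: str
    centroid: tuple        # (x_px, y_px)
    orientation: float     # radians
    arc_turning: float     # degrees, 0 for straight


def centerline_points(L: float, W: float, curvature_class: str,
                      arc_turning_deg: float, spacing_um: float) -> np.ndarray:
    """Centerline polyline (µm, centred on its mean) for one cell.

    The centerline has arc length L - W; the two hemispherical caps extend
    it to total length L. A single point is returned for round cells.
    """
    c = max(L - W, 0.0)
    if c <= spacing_um / 4:
        return np.zeros((1, 2))
    n = max(int(np.ceil(c / spacing_um)) + 1, 2)
    s = np.linspace(0.0, c, n)
    theta = np.radians(arc_turning_deg)
    if curvature_class == "straight" or theta <= 1e-9:
        pts = np.column_stack([s, np.zeros_like(s)])
    elif curvature_class in ("curved", "C"):
        # constant curvature kappa = theta / c, heading h(s) = kappa * s
        kappa = theta / c
        pts = np.column_stack([np.sin(kappa * s) / kappa,
                               (1.0 - np.cos(kappa * s)) / kappa])
    elif curvature_class == "S":
        kappa = theta / c  # each half turns theta/2 with opposite sign
        ds = np.diff(s)
        heading = np.where(s[:-1] < c / 2, kappa, -kappa) * ds
        h = np.concatenate([[0.0], np.cumsum(heading)])
        x = np.concatenate([[0.0], np.cumsum(np.cos(h[:-1]) * ds)])
        y = np.concatenate([[0.0], np.cumsum(np.sin(h[:-1]) * ds)])
        pts = np.column_stack([x, y])
    else:
        raise ValueError(f"unknown curvature class {curvature_class!r}")
    return pts - pts.mean(axis=0)


def _rotate(pts, phi):
    c, s = np.cos(phi), np.sin(phi)
    return pts @ np.array([[c, s], [-s, c]])


def place_cells(cells: pd.DataFrame, field: FieldSpec, rng,
                min_gap_um: float = 0.4, max_attempts: int = 200) -> pd.DataFrame:
    """Assign non-overlapping positions/orientations to a cell table.

    Adds ``x_px``, ``y_px``, ``orientation_rad`` columns. Raises if a cell
    cannot be placed within ``max_attempts`` rejection draws (field too
    crowded).
    """
    px = field.pixel_size
    spacing = 0.3 * px  # densified centerline spacing, µm
    placed_pts = []   # list of (n_i, 2) arrays, px units
    placed_w = []     # per-point cell width, µm
    tree = None
    xs, ys, phis = [], [], []
    order = cells.index.to_numpy()
    for i in order:
        L, W = cells.at[i, "L_um"], cells.at[i, "W_um"]
        local = centerline_points(L, W, cells.at[i, "curvature_class"],
                                  float(cells.at[i, "arc_turning_deg"]), spacing)
        r_px = W / 2.0 / px
        lo_x = field.border_margin + r_px + 1
        hi_x = field.width_px - 1 - field.border_margin - r_px - 1
        lo_y = field.border_margin + r_px + 1
        hi_y = field.height_px - 1 - field.border_margin - r_px - 1
        if hi_x <= lo_x or hi_y <= lo_y:
            raise ValueError("field too small for cell dimensions")
        for attempt in range(max_attempts):
            phi = rng.random() * 2 * np.pi
            pts = _rotate(local, phi) / px  # px units, centred
            span_x = pts[:, 0].max() - pts[:, 0].min()
            span_y = pts[:, 1].max() - pts[:, 1].min()
            if lo_x + span_x / 2 >= hi_x - span_x / 2 or lo_y + span_y / 2 >= hi_y - span_y / 2:
                continue
            cx = rng.uniform(lo_x + span_x / 2 - pts[:, 0].min() - span_x / 2,
                             hi_x - (pts[:, 0].max()))
            cy = rng.uniform(lo_y - pts[:, 1].min(), hi_y - pts[:, 1].max())
            abs_pts = pts + np.array([cx, cy])
            if np.any(abs_pts[:, 0] < lo_x - r_px) or np.any(abs_pts[:, 0] > hi_x + r_px) \
               or np.any(abs_pts[:, 1] < lo_y - r_px) or np.any(abs_pts[:, 1] > hi_y + r_px):
                continue
            if tree is not None:
                d, j = tree.query(abs_pts, k=1)
                w_other = all_w[j]
                need = (W + w_other) / 2.0 + min_gap_um
                if np.any(d * px < need):
                    continue
            xs.append(cx)
            ys.append(cy)
            phis.append(phi)
            placed_pts.append(abs_pts)
            placed_w.append(np.full(len(abs_pts), W))
            all_pts = np.vstack(placed_pts)
            all_w = np.concatenate(placed_w)
            tree = cKDTree(all_pts)
            break
        else:
            raise RuntimeError(
                f"could not place cell {i} after {max_attempts} attempts")
    out = cells.copy()
    out["x_px"] = xs
    out["y_px"] = ys
    out["orientation_rad"] = phis
    return out


def render_micrograph(cells: pd.DataFrame | None, field: FieldSpec, seed,
                      min_gap_um: float = 0.4):
    """Render a micrograph and return ``(image_uint16, truth_table)``.

    ``cells`` is a ground-truth table (as from
    :func:`prokmorph.synthetic.sample_cells`); if it lacks ``x_px``/``y_px``
    columns the cells are placed by rejection sampling first. ``None`` or an
    empty table renders pure background.
    """
    rng = np.random.default_rng(seed)
    h, w = field.height_px, field.width_px
    cov = np.zeros((h, w), dtype=float)

    if cells is None:
        cells = pd.DataFrame(columns=["cell_id", "morphotype", "L_um", "W_um",
                                      "curvature_class", "arc_turning_deg"])
    cells = cells.reset_index(drop=True)
    if len(cells) and not {"x_px", "y_px"}.issubset(cells.columns):
        cells = place_cells(cells, field, rng, min_gap_um=min_gap_um)

    px = field.pixel_size
    spacing = 0.3 * px
    for i in range(len(cells)):
        L, W = cells.at[i, "L_um"], cells.at[i, "W_um"]
        local = centerline_points(L, W, cells.at[i, "curvature_class"],
                                  float(cells.at[i, "arc_turning_deg"]), spacing)
        pts = _rotate(local, float(cells.at[i, "orientation_rad"])) / px
        pts = pts + np.array([cells.at[i, "x_px"], cells.at[i, "y_px"]])
        r = W / 2.0 / px
        x0 = max(int(np.floor(pts[:, 0].min() - r - 2)), 0)
        x1 = min(int(np.ceil(pts[:, 0].max() + r + 2)) + 1, w)
        y0 = max(int(np.floor(pts[:, 1].min() - r - 2)), 0)
        y1 = min(int(np.ceil(pts[:, 1].max() + r + 2)) + 1, h)
        gx, gy = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
        grid = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
        d, _ = cKDTree(pts).query(grid, k=1)
        local_cov = np.clip(r - d + 0.5, 0.0, 1.0).reshape(gy.shape)
        np.maximum(cov[y0:y1, x0:x1], local_cov, out=cov[y0:y1, x0:x1])

    img = field.background_level + field.signal_level * cov
    if field.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, field.psf_sigma / px)
    if field.background_noise_sd > 0:
        img = img + rng.normal(0.0, field.background_noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    truth = cells.copy()
    return img, truth


def ground_truth_records(truth: pd.DataFrame):
    """View a placed truth table as :class:`GroundTruthCell` records."""
    return [GroundTruthCell(int(r.cell_id), r.morphotype, float(r.L_um),
                            float(r.W_um), r.curvature_class,
                            (float(r.x_px), float(r.y_px)),
                            float(r.orientation_rad),
                            float(r.arc_turning_deg))
            for r in truth.itertuples()]


def bead_field(n_beads: int, diameter_um: float, field: FieldSpec, seed) -> pd.DataFrame:
    """Ground-truth table for a field of monosized calibration beads."""
    return pd.DataFrame({
        "cell_id": np.arange(n_beads),
        "morphotype": "cocci",
        "L_um": diameter_um,
        "W_um": diameter_um,
        "curvature_class": "straight",
        "arc_turning_deg": 0.0,
    })
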