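"""Per-cell readouts of an equilibrium state.

Shape is summarized by the shape tensor ``S = (1/Z) sum_i z_i z_i^T`` built
from the vectors ``z_i`` running from the polygon's area centroid to its
vertices.  Its eigenvalue ratio gives the cell elongation, its major
eigenvector the cell axis; the angle between that axis and the outward
radial direction (folded to [0, 90] degrees, nematic convention) is the
angle deviation: 0 means radial, 90 circumferential alignment.

Stress is the junction-tension dyadic average plus an isotropic elastic
pressure; strain rescales the shape-tensor eigenvalues into ellipse
semi-axes and compares them with the radius of the stress-free circle of
area ``g A0``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateShapeError, InvalidPolygonError, VoromechError
from .mechanics import MechanicsParams, SimulationState
from .tessellation import BOUNDARY, EXTERIOR, polygon_centroid

#: elongation below which the major axis (and hence the angle deviation)
#: is considered undefined
DEGENERATE_ELONGATION = 1.0 + 1e-6


def shape_tensor(polygon: np.ndarray) -> np.ndarray:
    """Second-moment shape tensor of a polygon's vertices about its centroid."""
    polygon = np.asarray(polygon, dtype=float)
    if len(polygon) < 3:
        raise InvalidPolygonError("polygon needs at least 3 vertices")
    z = polygon - polygon_centroid(polygon)
    return z.T @ z / len(polygon)


def _eig_sorted(S: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Eigenvalues (major, minor) and major-axis eigenvector of a 2x2 tensor."""
    ev, evec = np.linalg.eigh(np.asarray(S, dtype=float))
    return float(ev[1]), float(ev[0]), evec[:, 1]


def elongation(S: np.ndarray) -> float:
    """Ratio of major to minor shape-tensor eigenvalue (>= 1)."""
    lam_a, lam_b, _ = _eig_sorted(S)
    if lam_b < 1e-12 * (lam_a + lam_b):
        raise DegenerateShapeError("minor eigenvalue vanishes: degenerate shape")
    return lam_a / lam_b


def angle_deviation(
    S: np.ndarray, centroid: np.ndarray, pattern_center: np.ndarray
) -> float:
    """Acute angle (degrees) between the cell's major axis and the outward
    radial direction; ``nan`` when the shape is too isotropic to orient."""
    lam_a, lam_b, major = _eig_sorted(S)
    if lam_b < 1e-12 * (lam_a + lam_b):
        raise DegenerateShapeError("degenerate shape tensor")
    if lam_a / lam_b < DEGENERATE_ELONGATION:
        return np.nan
    radial = np.asarray(centroid, dtype=float) - np.asarray(pattern_center, dtype=float)
    norm = np.linalg.norm(radial)
    if norm == 0:
        raise VoromechError("centroid coincides with the pattern center")
    cosang = abs(float(major @ (radial / norm)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def cell_stress(cell: dict, params: MechanicsParams) -> dict:
    """Average stress tensor of one cell and its radial/circumferential parts.

    ``cell`` carries ``area``, ``A0``, ``cell_class``, ``centroid``,
    ``pattern_center`` and per-junction records ``junctions`` as tuples
    ``(tension, unit_vector, length)``.  The stress is

    ``sigma = (1/A) sum_b (Lambda_b / 2) t_b t_b^T l_b
    + K_eff (A / (g_eff A0) - 1) I``.
    """
    A = cell["area"]
    if not A > 0:
        raise InvalidPolygonError("non-positive cell area")
    is_boundary = cell.get("cell_class") == BOUNDARY
    K_eff = params.rho * params.K_interior if is_boundary else params.K_interior
    g_eff = params.rho_g * params.g if is_boundary else params.g
    sigma = np.zeros((2, 2))
    for tension, t_hat, length in cell.get("junctions", ()):
        if length <= 0:
            continue
        t_hat = np.asarray(t_hat, dtype=float)
        sigma += 0.5 * tension * np.outer(t_hat, t_hat) * length
    sigma /= A
    sigma += K_eff * (A / (g_eff * cell["A0"]) - 1.0) * np.eye(2)
    radial = np.asarray(cell["centroid"]) - np.asarray(cell["pattern_center"])
    r_hat = radial / np.linalg.norm(radial)
    t_hat = np.array([-r_hat[1], r_hat[0]])
    return {
        "sigma": sigma,
        "sigma_rr": float(r_hat @ sigma @ r_hat),
        "sigma_tt": float(t_hat @ sigma @ t_hat),
    }


def cell_strains(
    S: np.ndarray, area: float, A0: float, g_eff: float
) -> tuple[float, float]:
    """Principal stretches of a cell relative to its stress-free circle.

    The shape-tensor eigenvalues are rescaled by ``sqrt(A / (pi la lb))`` so
    they act as the semi-axes of an ellipse of the cell's area, then divided
    by the stress-free radius ``sqrt(g A0 / pi)``.  An isotropic cell at
    ``A = g A0`` maps to (1, 1), and the product of the stretches always
    equals ``A / (g A0)``.
    """
    lam_a, lam_b, _ = _eig_sorted(S)
    if lam_b <= 0:
        raise DegenerateShapeError("degenerate shape tensor")
    scale = np.sqrt(area / (np.pi * lam_a * lam_b))
    r0 = np.sqrt(g_eff * A0 / np.pi)
    return float(lam_a * scale / r0), float(lam_b * scale / r0)


def summarize_state(state: SimulationState) -> pd.DataFrame:
    """One morphometric row per non-exterior cell of an equilibrated state.

    Columns: cell_id, cell_class, x, y, normalized_radius, area, elongation,
    angle_deviation_deg (nan for near-isotropic cells), eps_a, eps_b,
    sigma_rr, sigma_tt.
    """
    t = state.tessellation
    params = state.params
    cls = state.centers.cell_class
    center = np.asarray(state.pattern.center, dtype=float)
    demarc = state.demarcated
    rows = []
    for i in np.where(demarc)[0]:
        i = int(i)
        poly = t.cell_polygon(i)
        cen = polygon_centroid(poly)
        S = shape_tensor(poly)
        area = float(t.areas[i])
        g_eff = (
            params.rho_g * params.g if cls[i] == BOUNDARY else params.g
        )
        juncs = []
        for j in t.cell_junctions(i):
            other = j.cell_j if j.cell_i == i else j.cell_i
            if cls[other] == EXTERIOR or j.length <= 0:
                continue
            vec = t.vertices[j.v1] - t.vertices[j.v2]
            juncs.append((params.lam, vec / np.linalg.norm(vec), j.length))
        stress = cell_stress(
            {
                "area": area,
                "A0": float(params.A0_per_cell[i]),
                "cell_class": cls[i],
                "centroid": cen,
                "pattern_center": center,
                "junctions": juncs,
            },
            params,
        )
        eps_a, eps_b = cell_strains(S, area, float(params.A0_per_cell[i]), g_eff)
        rows.append(
            {
                "cell_id": i,
                "cell_class": cls[i],
                "x": cen[0],
                "y": cen[1],
                "normalized_radius": float(
                    np.linalg.norm(cen - center) / state.pattern.outer_radius
                ),
                "area": area,
                "elongation": elongation(S),
                "angle_deviation_deg": angle_deviation(S, cen, center),
                "eps_a": eps_a,
                "eps_b": eps_b,
                "sigma_rr": stress["sigma_rr"],
                "sigma_tt": stress["sigma_tt"],
            }
        )
    return pd.DataFrame(rows)


def group_summary(cells: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of the morphometrics per cell class.

    Near-isotropic cells (undefined orientation) are excluded from the
    angle-deviation mean; their count is reported in ``n_degenerate``.
    """
    out = []
    for cls_name, grp in cells.groupby("cell_class"):
        row = {"cell_class": cls_name, "n_cells": len(grp)}
        for col in ("area", "elongation", "eps_a", "eps_b", "sigma_rr", "sigma_tt"):
            row[f"{col}_mean"] = grp[col].mean()
            row[f"{col}_sem"] = grp[col].sem()
        ang = grp["angle_deviation_deg"].dropna()
        row["angle_deviation_deg_mean"] = ang.mean()
        row["angle_deviation_deg_sem"] = ang.sem()
        row["n_degenerate"] = int(grp["angle_deviation_deg"].isna().sum())
        out.append(row)
    return pd.DataFrame(out)
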