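"""Shrake-Rupley solvent-accessible surface area and buried-surface metrics.

The sphere point set is a deterministic golden-section spiral lattice (no
RNG), so areas are bit-reproducible across runs.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from coopfold.structure_metrics.model import VDW_RADII, Selection, StructureModel

__all__ = ["sphere_points", "shrake_rupley_sasa", "buried_surface_area"]


def sphere_points(n: int) -> np.ndarray:
    """n points quasi-uniform on the unit sphere (golden spiral lattice)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _radii_for(model: StructureModel, fallback: float | None) -> np.ndarray:
    radii = np.empty(len(model))
    for i, atom in enumerate(model.atoms):
        r = VDW_RADII.get(atom.element.upper())
        if r is None:
            if fallback is None:
                raise ValueError(
                    f"no van der Waals radius for element {atom.element!r} "
                    "and no fallback configured"
                )
            r = fallback
        radii[i] = r
    return radii


def shrake_rupley_sasa(
    model: StructureModel,
    probe: float = 1.4,
    n_sphere_points: int = 960,
    fallback_radius: float | None = 1.70,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Angstrom^2).

    Counts, per atom, the fraction of ``n_sphere_points`` test points on the
    expanded sphere (r_vdw + probe) not occluded by any neighbour's expanded
    sphere, and scales by the sphere area.
    """
    coords = model.coords
    radii = _radii_for(model, fallback_radius) + probe
    n = coords.shape[0]
    unit = sphere_points(n_sphere_points)

    tree = cKDTree(coords)
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        neighbours = [
            j for j in tree.query_ball_point(coords[i], radii[i] + radii.max())
            if j != i
            and np.dot(coords[j] - coords[i], coords[j] - coords[i])
            < (radii[i] + radii[j]) ** 2
        ]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 >= radii[j] * radii[j]
            if not accessible.any():
                break
        frac = accessible.mean()
        areas[i] = frac * 4.0 * math.pi * radii[i] * radii[i]
    return areas


def buried_surface_area(
    model: StructureModel,
    part_a: Selection | str,
    part_b: Selection | str,
    probe: float = 1.4,
    n_sphere_points: int = 960,
    fallback_radius: float | None = 1.70,
) -> float:
    """BSA = SASA(A alone) + SASA(B alone) - SASA(A and B together).

    The two selections must be disjoint.  Negative values from point-count
    noise are clipped at zero.
    """
    a = model.select(part_a)
    b = model.select(part_b)
    keys_a = {(x.chain, x.resnum, x.icode, x.name) for x in a.atoms}
    keys_b = {(x.chain, x.resnum, x.icode, x.name) for x in b.atoms}
    if keys_a & keys_b:
        raise ValueError("part_a and part_b overlap")
    combined = StructureModel(atoms=a.atoms + b.atoms, label=model.label)
    kwargs = dict(
        probe=probe, n_sphere_points=n_sphere_points, fallback_radius=fallback_radius
    )
    sasa_a = float(shrake_rupley_sasa(a, **kwargs).sum())
    sasa_b = float(shrake_rupley_sasa(b, **kwargs).sum())
    sasa_ab = float(shrake_rupley_sasa(combined, **kwargs).sum())
    return max(sasa_a + sasa_b - sasa_ab, 0.0)
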