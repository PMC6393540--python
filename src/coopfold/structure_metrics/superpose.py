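"""Kabsch superposition and derived rigid-body metrics."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from coopfold.structure_metrics.model import (
    ATOM_SETS,
    Selection,
    StructureModel,
)

__all__ = [
    "SuperpositionResult",
    "kabsch_superpose",
    "kabsch_rotation",
    "backbone_rmsd",
    "com_distance",
    "relative_rotation",
    "rotation_angle_deg",
    "pair_atoms",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform (mobile -> reference) and the resulting RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        if rot.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if abs(np.linalg.det(rot) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_rotation(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rotation/translation mapping mobile onto reference.

    SVD-based Kabsch with a reflection guard (the smallest singular
    direction is flipped when det < 0, so the result is always a proper
    rotation).  Returns (R, t, rmsd) with x_ref ~ R x_mob + t.
    """
    p = np.asarray(mobile, dtype=float)
    q = np.asarray(reference, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (N, 3) arrays")
    if p.shape[0] < 3:
        raise ValueError("need at least 3 paired points")
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    t = qc - rot @ pc
    moved = p @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return rot, t, rmsd


def pair_atoms(
    mobile: StructureModel,
    reference: StructureModel,
    pairing: str = "by-position",
    residue_map: dict[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired coordinate arrays for superposition.

    ``by-position`` pairs the i-th atom of each selection; ``by-residue-number``
    pairs atoms sharing (residue number, atom name), optionally translating
    reference residue numbers to mobile ones through ``residue_map``
    (reference resnum -> mobile resnum).  Unmatched residues raise, listing
    the offenders.
    """
    if pairing == "by-position":
        if len(mobile) != len(reference):
            raise ValueError(
                f"by-position pairing needs equal atom counts "
                f"({len(mobile)} vs {len(reference)})"
            )
        return mobile.coords, reference.coords
    if pairing != "by-residue-number":
        raise ValueError(f"unknown pairing mode {pairing!r}")

    mob_index = {(a.resnum, a.icode, a.name): i for i, a in enumerate(mobile.atoms)}
    mob_rows, ref_rows = [], []
    missing: list[tuple[int, str]] = []
    for j, a in enumerate(reference.atoms):
        resnum = a.resnum
        if residue_map is not None:
            if resnum not in residue_map:
                continue  # residues absent from the map are simply skipped
            resnum = residue_map[resnum]
        key = (resnum, a.icode, a.name)
        if key in mob_index:
            mob_rows.append(mob_index[key])
            ref_rows.append(j)
        else:
            missing.append((a.resnum, a.name))
    if not mob_rows:
        raise ValueError("no atom pairs found with by-residue-number pairing")
    if missing and residue_map is None:
        unmatched = sorted({r for r, _ in missing})
        raise ValueError(f"unmatched residues in pairing: {unmatched}")
    return mobile.coords[mob_rows], reference.coords[ref_rows]


def kabsch_superpose(
    mobile: StructureModel,
    reference: StructureModel,
    mobile_selection: Selection | str | None = None,
    reference_selection: Selection | str | None = None,
    pairing: str = "by-position",
    residue_map: dict[int, int] | None = None,
) -> SuperpositionResult:
    """Superpose selected atoms of ``mobile`` onto ``reference``."""
    mob = mobile.select(mobile_selection) if mobile_selection else mobile
    ref = reference.select(reference_selection) if reference_selection else reference
    p, q = pair_atoms(mob, ref, pairing=pairing, residue_map=residue_map)
    rot, t, rmsd = kabsch_rotation(p, q)
    return SuperpositionResult(rotation=rot, translation=t, rmsd=rmsd, n_pairs=p.shape[0])


def backbone_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    selection_a: Selection | str,
    selection_b: Selection | str,
    pairing: str = "by-residue-number",
    residue_map: dict[int, int] | None = None,
) -> float:
    """Superposed backbone (N, CA, C, O) RMSD between two selections.

    ``residue_map`` maps residue numbers of ``model_a``'s selection to those
    of ``model_b`` for cross-protein comparisons.
    """
    backbone = ATOM_SETS["backbone"]
    sel_a = Selection.parse(selection_a) if isinstance(selection_a, str) else selection_a
    sel_b = Selection.parse(selection_b) if isinstance(selection_b, str) else selection_b
    if sel_a.atom_names is None:
        sel_a = Selection(sel_a.chains, sel_a.residue_ranges, backbone)
    if sel_b.atom_names is None:
        sel_b = Selection(sel_b.chains, sel_b.residue_ranges, backbone)
    result = kabsch_superpose(
        model_b.select(sel_b),
        model_a.select(sel_a),
        pairing=pairing,
        residue_map=residue_map,
    )
    return result.rmsd


def com_distance(
    model: StructureModel,
    selection_a: Selection | str,
    selection_b: Selection | str,
    weighting: str = "uniform",
) -> float:
    """Distance between the centroids of two selections (Angstrom)."""
    a = model.select(selection_a)
    b = model.select(selection_b)
    if weighting == "uniform":
        ca = a.coords.mean(axis=0)
        cb = b.coords.mean(axis=0)
    elif weighting == "mass":
        wa = a.masses()
        wb = b.masses()
        ca = (wa[:, None] * a.coords).sum(axis=0) / wa.sum()
        cb = (wb[:, None] * b.coords).sum(axis=0) / wb.sum()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return float(np.linalg.norm(ca - cb))


def rotation_angle_deg(rotation: np.ndarray) -> float:
    """Rotation angle of a proper rotation matrix: arccos((trace - 1)/2)."""
    tr = float(np.trace(np.asarray(rotation, dtype=float)))
    return math.degrees(math.acos(min(1.0, max(-1.0, (tr - 1.0) / 2.0))))


def relative_rotation(
    complex1: StructureModel,
    complex2: StructureModel,
    align_on: tuple[Selection | str, Selection | str],
    measure: tuple[Selection | str, Selection | str],
    pairing: str = "by-residue-number",
    align_residue_map: dict[int, int] | None = None,
    measure_residue_map: dict[int, int] | None = None,
) -> dict[str, float]:
    """Inter-domain rotation between two complexes after alignment.

    Superposes ``complex2`` onto ``complex1`` using the ``align_on``
    selection pair, then finds the optimal rotation mapping the measured
    selection of complex1 onto the (aligned) measured selection of
    complex2.  Returns the rotation angle in degrees and the displacement
    between the measured centroids after alignment.

    Residue maps translate complex1 residue numbers to complex2 numbers for
    cross-protein comparisons.
    """
    sel1_align, sel2_align = align_on
    sel1_meas, sel2_meas = measure
    # pair_atoms maps reference (complex1) residue numbers to mobile
    # (complex2) numbers, which is the direction align_residue_map uses.
    align = kabsch_superpose(
        complex2.select(sel2_align),
        complex1.select(sel1_align),
        pairing=pairing,
        residue_map=align_residue_map,
    )
    meas1 = complex1.select(sel1_meas)
    meas2 = complex2.select(sel2_meas).transformed(align.rotation, align.translation)
    p, q = pair_atoms(
        meas1, meas2, pairing=pairing, residue_map=_invert(measure_residue_map)
    )
    rot, _, _ = kabsch_rotation(p, q)
    angle = rotation_angle_deg(rot)
    displacement = float(
        np.linalg.norm(meas1.coords.mean(axis=0) - meas2.coords.mean(axis=0))
    )
    return {"angle_deg": angle, "com_displacement_A": displacement}


def _invert(mapping: dict[int, int] | None) -> dict[int, int] | None:
    if mapping is None:
        return None
    return {v: k for k, v in mapping.items()}
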