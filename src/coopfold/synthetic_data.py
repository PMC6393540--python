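"""Seeded generators for every input the pipeline needs.

All generators are pure functions of (spec, seed): regenerating with the
same arguments is byte-identical.  File-emitting fixtures write a
ground-truth sidecar JSON next to the data so downstream recovery tests
never hard-code expected values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from coopfold.itc_binding import (
    BindingParameters,
    TitrationExperiment,
    TitrationProtocol,
    simulate_isotherm,
)
from coopfold.io_cli.formats import write_itc_csv, write_saxs_dat
from coopfold.saxs_analysis.debye import debye_profile, rg_from_coords
from coopfold.saxs_analysis.ensemble import BeadEnsemble, generate_tail_conformers
from coopfold.saxs_analysis.profiles import ScatteringProfile
from coopfold.structure_metrics.model import Atom, StructureModel, write_pdb

__all__ = [
    "OperatorVariant",
    "OPERATOR_VARIANTS",
    "reverse_complement",
    "make_itc_fixture",
    "make_globular_body",
    "make_rigid_plus_tail_system",
    "make_toy_structures",
    "write_operator_fixtures",
    "build_ideal_helix",
    "rotation_about_axis",
]


# ---------------------------------------------------------------------------
# Operator sequence fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperatorVariant:
    """One operator variant: mutations lowercase, palindrome marked by slice.

    ``offset`` aligns the (possibly truncated) variant against the
    wild-type 33-mer.  ``ka`` (M^-2) and ``dh`` (kcal/mol) are the measured
    binding parameters where determined.
    """

    name: str
    sequence: str
    offset: int = 0
    ka: float | None = None
    dh: float | None = None


WILD_TYPE_OPERATOR = "AAATTAACGAATAACGTTAAGCATTCAGCTCAT"
CENTRAL_PALINDROME = "TAACGTTA"

OPERATOR_VARIANTS: tuple[OperatorVariant, ...] = (
    OperatorVariant("wild_type", WILD_TYPE_OPERATOR, 0, 3.0e13, -19.0),
    OperatorVariant("variant_1", "AAATTAACGAATAACGggccGCATTCAGCT", 0, 2.1e9, None),
    OperatorVariant("variant_2", "AAATTAACGAAgccCGTTAAGCcggCAGCT", 0, 4.7e11, -5.2),
    OperatorVariant("variant_3", "AAATTAACGAATAgtGTTAAGCATTCAGCT", 0, 3.9e11, -5.6),
    OperatorVariant("variant_4", "AAAggcACGAATAACGTTAAGCATTCAGCT", 0, 4.3e13, -14.6),
    OperatorVariant("variant_5", "AAATTAACGccgAACGTTAAGCATTCAGC", 0, 7.1e12, -15.4),
    OperatorVariant("variant_6", "AAATTAACGAATAACGTTAAGCcggCAGCT", 0, 1.5e13, -14.8),
    OperatorVariant("left_side_mirrored", "AAATTAACGAATAACGTTAttcgttaattt", 0, 5.2e12, -23.4),
    OperatorVariant("right_side_mirrored", "agctgaatgctTAACGTTAAGCATTCAGCT", 0, 3.5e12, -26.7),
    OperatorVariant("central_palindrome", "GAATAACGTTAAG", 8, None, None),
    OperatorVariant("upstream_half", "AAATTAACGAATAACGTTAAG", 0, None, None),
    OperatorVariant("downstream_half", "AATAACGTTAAGCATTCAGCT", 9, None, None),
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string, preserving letter case."""
    bad = set(sequence) - set("ACGTacgt")
    if bad:
        raise ValueError(f"not a DNA sequence, offending characters: {sorted(bad)}")
    return sequence.translate(_COMPLEMENT)[::-1]


def write_operator_fixtures(path: str | Path) -> list[OperatorVariant]:
    """Emit the operator variant table as FASTA (each duplex: both strands).

    Validates that the central palindrome is its own reverse complement and
    that every variant's uppercase positions match the wild type.
    """
    if reverse_complement(CENTRAL_PALINDROME) != CENTRAL_PALINDROME:
        raise AssertionError("central palindrome must be self-reverse-complementary")
    for var in OPERATOR_VARIANTS:
        for k, base in enumerate(var.sequence):
            if base.isupper() and base != WILD_TYPE_OPERATOR[var.offset + k]:
                raise AssertionError(
                    f"{var.name}: uppercase position {k} disagrees with wild type"
                )
    records = []
    for var in OPERATOR_VARIANTS:
        records.append(f">{var.name} offset={var.offset}")
        records.append(var.sequence)
        records.append(f">{var.name}_complement")
        records.append(reverse_complement(var.sequence))
    Path(path).write_text("\n".join(records) + "\n")
    return list(OPERATOR_VARIANTS)


# ---------------------------------------------------------------------------
# ITC fixtures
# ---------------------------------------------------------------------------

def make_itc_fixture(
    params: BindingParameters,
    protocol: TitrationProtocol,
    noise_sd: float,
    seed: int,
    path: str | Path,
) -> TitrationExperiment:
    """Simulate one isotherm and write it as CSV with a truth sidecar."""
    exp = simulate_isotherm(params, protocol, noise_sd=noise_sd, seed=seed)
    path = Path(path)
    write_itc_csv(exp, path, extra_meta={"noise_sd": repr(noise_sd)})
    truth = {
        "K_A": params.ka,
        "dH_kcal_mol": params.dh,
        "offset_kcal_mol": params.offset,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    path.with_suffix(path.suffix + ".truth.json").write_text(
        json.dumps(truth, indent=2) + "\n"
    )
    return exp


# ---------------------------------------------------------------------------
# SAXS bead fixtures
# ---------------------------------------------------------------------------

def make_globular_body(radius: float, n_beads: int, seed: int = 0) -> np.ndarray:
    """Beads uniform in a sphere of given radius (seeded rejection sampling)."""
    if n_beads < 10:
        raise ValueError("n_beads must be >= 10")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    rng = np.random.default_rng(seed)
    out = np.empty((n_beads, 3))
    filled = 0
    while filled < n_beads:
        cand = rng.uniform(-radius, radius, size=(2 * (n_beads - filled) + 16, 3))
        keep = cand[np.einsum("ij,ij->i", cand, cand) <= radius * radius]
        take = min(keep.shape[0], n_beads - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def make_rigid_plus_tail_system(
    body_radius: float = 15.0,
    n_body: int = 80,
    n_tail: int = 22,
    n_conformers: int = 50,
    seed: int = 0,
    q_grid: np.ndarray | None = None,
    mixture: dict[int, float] | None = None,
    noise_a_fraction: float = 1e-4,
    noise_b: float = 0.01,
    out_dir: str | Path | None = None,
) -> tuple[BeadEnsemble, ScatteringProfile, dict]:
    """Globular body + flexible-tail conformer pool + noisy mixture curve.

    The designated mixture (default: the two most compact conformers at
    0.7/0.3) is summed from noise-free member profiles, then q-dependent
    Gaussian noise sigma(q) = a + b*I(q) is added with a = ``noise_a_fraction``
    * I(0).  When ``out_dir`` is given, writes ``mixture.dat`` plus a
    ``truth.json`` sidecar with the true weights and member Rg values.
    """
    if q_grid is None:
        q_grid = np.linspace(0.008, 0.4, 80)
    body = make_globular_body(body_radius, n_body, seed=seed)
    # anchor: bead closest to the surface along +x, so tails point outward
    anchor = int(np.argmax(body[:, 0]))
    ensemble = generate_tail_conformers(
        body, anchor_index=anchor, n_tail=n_tail,
        n_conformers=n_conformers, seed=seed + 1,
    )
    profiles = [debye_profile(m, q_grid) for m in ensemble.members]

    if mixture is None:
        rgs = ensemble.member_rg()
        order = np.argsort(rgs)
        mixture = {int(order[0]): 0.7, int(order[-1]): 0.3}
    if abs(sum(mixture.values()) - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    i_mix = np.zeros_like(q_grid)
    for idx, w in mixture.items():
        i_mix += w * profiles[idx].i
    sigma = noise_a_fraction * i_mix[0] + noise_b * i_mix
    # sigma must stay positive even for a nominally noise-free fixture
    sigma = np.maximum(sigma, 1e-12 * max(i_mix[0], 1.0))
    rng = np.random.default_rng(seed + 2)
    noise = rng.normal(0.0, 1.0, size=q_grid.size) * sigma
    if noise_a_fraction == 0.0 and noise_b == 0.0:
        noise = np.zeros_like(q_grid)
    noisy = ScatteringProfile(
        q=q_grid,
        i=i_mix + noise,
        sigma=sigma,
        comments=(f"synthetic tail-ensemble mixture, seed={seed}",),
    )
    truth = {
        "seed": seed,
        "mixture": {str(k): v for k, v in mixture.items()},
        "member_rg": [float(rg_from_coords(m)) for m in ensemble.members],
        "n_body": n_body,
        "n_tail": n_tail,
        "body_radius": body_radius,
        "anchor_index": anchor,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_saxs_dat(noisy, out_dir / "mixture.dat")
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return ensemble, noisy, truth


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

def build_ideal_helix(
    n_residues: int,
    chain: str = "A",
    start_resnum: int = 1,
    origin: np.ndarray | None = None,
    axis_direction: str = "z",
) -> StructureModel:
    """CA-only ideal alpha helix: radius 2.3 A, rise 1.5 A, 100 deg/residue."""
    if n_residues < 1:
        raise ValueError("need at least one residue")
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    atoms = []
    for k in range(n_residues):
        ang = math.radians(100.0 * k)
        local = np.array([2.3 * math.cos(ang), 2.3 * math.sin(ang), 1.5 * k])
        if axis_direction == "x":
            local = local[[2, 0, 1]]
        elif axis_direction == "y":
            local = local[[1, 2, 0]]
        pos = origin + local
        atoms.append(
            Atom(chain, start_resnum + k, "", "ALA", "CA", "C",
                 float(pos[0]), float(pos[1]), float(pos[2]))
        )
    return StructureModel(atoms=tuple(atoms), label=f"helix_{chain}")


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis must be non-zero")
    k = axis / norm
    a = math.radians(angle_deg)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(a) * kx + (1.0 - math.cos(a)) * (kx @ kx)


def make_toy_structures(
    seed: int = 0,
    out_dir: str | Path | None = None,
    helix_separation: float = 30.0,
    domain_rotation_deg: float = 25.0,
    domain_displacement: float = 6.8,
) -> dict[str, StructureModel | dict]:
    """Toy PDB fixtures with exactly known geometric ground truth.

    Emits (a) a helix pair at an exact centroid separation, (b) a two-domain
    complex pair where the second copy has one domain rotated by an exact
    angle about its centroid and displaced by an exact distance, and (c) a
    rigid-transformed copy of a random cloud for RMSD-zero checks.
    """
    rng = np.random.default_rng(seed)

    helix_a = build_ideal_helix(11, chain="A")
    centroid = helix_a.coords.mean(axis=0)
    shift = np.array([helix_separation, 0.0, 0.0])
    helix_b_atoms = tuple(
        Atom("B", a.resnum, "", a.resname, a.name, a.element,
             a.x + shift[0], a.y + shift[1], a.z + shift[2])
        for a in helix_a.atoms
    )
    helix_pair = StructureModel(
        atoms=helix_a.atoms + helix_b_atoms, label="helix_pair"
    )

    # two-domain complex: anchor domain A (helix) + mobile domain B (cloud)
    cloud = rng.normal(scale=4.0, size=(24, 3)) + np.array([18.0, 0.0, 6.0])
    domain_b_atoms = tuple(
        Atom("B", k + 1, "", "GLY", "CA", "C", float(p[0]), float(p[1]), float(p[2]))
        for k, p in enumerate(cloud)
    )
    complex1 = StructureModel(
        atoms=helix_a.atoms + domain_b_atoms, label="complex1"
    )
    rot = rotation_about_axis(np.array([0.3, 1.0, 0.2]), domain_rotation_deg)
    b_centroid = cloud.mean(axis=0)
    disp = np.array([0.0, domain_displacement, 0.0])
    cloud2 = (cloud - b_centroid) @ rot.T + b_centroid + disp
    domain_b2_atoms = tuple(
        Atom("B", k + 1, "", "GLY", "CA", "C", float(p[0]), float(p[1]), float(p[2]))
        for k, p in enumerate(cloud2)
    )
    complex2 = StructureModel(
        atoms=helix_a.atoms + domain_b2_atoms, label="complex2"
    )

    # rigid-transformed copy of a random cloud
    cloud_c = rng.normal(scale=5.0, size=(20, 3))
    model_c = StructureModel(
        atoms=tuple(
            Atom("A", k + 1, "", "GLY", "CA", "C",
                 float(p[0]), float(p[1]), float(p[2]))
            for k, p in enumerate(cloud_c)
        ),
        label="cloud",
    )
    rot_c = rotation_about_axis(np.array([1.0, 2.0, -1.0]), 37.0)
    model_c_moved = model_c.transformed(rot_c, np.array([5.0, -3.0, 2.0]))

    truth = {
        "seed": seed,
        "helix_separation": helix_separation,
        "domain_rotation_deg": domain_rotation_deg,
        "domain_displacement": domain_displacement,
        "cloud_rotation_deg": 37.0,
        "helix_a_centroid": centroid.tolist(),
    }
    out = {
        "helix_pair": helix_pair,
        "complex1": complex1,
        "complex2": complex2,
        "cloud": model_c,
        "cloud_transformed": model_c_moved,
        "truth": truth,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("helix_pair", "complex1", "complex2", "cloud", "cloud_transformed"):
            write_pdb(out[name], out_dir / f"{name}.pdb")
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return out
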