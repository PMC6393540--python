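"""Coarse-grained Debye scattering from bead coordinates.

One bead per residue with a constant form factor is plenty for the low-q
(q < ~0.3 A^-1) disorder diagnostics this package targets; the double sum
is evaluated exactly (no distance binning) in q-chunks to bound memory.
"""

from __future__ import annotations

import numpy as np

from coopfold.saxs_analysis.profiles import ScatteringProfile

__all__ = ["debye_profile", "rg_from_coords", "pairwise_distances"]


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Condensed upper-triangle distances of an (N, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    diff = coords[iu] - coords[ju]
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def debye_profile(
    beads: np.ndarray,
    q_grid: np.ndarray,
    form_factor: float | np.ndarray = 1.0,
    chunk: int = 32,
) -> ScatteringProfile:
    """Exact Debye double-sum profile of a bead model.

    I(q) = sum_ij f_i f_j sinc(q r_ij); I(0) = (sum f)^2.

    Parameters
    ----------
    beads : (N, 3) array
        Bead coordinates in Angstrom, N >= 1.
    q_grid : 1-D array
        Scattering vector magnitudes, A^-1, strictly increasing, > 0.
    form_factor : float or (N,) array
        Constant per-bead scattering weight.
    chunk : int
        Number of q values evaluated per vectorized block.
    """
    coords = np.atleast_2d(np.asarray(beads, dtype=float))
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise ValueError("beads must be an (N, 3) array with N >= 1")
    q = np.asarray(q_grid, dtype=float)
    f = np.broadcast_to(np.asarray(form_factor, dtype=float), (coords.shape[0],))

    self_term = float(np.sum(f * f))
    n = coords.shape[0]
    if n == 1:
        return ScatteringProfile(q=q, i=np.full(q.size, self_term))

    iu, ju = np.triu_indices(n, k=1)
    d = pairwise_distances(coords)
    ff = f[iu] * f[ju]

    intensity = np.empty(q.size)
    tiny = d < 1e-12  # coincident beads: sinc -> 1
    for lo in range(0, q.size, chunk):
        qc = q[lo : lo + chunk, None]
        y = qc * d[None, :]
        kernel = np.sin(y)
        kernel /= np.where(y > 0, y, 1.0)
        if tiny.any():
            kernel[:, tiny] = 1.0
        intensity[lo : lo + chunk] = self_term + 2.0 * (kernel @ ff)
    return ScatteringProfile(q=q, i=intensity)


def rg_from_coords(
    beads: np.ndarray, masses: np.ndarray | None = None
) -> float:
    """Radius of gyration: mass-weighted RMS distance from the centroid."""
    coords = np.atleast_2d(np.asarray(beads, dtype=float))
    if coords.shape[0] < 1 or coords.shape[1] != 3:
        raise ValueError("beads must be an (N, 3) array with N >= 1")
    if masses is None:
        w = np.ones(coords.shape[0])
    else:
        w = np.asarray(masses, dtype=float)
        if w.shape != (coords.shape[0],) or np.any(w <= 0):
            raise ValueError("masses must be positive, one per bead")
    w = w / w.sum()
    center = w @ coords
    d2 = np.einsum("ij,ij->i", coords - center, coords - center)
    return float(np.sqrt(w @ d2))
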