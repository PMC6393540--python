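"""Flexible-tail conformer pools and multi-state ensemble fitting.

A rigid coarse-grained body gets a self-avoiding random tail appended bead
by bead; pools of such conformers are fitted against an experimental curve
as weighted k-state mixtures (non-negative least squares per candidate
subset, exact enumeration for small pools, beam search otherwise).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from coopfold.saxs_analysis.debye import rg_from_coords
from coopfold.saxs_analysis.profiles import ScatteringProfile

__all__ = [
    "BeadEnsemble",
    "MultiStateFit",
    "generate_tail_conformers",
    "multistate_enumerate",
    "rg_distribution",
]

TAIL_BOND_LENGTH = 3.8  # Angstrom, CA-CA virtual bond


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadEnsemble:
    """A pool of same-size bead conformers with simplex weights.

    ``rigid_range`` / ``tail_range`` are half-open index ranges into each
    member identifying the shared rigid body and the sampled tail.
    """

    members: tuple[np.ndarray, ...]
    weights: np.ndarray
    rigid_range: tuple[int, int]
    tail_range: tuple[int, int]
    seed: int | None = None

    def __post_init__(self) -> None:
        members = tuple(np.asarray(m, dtype=float) for m in self.members)
        if not members:
            raise ValueError("ensemble needs at least one member")
        n = members[0].shape[0]
        for m in members:
            if m.ndim != 2 or m.shape[1] != 3:
                raise ValueError("members must be (N, 3) arrays")
            if m.shape[0] != n:
                raise ValueError("all members must share the bead count")
        object.__setattr__(self, "members", members)
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(members),):
            raise ValueError("one weight per member required")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def n_beads(self) -> int:
        return self.members[0].shape[0]

    def member_rg(self) -> np.ndarray:
        return np.array([rg_from_coords(m) for m in self.members])


@dataclass(frozen=True)
class MultiStateFit:
    """Best k-state models for k = 1..max_states against one experiment."""

    best_by_k: dict[int, dict] = field(default_factory=dict)

    def best(self) -> dict:
        """Overall best model (lowest chi2; ties go to smaller k)."""
        return min(
            self.best_by_k.values(), key=lambda m: (m["chi2"], m["k"])
        )

    def chi2_by_k(self) -> dict[int, float]:
        return {k: m["chi2"] for k, m in sorted(self.best_by_k.items())}


# ---------------------------------------------------------------------------
# Tail conformer generation
# ---------------------------------------------------------------------------

def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    norm = np.linalg.norm(v)
    while norm < 1e-12:
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
    return v / norm


def generate_tail_conformers(
    rigid: np.ndarray,
    anchor_index: int,
    n_tail: int,
    n_conformers: int,
    seed: int = 0,
    bond: float = TAIL_BOND_LENGTH,
    clash_radius: float = 2.0,
    max_bead_retries: int = 200,
    max_chain_restarts: int = 100,
) -> BeadEnsemble:
    """Append self-avoiding random tails to a rigid bead body.

    Each tail bead extends the chain by ``bond`` Angstrom in a uniformly
    random direction, rejecting positions within ``clash_radius`` of the
    rigid body or previous tail beads.  Bead placement retries are bounded;
    exhausting them restarts the whole chain, and exhausting restarts
    raises.  Deterministic for a given seed.
    """
    rigid = np.asarray(rigid, dtype=float)
    if rigid.ndim != 2 or rigid.shape[1] != 3:
        raise ValueError("rigid must be an (N, 3) array")
    if not 0 <= anchor_index < rigid.shape[0]:
        raise ValueError("anchor_index out of range")
    if n_tail < 0 or n_conformers < 1:
        raise ValueError("n_tail must be >= 0 and n_conformers >= 1")

    rng = np.random.default_rng(seed)
    n_rigid = rigid.shape[0]
    members: list[np.ndarray] = []
    for _ in range(n_conformers):
        if n_tail == 0:
            members.append(rigid.copy())
            continue
        tail = _grow_tail(
            rigid, anchor_index, n_tail, rng, bond, clash_radius,
            max_bead_retries, max_chain_restarts,
        )
        members.append(np.vstack([rigid, tail]))

    k = len(members)
    return BeadEnsemble(
        members=tuple(members),
        weights=np.full(k, 1.0 / k),
        rigid_range=(0, n_rigid),
        tail_range=(n_rigid, n_rigid + n_tail),
        seed=seed,
    )


def _grow_tail(
    rigid: np.ndarray,
    anchor_index: int,
    n_tail: int,
    rng: np.random.Generator,
    bond: float,
    clash_radius: float,
    max_bead_retries: int,
    max_chain_restarts: int,
) -> np.ndarray:
    r2 = clash_radius * clash_radius
    for _ in range(max_chain_restarts):
        tail = np.empty((n_tail, 3))
        prev = rigid[anchor_index]
        ok = True
        for j in range(n_tail):
            placed = False
            for _ in range(max_bead_retries):
                cand = prev + bond * _random_unit_vector(rng)
                # self-clash: rigid body (anchor excluded) and earlier tail
                d_rigid = np.einsum(
                    "ij,ij->i", rigid - cand, rigid - cand
                )
                d_rigid[anchor_index] = np.inf
                if np.any(d_rigid < r2):
                    continue
                if j > 0:
                    seg = tail[: j - 1] if j > 1 else np.empty((0, 3))
                    if seg.size:
                        d_tail = np.einsum("ij,ij->i", seg - cand, seg - cand)
                        if np.any(d_tail < r2):
                            continue
                tail[j] = cand
                prev = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return tail
    raise RuntimeError(
        f"tail growth failed: persistent clashes near bead {anchor_index} "
        f"after {max_chain_restarts} chain restarts"
    )


# ---------------------------------------------------------------------------
# Multi-state enumeration
# ---------------------------------------------------------------------------

def _fit_subset(
    design: np.ndarray, target: np.ndarray, subset: tuple[int, ...]
) -> tuple[np.ndarray, float, float]:
    """NNLS weights for one candidate subset; returns (weights, scale, chi2).

    ``design`` holds sigma-whitened model intensities column-wise and
    ``target`` the whitened experimental intensities, so the NNLS
    coefficients a_i jointly encode scale c = sum(a) and simplex weights
    w = a / c.
    """
    a, _ = nnls(design[:, subset], target)
    resid = target - design[:, subset] @ a
    chi2 = float(resid @ resid) / target.size
    total = float(a.sum())
    if total <= 0:
        return np.zeros(len(subset)), 0.0, float(target @ target) / target.size
    return a / total, total, chi2


def multistate_enumerate(
    pool: list[ScatteringProfile],
    exp: ScatteringProfile,
    max_states: int = 4,
    exact_bound: int = 25000,
    beam_width: int = 100,
) -> MultiStateFit:
    """Best k-state mixtures of pool profiles for k = 1..max_states.

    Per candidate subset the member coefficients are solved by non-negative
    least squares on sigma-whitened intensities, then split into simplex
    weights and an overall scale.  Subsets are enumerated exactly while
    C(pool, k) <= ``exact_bound``; larger problems use a beam search seeded
    by the best (k-1)-state models, which also guarantees chi2 is
    non-increasing in k.
    """
    if not pool:
        raise ValueError("empty conformer pool")
    if max_states < 1:
        raise ValueError("max_states must be >= 1")
    sigma = exp.sigma_or_default()
    target = exp.i / sigma
    columns = []
    for prof in pool:
        if prof.q.shape == exp.q.shape and np.allclose(prof.q, exp.q):
            im = prof.i
        else:
            if exp.q[0] < prof.q[0] - 1e-12 or exp.q[-1] > prof.q[-1] + 1e-12:
                raise ValueError("pool profile q range does not cover experiment")
            im = np.interp(exp.q, prof.q, prof.i)
        columns.append(im / sigma)
    design = np.column_stack(columns)
    n = len(pool)

    best_by_k: dict[int, dict] = {}
    # k = 1 is always exact.
    prev_frontier: list[tuple[int, ...]] = []
    for k in range(1, min(max_states, n) + 1):
        n_subsets = math.comb(n, k)
        candidates: set[tuple[int, ...]]
        if n_subsets <= exact_bound:
            candidates = set(itertools.combinations(range(n), k))
        else:
            candidates = set()
            seeds = prev_frontier or [()]
            for base in seeds:
                for j in range(n):
                    if j in base:
                        continue
                    candidates.add(tuple(sorted((*base, j))))
        scored = []
        for subset in candidates:
            w, c, chi2 = _fit_subset(design, target, subset)
            scored.append((chi2, subset, w, c))
        scored.sort(key=lambda t: (t[0], t[1]))
        chi2, subset, w, c = scored[0]
        best_by_k[k] = {
            "k": k,
            "members": list(subset),
            "weights": w.tolist(),
            "scale": c,
            "chi2": chi2,
        }
        prev_frontier = [s for _, s, _, _ in scored[:beam_width]]

    # Nesting guard: a k-state model can always zero one weight, so enforce
    # monotonicity by carrying forward a better smaller model if needed.
    for k in range(2, max(best_by_k) + 1):
        if best_by_k[k]["chi2"] > best_by_k[k - 1]["chi2"]:
            smaller = dict(best_by_k[k - 1])
            smaller["k"] = k
            best_by_k[k] = smaller
    return MultiStateFit(best_by_k=best_by_k)


def rg_distribution(
    fit_model: dict,
    ensemble: BeadEnsemble,
    bin_width: float = 1.0,
) -> dict[str, np.ndarray]:
    """Weighted Rg histogram of one fitted multi-state model.

    Parameters
    ----------
    fit_model : dict
        One entry of :class:`MultiStateFit` (keys ``members``, ``weights``).
    ensemble : BeadEnsemble
        The pool the member indices refer to.
    bin_width : float
        Histogram bin width in Angstrom.

    Returns
    -------
    dict with ``edges`` (length B+1), ``weights`` (length B, sums to 1)
    and the raw per-member ``rg`` / ``member_weights`` arrays.
    """
    members = list(fit_model["members"])
    weights = np.asarray(fit_model["weights"], dtype=float)
    if len(members) != weights.size:
        raise ValueError("members and weights must align")
    if any(m < 0 or m >= len(ensemble) for m in members):
        raise ValueError("fit refers to members outside the ensemble")
    rgs = np.array([rg_from_coords(ensemble.members[m]) for m in members])
    lo = math.floor(rgs.min() / bin_width) * bin_width
    hi = math.ceil(rgs.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    hist, edges = np.histogram(rgs, bins=edges, weights=weights)
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return {
        "edges": edges,
        "weights": hist,
        "rg": rgs,
        "member_weights": weights,
    }
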