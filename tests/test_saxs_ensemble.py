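"""Tests for Debye profiles, Rg, tail conformers and multi-state fitting."""

from __future__ import annotations

import math

import numpy as np
import pytest

from coopfold.saxs_analysis.debye import debye_profile, pairwise_distances, rg_from_coords
from coopfold.saxs_analysis.ensemble import (
    BeadEnsemble,
    generate_tail_conformers,
    multistate_enumerate,
    rg_distribution,
)
from coopfold.saxs_analysis.profiles import ScatteringProfile, guinier_fit
from coopfold.synthetic_data import make_globular_body


class TestDebyeProfile:
    def test_single_bead_flat(self):
        q = np.linspace(0.01, 0.5, 20)
        prof = debye_profile(np.array([[1.0, 2.0, 3.0]]), q)
        assert np.allclose(prof.i, 1.0)

    def test_two_beads_closed_form(self):
        r = 7.0
        coords = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
        q = np.linspace(0.01, 0.5, 40)
        prof = debye_profile(coords, q)
        expected = 2.0 + 2.0 * np.sin(q * r) / (q * r)
        assert np.allclose(prof.i, expected, rtol=1e-12)

    def test_sphere_matches_analytic_form_factor(self, sphere_body, sphere_profile):
        radius = 20.0
        q = sphere_profile.q
        qr = q * radius
        analytic = (3.0 * (np.sin(qr) - qr * np.cos(qr)) / qr**3) ** 2
        mask = qr <= 3.0
        ratio = sphere_profile.i[mask] / sphere_profile.i.max() / analytic[mask]
        normalized = sphere_profile.i[mask] / (len(sphere_body) ** 2)
        assert np.all(np.abs(normalized / analytic[mask] - 1.0) < 0.02)

    def test_i0_is_total_scattering_squared(self):
        coords = make_globular_body(10.0, 50, seed=2)
        q = np.array([1e-6])
        prof = debye_profile(coords, q, form_factor=2.0)
        assert prof.i[0] == pytest.approx((2.0 * 50) ** 2, rel=1e-8)

    def test_guinier_round_trip_recovers_rg(self, sphere_body, sphere_profile):
        rg_direct = rg_from_coords(sphere_body)
        rg_fit = guinier_fit(sphere_profile).rg
        assert abs(rg_fit - rg_direct) / rg_direct < 0.03


class TestRgFromCoords:
    def test_two_beads(self):
        d = 6.0
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        assert rg_from_coords(coords) == pytest.approx(d / 2.0, rel=1e-12)

    def test_single_bead_zero(self):
        assert rg_from_coords(np.array([[1.0, 1.0, 1.0]])) == 0.0

    def test_uniform_sphere_limit(self):
        body = make_globular_body(20.0, 5000, seed=4)
        assert rg_from_coords(body) == pytest.approx(
            20.0 * math.sqrt(3.0 / 5.0), rel=0.02
        )

    def test_mass_weighting(self):
        coords = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        # all mass on one bead: Rg -> 0
        assert rg_from_coords(coords, masses=np.array([1e9, 1e-9])) < 1e-3


class TestTailConformers:
    def test_zero_tail_gives_identical_copies(self):
        rigid = make_globular_body(10.0, 30, seed=1)
        ens = generate_tail_conformers(rigid, 0, 0, 5, seed=2)
        assert len(ens) == 5
        for m in ens.members:
            assert np.array_equal(m, rigid)

    def test_bond_lengths_exact(self):
        rigid = make_globular_body(10.0, 30, seed=1)
        anchor = int(np.argmax(rigid[:, 0]))
        ens = generate_tail_conformers(rigid, anchor, 10, 8, seed=3)
        for m in ens.members:
            tail = m[ens.tail_range[0]:ens.tail_range[1]]
            chain = np.vstack([m[anchor], tail])
            steps = np.linalg.norm(np.diff(chain, axis=0), axis=1)
            assert np.allclose(steps, 3.8, atol=1e-6)

    def test_no_clashes(self):
        rigid = make_globular_body(10.0, 30, seed=1)
        anchor = int(np.argmax(rigid[:, 0]))
        ens = generate_tail_conformers(rigid, anchor, 15, 10, seed=4,
                                       clash_radius=2.0)
        t0, t1 = ens.tail_range
        for m in ens.members:
            tail = m[t0:t1]
            # tail beads vs all other beads (rigid internal distances are
            # the fixture's business, not the sampler's)
            d = pairwise_distances(m)
            n = m.shape[0]
            iu, ju = np.triu_indices(n, k=1)
            involves_tail = (iu >= t0) | (ju >= t0)
            assert np.all(d[involves_tail] >= 2.0 - 1e-9)

    def test_excluded_volume_expansion(self):
        # free 22-bead chain: self-avoiding msd(end-end) must exceed the
        # ideal-chain baseline n b^2 produced by the same generator with
        # clash checks off
        anchor = np.zeros((1, 3))
        n_tail, n_conf = 22, 500
        saw = generate_tail_conformers(anchor, 0, n_tail, n_conf, seed=9,
                                       clash_radius=2.0)
        ideal = generate_tail_conformers(anchor, 0, n_tail, n_conf, seed=9,
                                         clash_radius=0.0)
        def msd_end(ens):
            return np.mean([
                np.sum((m[-1] - m[0]) ** 2) for m in ens.members
            ])
        msd_ideal = msd_end(ideal)
        assert msd_ideal == pytest.approx(n_tail * 3.8**2, rel=0.15)
        assert msd_end(saw) > 1.1 * msd_ideal

    def test_seed_reproducibility(self):
        rigid = make_globular_body(10.0, 20, seed=1)
        a = generate_tail_conformers(rigid, 0, 8, 4, seed=5)
        b = generate_tail_conformers(rigid, 0, 8, 4, seed=5)
        for ma, mb in zip(a.members, b.members):
            assert np.array_equal(ma, mb)

    def test_impossible_geometry_raises(self):
        rigid = make_globular_body(10.0, 30, seed=1)
        with pytest.raises(RuntimeError, match="clash"):
            # clash radius spanning the whole body: no placement can succeed
            generate_tail_conformers(rigid, 0, 5, 1, seed=1, clash_radius=30.0,
                                     max_bead_retries=10, max_chain_restarts=3)

    def test_invalid_args(self):
        rigid = make_globular_body(10.0, 20, seed=1)
        with pytest.raises(ValueError):
            generate_tail_conformers(rigid, 99, 5, 1)
        with pytest.raises(ValueError):
            generate_tail_conformers(rigid, 0, -1, 1)


class TestBeadEnsembleType:
    def test_weights_must_be_simplex(self):
        m = (np.zeros((3, 3)), np.ones((3, 3)))
        with pytest.raises(ValueError):
            BeadEnsemble(members=m, weights=np.array([0.7, 0.7]),
                         rigid_range=(0, 3), tail_range=(3, 3))

    def test_mismatched_bead_counts(self):
        m = (np.zeros((3, 3)), np.ones((4, 3)))
        with pytest.raises(ValueError):
            BeadEnsemble(members=m, weights=np.array([0.5, 0.5]),
                         rigid_range=(0, 3), tail_range=(3, 3))


@pytest.fixture(scope="module")
def pool_and_truth(tail_system):
    ensemble, noisy, truth = tail_system
    pool = [debye_profile(m, noisy.q) for m in ensemble.members]
    return ensemble, pool, noisy, truth


class TestMultiStateFit:
    def test_exact_member_recovered_at_k1(self, pool_and_truth):
        _, pool, _, _ = pool_and_truth
        target_idx = 7
        exact = ScatteringProfile(
            q=pool[target_idx].q, i=pool[target_idx].i,
            sigma=0.01 * pool[target_idx].i,
        )
        fit = multistate_enumerate(pool, exact, max_states=1)
        best = fit.best_by_k[1]
        assert best["members"] == [target_idx]
        assert best["weights"][0] == pytest.approx(1.0)
        assert best["chi2"] < 0.01

    def test_known_mixture_recovery(self, pool_and_truth):
        _, pool, noisy, truth = pool_and_truth
        fit = multistate_enumerate(pool, noisy, max_states=2)
        best = fit.best_by_k[2]
        expected = {int(k): w for k, w in truth["mixture"].items()}
        got = dict(zip(best["members"], best["weights"]))
        assert set(got) == set(expected)
        for member, weight in expected.items():
            assert got[member] == pytest.approx(weight, abs=0.05)

    def test_mixture_recovery_across_seeds(self):
        # invariant: weight recovery within +-0.05 across 10 seeds at 1% noise
        from coopfold.synthetic_data import make_rigid_plus_tail_system

        failures = 0
        for seed in range(10):
            ensemble, noisy, truth = make_rigid_plus_tail_system(
                n_body=60, n_conformers=25, seed=100 + seed,
                q_grid=np.linspace(0.01, 0.35, 60),
            )
            pool = [debye_profile(m, noisy.q) for m in ensemble.members]
            best = multistate_enumerate(pool, noisy, max_states=2).best_by_k[2]
            got = dict(zip(best["members"], best["weights"]))
            expected = {int(k): w for k, w in truth["mixture"].items()}
            if set(got) != set(expected) or any(
                abs(got[m] - w) > 0.05 for m, w in expected.items()
            ):
                failures += 1
        assert failures == 0

    def test_chi2_non_increasing_in_k(self, pool_and_truth):
        _, pool, noisy, _ = pool_and_truth
        fit = multistate_enumerate(pool, noisy, max_states=3)
        chi = fit.chi2_by_k()
        assert chi[1] >= chi[2] >= chi[3]

    def test_weights_simplex(self, pool_and_truth):
        _, pool, noisy, _ = pool_and_truth
        fit = multistate_enumerate(pool, noisy, max_states=3)
        for model in fit.best_by_k.values():
            w = np.asarray(model["weights"])
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_beam_search_matches_exact_on_small_pool(self, pool_and_truth):
        _, pool, noisy, _ = pool_and_truth
        exact = multistate_enumerate(pool, noisy, max_states=2)
        beamed = multistate_enumerate(pool, noisy, max_states=2, exact_bound=10,
                                      beam_width=50)
        assert beamed.best_by_k[2]["chi2"] <= exact.best_by_k[2]["chi2"] * 1.05

    def test_empty_pool_rejected(self, pool_and_truth):
        _, _, noisy, _ = pool_and_truth
        with pytest.raises(ValueError):
            multistate_enumerate([], noisy)


class TestRgDistribution:
    def test_single_state_single_bin(self, tail_system):
        ensemble, noisy, _ = tail_system
        model = {"members": [3], "weights": [1.0]}
        hist = rg_distribution(model, ensemble, bin_width=1.0)
        assert hist["weights"].sum() == pytest.approx(1.0)
        assert np.count_nonzero(hist["weights"]) == 1

    def test_mixture_two_peaks(self, tail_system):
        ensemble, noisy, truth = tail_system
        pool = [debye_profile(m, noisy.q) for m in ensemble.members]
        best = multistate_enumerate(pool, noisy, max_states=2).best_by_k[2]
        hist = rg_distribution(best, ensemble, bin_width=0.5)
        assert hist["weights"].sum() == pytest.approx(1.0, abs=1e-12)
        expected = {int(k): w for k, w in truth["mixture"].items()}
        rgs = {m: ensemble.member_rg()[m] for m in expected}
        # mass near each true Rg matches the generating weight
        edges = hist["edges"]
        for member, weight in expected.items():
            sel = (edges[:-1] >= rgs[member] - 1.0) & (edges[1:] <= rgs[member] + 1.0)
            assert hist["weights"][sel].sum() == pytest.approx(weight, abs=0.05)

    def test_invalid_member_reference(self, tail_system):
        ensemble, _, _ = tail_system
        with pytest.raises(ValueError):
            rg_distribution({"members": [999], "weights": [1.0]}, ensemble)
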