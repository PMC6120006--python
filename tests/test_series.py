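"""Angular parts, truncated series energies, and forces/torques."""

import numpy as np
import pytest

from cgblob.potentials import valid_index_pairs
from cgblob.quaternion import quat_multiply, random_quaternion
from cgblob.series import (BlobState, TruncationScheme, allatom_energy,
                           allatom_force_torque, angular_part_direct,
                           angular_part_tensor, finite_difference_force_torque,
                           interblob_energy, interblob_force_torque)
from cgblob.tensors import BlobTemplate


def _random_states(make_blob, seed, na=5, nb=7, sep=8.0):
    rng = np.random.default_rng(seed)
    qa, qb = random_quaternion(rng, 2)
    a = BlobState(make_blob(na, seed=seed), rng.normal(0, 1, 3) + [0, 0, sep], qa)
    b = BlobState(make_blob(nb, seed=seed + 1), rng.normal(0, 1, 3), qb)
    return a, b


def _theta_scale(a, b, m):
    ra = a.template.radius + 1.0
    rb = b.template.radius + 1.0
    return a.template.n_atoms * b.template.n_atoms * (ra + rb) ** m


class TestTruncationScheme:
    def test_even_and_odd_pairs(self):
        assert set(TruncationScheme.up_to(4)) == {
            (0, 0), (2, 0), (2, 2), (4, 0), (4, 2), (4, 4),
            (1, 1), (3, 1), (3, 3)}
        assert list(TruncationScheme.up_to(0)) == [(0, 0)]

    def test_parity_constraint(self):
        for m, n in TruncationScheme.up_to(4):
            assert (m + n) % 2 == 0 and (m - n) % 2 == 0


class TestAngularParts:
    def test_zeroth_is_the_pair_count(self, make_blob):
        a, b = _random_states(make_blob, 3)
        assert angular_part_direct(a, b, 0, 0) == 35.0

    def test_point_blobs_have_no_structure(self):
        pt = BlobTemplate([[0.0, 0, 0]], [1.0])
        a = BlobState(pt, [0, 0, 5.0])
        b = BlobState(pt, [0, 0, 0.0])
        for m, n in valid_index_pairs(4):
            if m:
                assert angular_part_direct(a, b, m, n) == 0.0

    def test_22_hand_expansion(self, make_blob):
        """Theta(2,2) expands to N_B Rh.G_A(2).Rh + N_A Rh.G_B(2).Rh
        - 2 (Rh.G_A(1))(Rh.G_B(1))."""
        a, b = _random_states(make_blob, 11, na=3, nb=3)
        rhat = (a.position - b.position)
        rhat /= np.linalg.norm(rhat)
        ga, gb = a.lab_tensors, b.lab_tensors
        hand = (gb.n_atoms * rhat @ ga.gamma[2] @ rhat
                + ga.n_atoms * rhat @ gb.gamma[2] @ rhat
                - 2 * (rhat @ ga.gamma[1]) * (rhat @ gb.gamma[1]))
        assert angular_part_direct(a, b, 2, 2) == pytest.approx(hand, rel=1e-12)

    def test_tensor_route_matches_direct_summation(self, make_blob):
        for seed in range(20):
            a, b = _random_states(make_blob, 50 + seed)
            rhat = a.position - b.position
            rhat /= np.linalg.norm(rhat)
            for m, n in valid_index_pairs(4):
                direct = angular_part_direct(a, b, m, n)
                tens = angular_part_tensor(a.lab_tensors, b.lab_tensors, rhat, m, n)
                assert abs(direct - tens) <= 1e-9 * _theta_scale(a, b, m)

    def test_body_frame_tensors_rejected(self, make_blob):
        from cgblob.tensors import compute_moment_tensors
        mt = compute_moment_tensors(make_blob(3))
        with pytest.raises(ValueError):
            angular_part_tensor(mt, mt, np.array([0, 0, 1.0]), 0, 0)


class TestEnergies:
    def test_point_blobs_reduce_to_bare_potential(self, atomic_morse):
        pt = BlobTemplate([[0.0, 0, 0]], [1.0])
        a = BlobState(pt, [0, 0, 6.0])
        b = BlobState(pt, [0, 0, 0.0])
        for order in (0, 3, 4):
            e = interblob_energy(a, b, atomic_morse, TruncationScheme.up_to(order))
            assert e == pytest.approx(float(atomic_morse(6.0)), rel=1e-12)
        assert allatom_energy(a, b, atomic_morse) == pytest.approx(
            float(atomic_morse(6.0)))

    def test_invariant_under_global_rotation(self, make_blob, atomic_morse):
        rng = np.random.default_rng(8)
        a, b = _random_states(make_blob, 21)
        sch = TruncationScheme.up_to(4)
        e0 = interblob_energy(a, b, atomic_morse, sch)
        q = random_quaternion(rng)
        from cgblob.quaternion import quat_to_matrix
        rot = quat_to_matrix(q)
        a2 = BlobState(a.template, rot @ a.position, quat_multiply(q, a.orientation))
        b2 = BlobState(b.template, rot @ b.position, quat_multiply(q, b.orientation))
        e1 = interblob_energy(a2, b2, atomic_morse, sch)
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_allatom_symmetric_in_blob_exchange(self, make_blob, atomic_morse):
        a, b = _random_states(make_blob, 31)
        assert allatom_energy(a, b, atomic_morse) == pytest.approx(
            allatom_energy(b, a, atomic_morse), rel=1e-12)

    def test_series_approaches_allatom_with_distance_and_order(
            self, make_blob, atomic_morse):
        """Median |V_series - E_allatom| is non-increasing in the order
        0 -> 2 -> 4 and shrinks as R grows at fixed order."""
        rng = np.random.default_rng(5)
        meds = {}
        for ratio in (3.0, 5.0, 10.0):
            errs = {0: [], 2: [], 4: []}
            for t in range(12):
                ta = make_blob(5, scale=0.5, seed=400 + t)
                tb = make_blob(5, scale=0.5, seed=500 + t)
                rho_max = max(ta.radius, tb.radius)
                qa, qb = random_quaternion(rng, 2)
                a = BlobState(ta, [0, 0, ratio * rho_max], qa)
                b = BlobState(tb, [0, 0, 0.0], qb)
                exact = allatom_energy(a, b, atomic_morse)
                for order in errs:
                    e = interblob_energy(a, b, atomic_morse,
                                         TruncationScheme.up_to(order))
                    errs[order].append(abs(e - exact))
            meds[ratio] = [np.median(errs[o]) for o in (0, 2, 4)]
            assert meds[ratio][0] >= meds[ratio][1] >= meds[ratio][2]
        # fixed order, larger separation -> smaller error
        for i in range(3):
            assert meds[3.0][i] >= meds[10.0][i]

    def test_c60_pair_error_shrinks_with_order(self, c60, atomic_morse):
        """C60-C60 at 13 A with the atomic Morse: each added order removes
        part of the residual (the exponential potential amplifies the cage
        moments, so convergence in order is monotone but slow)."""
        a = BlobState(c60, [0, 0, 13.0])
        b = BlobState(c60, [0, 0, 0.0])
        exact = allatom_energy(a, b, atomic_morse)
        errs = [abs(interblob_energy(a, b, atomic_morse,
                                     TruncationScheme.up_to(o)) - exact)
                for o in (0, 2, 4)]
        assert errs[0] > errs[1] > errs[2]

    def test_c60_lj_series_within_5_percent(self, c60):
        """For an inverse-power potential the relative series error decays
        with distance: a graphitic Lennard-Jones C60 pair at 16 A is inside
        5% at fourth order."""
        from cgblob.potentials import LennardJonesPotential
        lj = LennardJonesPotential(epsilon=0.0028, sigma=3.47)
        a = BlobState(c60, [0, 0, 16.0])
        b = BlobState(c60, [0, 0, 0.0])
        exact = allatom_energy(a, b, lj)
        series = interblob_energy(a, b, lj, TruncationScheme.up_to(4))
        assert abs(series - exact) / abs(exact) < 0.05

    def test_coincident_centres_rejected(self, make_blob, atomic_morse):
        a = BlobState(make_blob(3), [0, 0, 0.0])
        b = BlobState(make_blob(3), [0, 0, 0.0])
        with pytest.raises(ValueError):
            interblob_energy(a, b, atomic_morse, TruncationScheme.up_to(2))


class TestForcesTorques:
    def test_point_blobs_feel_central_force_only(self, atomic_morse):
        pt = BlobTemplate([[0.0, 0, 0]], [1.0])
        a = BlobState(pt, [0, 0, 6.0])
        b = BlobState(pt, [0, 0, 0.0])
        f, ta, tb = interblob_force_torque(a, b, atomic_morse,
                                           TruncationScheme.up_to(4))
        du = float(atomic_morse.derivative(6.0, 1))
        np.testing.assert_allclose(f, [0, 0, -du], atol=1e-12)
        assert np.abs(ta).max() == pytest.approx(0.0, abs=1e-14)
        assert np.abs(tb).max() == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_analytic_matches_finite_differences(self, make_blob, atomic_morse, seed):
        a, b = _random_states(make_blob, seed, sep=7.0)
        sch = TruncationScheme.up_to(4)
        f, ta, tb = interblob_force_torque(a, b, atomic_morse, sch, method="analytic")
        ffd, tafd, tbfd = interblob_force_torque(a, b, atomic_morse, sch, method="fd")
        scale = max(np.abs(ffd).max(), 1e-10)
        assert np.abs(f - ffd).max() / scale < 1e-5
        for x, y in ((ta, tafd), (tb, tbfd)):
            s = max(np.abs(y).max(), 1e-10)
            assert np.abs(x - y).max() / s < 1e-5

    def test_allatom_force_torque_matches_finite_differences(
            self, make_blob, atomic_morse):
        a, b = _random_states(make_blob, 77, sep=6.0)
        f, ta, tb = allatom_force_torque(a, b, atomic_morse)
        ffd, tafd, tbfd = finite_difference_force_torque(
            a, b, lambda x, y: allatom_energy(x, y, atomic_morse))
        np.testing.assert_allclose(f, ffd, rtol=1e-5, atol=1e-10)
        np.testing.assert_allclose(ta, tafd, rtol=1e-5, atol=1e-10)
        np.testing.assert_allclose(tb, tbfd, rtol=1e-5, atol=1e-10)

    def test_inversion_symmetric_blob_feels_no_torque(self, atomic_morse):
        """Even-order schemes on inversion-symmetric blobs: odd moments
        vanish, so the series is orientation even and torques cancel."""
        rng = np.random.default_rng(12)
        half = rng.normal(0, 1.0, (4, 3))
        pos = np.vstack([half, -half])  # inversion symmetric by construction
        blob = BlobTemplate(pos, np.ones(8))
        qa, qb = random_quaternion(rng, 2)
        a = BlobState(blob, [0, 0, 7.0], qa)
        b = BlobState(blob, [0, 0, 0.0], qb)
        scheme = TruncationScheme(max_m=4, index_pairs=(
            (0, 0), (2, 0), (2, 2), (4, 0), (4, 2), (4, 4)))
        f, ta, tb = interblob_force_torque(a, b, atomic_morse, scheme)
        # Gamma(2), Gamma(4) survive inversion, so torques need not vanish;
        # but for C60 (isotropic through rank 4) they do:
        from cgblob import build_c60
        c = build_c60()
        a2 = BlobState(c, [0, 0, 11.0], qa)
        b2 = BlobState(c, [0, 0, 0.0], qb)
        _, ta2, tb2 = interblob_force_torque(a2, b2, atomic_morse, scheme)
        assert np.abs(ta2).max() < 1e-9
        assert np.abs(tb2).max() < 1e-9

    def test_c60_pair_force_consistent_with_energy_gradient(self, c60, atomic_morse):
        a = BlobState(c60, [0, 0, 10.5])
        b = BlobState(c60, [0, 0, 0.0])
        sch = TruncationScheme.up_to(4)
        f, _, _ = interblob_force_torque(a, b, atomic_morse, sch)
        h = 1e-4
        num = np.empty(3)
        for ax in range(3):
            pp, pm = a.position.copy(), a.position.copy()
            pp[ax] += h
            pm[ax] -= h
            num[ax] = -(interblob_energy(BlobState(c60, pp), b, atomic_morse, sch)
                        - interblob_energy(BlobState(c60, pm), b, atomic_morse, sch)
                        ) / (2 * h)
        np.testing.assert_allclose(f, num, rtol=1e-5, atol=1e-9)


def test_hexagon_face_scan_has_single_minimum(c60, atomic_morse):
    """All-atom hexagon-to-hexagon approach: one well, centred near 9.5-10 A."""
    from cgblob.fitting import scan_curve
    r = np.linspace(9.0, 14.0, 51)
    curve = scan_curve(c60, c60, atomic_morse, "hex-hex", r)
    e = curve.energies
    i = int(np.argmin(e))
    assert 9.5 <= r[i] <= 10.0
    # single minimum: energies decrease to it then increase
    assert np.all(np.diff(e[:i + 1]) < 0) and np.all(np.diff(e[i:]) > 0)
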