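"""Potential-energy terms, their analytic forces, and the parameter types."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chromoloop as cl
from chromoloop import _kernels
from chromoloop.model import LJ_CUTOFF, total_energy_forces


class TestScalarPotentials:
    @pytest.mark.parametrize(
        "r, expected",
        [(1.0, 0.0), (1.2, 1.0), (0.8, 1.0)],
    )
    def test_bond_energy_values(self, r, expected):
        assert cl.bond_energy(r) == pytest.approx(expected, abs=1e-12)

    def test_bond_energy_rejects_negative_length(self):
        with pytest.raises(ValueError):
            cl.bond_energy(-0.1)

    @pytest.mark.parametrize(
        "alpha, k, expected",
        [(0.0, 5.0, 0.0), (np.pi / 2, 3.0, 3.0), (np.pi, 2.0, 4.0)],
    )
    def test_angle_energy_values(self, alpha, k, expected):
        assert cl.angle_energy(alpha, k) == pytest.approx(expected, abs=1e-12)

    def test_angle_energy_domain(self):
        with pytest.raises(ValueError):
            cl.angle_energy(3.5, 1.0)

    def test_repulsion_zero_beyond_range(self):
        assert cl.repulsive_energy(LJ_CUTOFF + 1e-9) == 0.0
        assert cl.repulsive_energy(5.0) == 0.0

    def test_repulsion_at_contact_distance(self):
        # raw U at r = 1 is 4*(1 - 1) + 1 = 1 kT, below the softening
        # threshold of e_cutoff/2 = 1.5, hence unsoftened
        assert cl.repulsive_energy(1.0, e_cutoff=3.0) == pytest.approx(
            1.0, abs=1e-4
        )

    def test_repulsion_limit_is_e_cutoff(self):
        # as r -> 0 the floored radius tends to 0.3 and tanh -> 1
        assert cl.repulsive_energy(0.0, e_cutoff=3.0) == pytest.approx(3.0)
        assert cl.repulsive_energy(1e-9, e_cutoff=5.0) == pytest.approx(5.0)

    def test_softening_is_continuous_at_threshold(self):
        # find r where the raw (floored) potential equals e_cutoff/2 and
        # check that the softened branch meets it there: tanh(0) = 0
        from scipy.optimize import brentq

        e_cutoff = 3.0

        def raw(r):
            rt = (r**10 + 0.3**10) ** 0.1
            return 4.0 * (rt**-12 - rt**-6) + 1.0 - 0.5 * e_cutoff

        r_star = brentq(raw, 0.4, 1.05)
        below = cl.repulsive_energy(r_star + 1e-9, e_cutoff=e_cutoff)
        above = cl.repulsive_energy(r_star - 1e-9, e_cutoff=e_cutoff)
        assert below == pytest.approx(0.5 * e_cutoff, abs=1e-6)
        assert above == pytest.approx(0.5 * e_cutoff, abs=1e-6)

    def test_phantom_zeroes_repulsion(self):
        r = np.linspace(0.0, 2.0, 101)
        assert np.all(cl.repulsive_energy(r, phantom=True) == 0.0)

    def test_continuity_and_cap_on_dense_grid(self):
        r = np.linspace(1e-4, 1.5, 200_001)
        u_soft = cl.repulsive_energy(r, e_cutoff=3.0, crossing_allowed=True)
        # crossing-enabled branch: bounded and jump-free everywhere
        # (softening threshold and LJ cutoff included)
        assert np.abs(np.diff(u_soft)).max() < 0.02
        assert u_soft.max() <= 3.0 + 1e-12
        u_hard = cl.repulsive_energy(r, e_cutoff=3.0, crossing_allowed=False)
        assert u_hard.max() > 1e5  # steep core down to the radius floor
        # non-crossing branch: continuous where the wall is not steep, and
        # joins zero continuously at the 2^(1/6) cutoff
        mod = u_hard < 50.0
        assert np.abs(np.diff(u_hard[mod])).max() < 0.05
        just_inside = cl.repulsive_energy(LJ_CUTOFF - 1e-9, crossing_allowed=False)
        assert just_inside == pytest.approx(0.0, abs=1e-6)

    @given(st.floats(0.0, 3.0), st.floats(0.5, 10.0))
    @settings(deadline=None, max_examples=50)
    def test_repulsion_nonnegative_and_monotone_flags(self, r, e_cutoff):
        u_on = cl.repulsive_energy(r, e_cutoff=e_cutoff, crossing_allowed=True)
        u_off = cl.repulsive_energy(r, e_cutoff=e_cutoff, crossing_allowed=False)
        assert u_on >= 0.0 and u_off >= 0.0
        assert u_on <= e_cutoff + 1e-9
        assert u_off >= u_on - 1e-9  # softening only ever lowers the energy


class TestConfinementRadius:
    @pytest.mark.parametrize(
        "n, phi, expected",
        [(2000, 0.02, 28.79), (2000, 0.20, 13.37)],
    )
    def test_values(self, n, phi, expected):
        assert cl.confinement_radius(n, phi) == pytest.approx(expected, rel=2e-3)

    def test_definition(self):
        # phi monomers per cubic diameter inside the confinement sphere
        n, phi = 500, 0.1
        R = cl.confinement_radius(n, phi)
        assert n / ((4.0 / 3.0) * np.pi * R**3) == pytest.approx(phi)

    def test_density_bounds(self):
        with pytest.raises(ValueError):
            cl.confinement_radius(100, 0.0)
        with pytest.raises(ValueError):
            cl.confinement_radius(100, 1.5)


class TestTotalEnergyForces:
    def test_square_ground_state(self):
        conf = cl.Conformation(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], is_ring=True
        )
        params = cl.SimulationParameters(
            n_monomers=4, phantom=True, stiffness_k=0.0, confined=False
        )
        e, f = total_energy_forces(conf, params)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.abs(f).max() == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(),
            dict(crossing_allowed=False),
            dict(phantom=True),
            dict(stiffness_k=0.0),
            dict(exclude_loop_anchor_repulsion=True),
            dict(confined=False),
        ],
    )
    def test_forces_match_finite_differences(self, kwargs, rng):
        n = 16
        params = cl.SimulationParameters(
            n_monomers=n, volume_density=0.1, loops=[(3, 11)], **kwargs
        )
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        x = np.c_[2 * np.cos(t), 2 * np.sin(t), 0.2 * rng.standard_normal(n)]
        x += 0.1 * rng.standard_normal((n, 3))
        conf = cl.Conformation(x)
        _, f = total_energy_forces(conf, params)
        h = 1e-6
        num = np.zeros_like(f)
        for i in range(n):
            for d in range(3):
                xp = x.copy()
                xp[i, d] += h
                xm = x.copy()
                xm[i, d] -= h
                ep, _ = total_energy_forces(cl.Conformation(xp), params)
                em, _ = total_energy_forces(cl.Conformation(xm), params)
                num[i, d] = -(ep - em) / (2 * h)
        scale = max(1.0, np.abs(f).max())
        assert np.abs(num - f).max() / scale < 1e-5

    def test_angle_energy_linear_in_stiffness(self, random_ring_conformation):
        base = dict(n_monomers=40, phantom=True, confined=False)
        e1, _ = total_energy_forces(
            random_ring_conformation, cl.SimulationParameters(stiffness_k=2.0, **base)
        )
        e2, _ = total_energy_forces(
            random_ring_conformation, cl.SimulationParameters(stiffness_k=4.0, **base)
        )
        e0, _ = total_energy_forces(
            random_ring_conformation, cl.SimulationParameters(stiffness_k=0.0, **base)
        )
        assert e2 - e0 == pytest.approx(2.0 * (e1 - e0), rel=1e-12)

    def test_phantom_energy_is_bonds_angles_confinement(self, random_ring_conformation):
        p_full = cl.SimulationParameters(n_monomers=40, volume_density=0.3)
        p_phantom = dataclasses.replace(p_full, phantom=True)
        e_ph, _ = total_energy_forces(random_ring_conformation, p_phantom)
        conf = random_ring_conformation
        bonds = cl.bond_energy(conf.bond_lengths()).sum()
        x = conf.coords
        u = x - np.roll(x, 1, axis=0)
        v = np.roll(x, -1, axis=0) - x
        cosa = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        angles = (p_full.stiffness_k * (1.0 - cosa)).sum()
        R = p_full.confinement_radius
        rad = np.linalg.norm(x, axis=1)
        conf_term = p_full.confinement_slope * np.clip(rad - R, 0, None).sum()
        assert e_ph == pytest.approx(bonds + angles + conf_term, rel=1e-12)

    def test_rejects_nonfinite_coordinates(self):
        with pytest.raises(ValueError):
            cl.Conformation(np.full((8, 3), np.nan))

    def test_compiled_kernel_matches_reference(self, rng):
        """The float32 production force kernel agrees with the float64
        vectorised reference on a crowded conformation."""
        n = 120
        params = cl.SimulationParameters(
            n_monomers=n, volume_density=0.15, loops=[(30, 90)]
        )
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        R = params.confinement_radius
        x = np.c_[
            0.8 * R * np.cos(t), 0.8 * R * np.sin(t), 0.3 * rng.standard_normal(n)
        ]
        x += 0.25 * rng.standard_normal((n, 3))
        _, f_ref = total_energy_forces(cl.Conformation(x), params)

        x0 = x[:, 0].astype(np.float32)
        x1 = x[:, 1].astype(np.float32)
        x2 = x[:, 2].astype(np.float32)
        cap = _kernels.pair_capacity(n)
        pi = np.empty(cap, np.int64)
        pj = np.empty(cap, np.int64)
        scratch = np.empty(80**3, np.int64)
        cid = np.empty(n, np.int64)
        order = np.empty(n, np.int64)
        npairs = _kernels._build_pairs(
            x0, x1, x2, 4.0, np.empty(0, np.int64), pi, pj, cid, order, scratch
        )
        assert npairs > 0
        f0 = np.zeros(n, np.float32)
        f1 = np.zeros(n, np.float32)
        f2 = np.zeros(n, np.float32)
        scr = [np.empty(n, np.float32) for _ in range(10)]
        loops = params.loop_pairs()
        _kernels._compute_forces(
            x0, x1, x2, f0, f1, f2, *scr, pi, pj, npairs,
            np.ascontiguousarray(loops[:, 0]), np.ascontiguousarray(loops[:, 1]),
            params.bond_k, params.stiffness_k, params.e_cutoff,
            True, False, R, params.confinement_slope, -1.0,
        )
        fk = np.c_[f0, f1, f2].astype(np.float64)
        assert np.abs(fk - f_ref).max() / np.abs(f_ref).max() < 1e-4


class TestParameterTypes:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            cl.SimulationParameters(n_monomers=3)
        with pytest.raises(ValueError):
            cl.SimulationParameters(n_monomers=101)  # odd
        with pytest.raises(ValueError):
            cl.SimulationParameters(n_monomers=100, volume_density=1.5)
        with pytest.raises(ValueError):
            cl.SimulationParameters(n_monomers=100, stiffness_k=-1.0)
        with pytest.raises(ValueError):
            cl.SimulationParameters(n_monomers=100, e_cutoff=0.0)
        with pytest.raises(ValueError):
            cl.SimulationParameters(n_monomers=100, loops=[(5, 5)])
        with pytest.raises(ValueError):
            cl.SimulationParameters(n_monomers=100, loops=[(5, 200)])

    def test_roundtrip_dict(self):
        p = cl.SimulationParameters(n_monomers=100, loops=[(10, 40)], seed=5)
        q = cl.SimulationParameters.from_dict(p.to_dict())
        assert q == p

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            cl.SimulationParameters.from_dict({"n_monomers": 100, "bogus": 1})

    def test_loop_geometry_helpers(self):
        lp = cl.LoopSpec(970, 1030)
        assert lp.length(2000) == 60
        inner = lp.interior(2000)
        assert inner[0] == 971 and inner[-1] == 1029 and len(inner) == 59
        # wrap-around loop
        lp2 = cl.LoopSpec(1990, 10)
        assert lp2.length(2000) == 20
        assert len(lp2.interior(2000)) == 19
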