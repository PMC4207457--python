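"""Contact maps, contact-frequency ratios, profiles, density, FISH."""

import numpy as np
import pytest

import chromoloop as cl
from chromoloop.analysis import (
    ContactMap,
    _anchors,
    contacts,
    control_pair,
    ensemble_heatmap,
    facilitation_pair,
    facilitation_score,
    fish_distances,
    insulation_pair,
    insulation_score,
    intra_loop_score,
    loop_base_profile,
    radial_density,
    two_loop_summary,
)
from chromoloop.dynamics import DESK_SCHEDULE, Ensemble
from chromoloop.model import Conformation, LoopSpec, SimulationParameters


def brute_force_contacts(coords, cutoff=2.0, min_sep=2):
    n = len(coords)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            sep = min(j - i, n - (j - i))
            if sep >= min_sep and np.linalg.norm(coords[i] - coords[j]) < cutoff:
                out.add((i, j))
    return out


def _fake_ensemble(coords, params=None):
    coords = np.asarray(coords, dtype=np.float32)
    if params is None:
        params = SimulationParameters(n_monomers=coords.shape[1])
    return Ensemble(
        coords=coords,
        block_indices=np.arange(coords.shape[0]),
        params=params,
        schedule=DESK_SCHEDULE,
        seed=0,
    )


class TestContacts:
    def test_pair_at_unit_distance_is_contact(self):
        x = np.zeros((8, 3))
        x[:, 0] = np.arange(8) * 10.0
        x[4] = [1.0, 0.0, 0.0]  # monomer 4 lands next to monomer 0
        pairs = contacts(Conformation(x))
        assert (0, 4) in pairs

    def test_distance_exactly_two_is_not_a_contact(self):
        x = np.zeros((8, 3))
        x[:, 0] = np.arange(8) * 10.0
        x[4] = [2.0, 0.0, 0.0]
        assert (0, 4) not in contacts(Conformation(x))
        x[4] = [2.0 - 1e-6, 0.0, 0.0]
        assert (0, 4) in contacts(Conformation(x))

    def test_near_diagonal_exclusion(self):
        t = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        ring = np.c_[1.5 * np.cos(t), 1.5 * np.sin(t), np.zeros_like(t)]
        pairs = contacts(Conformation(ring))
        for i, j in pairs:
            sep = min(j - i, 10 - (j - i))
            assert sep >= 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_grid_finder_equals_brute_force(self, seed):
        gen = np.random.default_rng(seed)
        n = 80
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        x = np.c_[4 * np.cos(t), 4 * np.sin(t), 0.5 * gen.standard_normal(n)]
        x += 0.4 * gen.standard_normal((n, 3))
        assert contacts(Conformation(x)) == brute_force_contacts(x)


class TestHeatmap:
    def test_single_conformation_indicator(self, random_ring_conformation):
        m = ensemble_heatmap(random_ring_conformation)
        pairs = contacts(random_ring_conformation)
        assert m.n_conformations == 1
        assert m.counts.sum() == 2 * len(pairs)
        for i, j in pairs:
            assert m.counts[i, j] == 1 and m.counts[j, i] == 1

    def test_repeated_conformation_scales_counts(self, random_ring_conformation):
        reps = np.repeat(random_ring_conformation.coords[None], 5, axis=0)
        m1 = ensemble_heatmap(random_ring_conformation)
        m5 = ensemble_heatmap(reps)
        assert np.array_equal(m5.counts, 5 * m1.counts)
        assert m5.n_conformations == 5
        # frequencies are then identical
        assert np.allclose(m5.frequency(), m1.frequency())

    def test_symmetry_and_zero_band(self, random_ring_conformation):
        m = ensemble_heatmap(random_ring_conformation)
        assert np.array_equal(m.counts, m.counts.T)
        n = m.n_monomers
        band = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        band = np.minimum(band, n - band)
        assert m.counts[band < m.min_sep].sum() == 0

    def test_mismatched_sizes_rejected(self):
        a = _fake_ensemble(np.zeros((1, 10, 3)))
        b = _fake_ensemble(np.zeros((1, 12, 3)))
        with pytest.raises(ValueError):
            ensemble_heatmap([a, b])

    def test_tsv_roundtrip(self, tmp_path, random_ring_conformation):
        m = ensemble_heatmap(random_ring_conformation)
        p = tmp_path / "map.tsv"
        m.to_tsv(p)
        back = ContactMap.from_tsv(p)
        assert np.array_equal(back.counts, m.counts)
        assert back.n_conformations == m.n_conformations
        assert back.cutoff == m.cutoff and back.min_sep == m.min_sep

    def test_npz_roundtrip(self, tmp_path, random_ring_conformation):
        m = ensemble_heatmap(random_ring_conformation)
        p = tmp_path / "map.npz"
        m.to_npz(p)
        back = ContactMap.from_npz(p)
        assert np.array_equal(back.counts, m.counts)


def _uniform_map(n=2000, count=4, n_conf=100, min_sep=2):
    counts = np.full((n, n), count, dtype=np.int64)
    band = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    band = np.minimum(band, n - band)
    counts[band < min_sep] = 0
    return ContactMap(counts=counts, n_conformations=n_conf, min_sep=min_sep)


LOOP = LoopSpec(970, 1030)


class TestRatioOperators:
    def test_insulation_identity_maps(self):
        m = _uniform_map()
        rr = insulation_score(m, m, LOOP, ep_distance=100)
        assert rr.ratio == 1.0
        assert rr.arrangement == "insulation"

    def test_facilitation_identity_maps(self):
        m = _uniform_map()
        rr = facilitation_score(m, m, LOOP, ep_distance=100)
        assert rr.ratio == 1.0
        # printed offset window for the 50 kb / 30 kb case is +/-6 monomers
        assert rr.window["offset_window"] == 6

    def test_facilitation_offset_window_scales(self):
        m = _uniform_map()
        rr = facilitation_score(m, m, LOOP, ep_distance=180)
        assert rr.window["offset_window"] == 20

    def test_intra_loop_identity_maps(self):
        m = _uniform_map()
        rr = intra_loop_score(m, m, LOOP, positions=(980, 1010))
        assert rr.ratio == 1.0
        assert rr.n_pairs == 1

    def test_insulation_window_definition(self):
        """Window = promoter-proximal third of the loop interior x (+/-3)
        separations; a map that doubles exactly those cells gives ratio 2."""
        base = _uniform_map()
        boosted = _uniform_map()
        enh = np.arange(1011, 1030)  # last third of interior 971..1029
        for e in enh:
            for s in range(97, 104):
                boosted.counts[e, e + s] *= 2
                boosted.counts[e + s, e] *= 2
        rr = insulation_score(boosted, base, LOOP, ep_distance=100)
        assert rr.ratio == pytest.approx(2.0)
        assert rr.n_pairs == len(enh) * 7
        assert sorted(rr.window["enhancer_positions"]) == list(enh)

    def test_insulation_enhancer_variants(self):
        m = _uniform_map()
        mid = insulation_score(m, m, LOOP, 100, enhancer="midpoint")
        assert mid.window["enhancer_positions"] == [1000]
        base = insulation_score(m, m, LOOP, 100, enhancer="near_base")
        assert base.window["enhancer_positions"] == [1029]
        expl = insulation_score(m, m, LOOP, 100, enhancer=[990])
        assert expl.n_pairs == 7

    def test_facilitation_window_is_symmetric_straddle(self):
        """All window pairs straddle the loop with midpoint within the
        printed offset of the loop centre."""
        base = _uniform_map()
        boosted = _uniform_map()
        pairs = []
        for s in range(97, 104):
            for i in range(0, 2000 - s):
                if abs(i + s / 2.0 - 1000.0) <= 6:
                    pairs.append((i, i + s))
        for i, j in pairs:
            boosted.counts[i, j] *= 3
            boosted.counts[j, i] *= 3
        rr = facilitation_score(boosted, base, LOOP, ep_distance=100)
        assert rr.ratio == pytest.approx(3.0)
        assert rr.n_pairs == len(pairs)
        for i, j in pairs:
            assert i < 970 and j > 1030  # enhancer before, promoter after

    def test_window_exits_chain_raises(self):
        m = _uniform_map()
        with pytest.raises(ValueError):
            insulation_score(m, m, LOOP, ep_distance=1500)

    def test_facilitation_requires_distance_beyond_loop(self):
        m = _uniform_map()
        with pytest.raises(ValueError):
            facilitation_score(m, m, LOOP, ep_distance=40)

    def test_intra_loop_positions_validated(self):
        m = _uniform_map()
        with pytest.raises(ValueError):
            intra_loop_score(m, m, LOOP, positions=(960, 1000))

    def test_run_spread_across_maps(self):
        """stderr is the spread of per-run ratios around the pooled value."""
        maps = [_uniform_map(count=c) for c in (3, 4, 5)]
        base = _uniform_map(count=4)
        rr = insulation_score(maps, [base], LOOP, ep_distance=100)
        assert rr.ratio == pytest.approx(1.0)
        assert rr.run_ratios == pytest.approx([0.75, 1.0, 1.25])
        assert rr.stderr == pytest.approx(np.std([0.75, 1.0, 1.25], ddof=1))


class TestLoopBaseProfile:
    def test_identical_maps_flat_at_one(self):
        m = _uniform_map(n=400)
        prof = loop_base_profile(m, m, base=200)
        vals = prof.ratio[~np.isnan(prof.ratio)]
        assert np.allclose(vals, 1.0)

    def test_peak_at_partner_anchor(self):
        n = 400
        loop_m = _uniform_map(n=n)
        base_m = _uniform_map(n=n)
        a, b = 170, 230
        loop_m.counts[a, b] = loop_m.counts[b, a] = 400  # bases in contact
        prof = loop_base_profile(loop_m, base_m, base=a)
        peak_offset = prof.offsets[np.nanargmax(prof.ratio)]
        assert peak_offset == b - a


class TestRadialDensity:
    def test_requires_two_runs(self):
        ens = _fake_ensemble(np.zeros((3, 200, 3)))
        with pytest.raises(ValueError):
            radial_density([ens], LoopSpec(70, 130))

    def test_identical_runs_give_unit_density(self, rng):
        """If every run is the same, the shuffled normalization cancels."""
        n = 200
        coords = rng.standard_normal((4, n, 3)).astype(np.float32) * 3
        e1 = _fake_ensemble(coords)
        e2 = _fake_ensemble(coords.copy())
        prof = radial_density([e1, e2], LoopSpec(70, 130))
        populated = ~np.isnan(prof.density)
        assert np.allclose(prof.density[populated], 1.0)
        assert np.allclose(prof.control[~np.isnan(prof.control)], 1.0)

    def test_bin_edges_are_half_monomer(self, rng):
        coords = rng.standard_normal((2, 100, 3)).astype(np.float32)
        prof = radial_density(
            [_fake_ensemble(coords), _fake_ensemble(coords)], LoopSpec(30, 70)
        )
        assert prof.bin_edges[0] == 0.0
        assert np.allclose(np.diff(prof.bin_edges), 0.5)

    def test_distal_monomer_definition(self):
        """Distal = outside the loop plus 20 monomers away from each base."""
        from chromoloop.analysis import _arc_indices

        idx = _arc_indices(970, 1030, 2000)
        assert idx[0] == 970 and idx[-1] == 1030 and len(idx) == 61


class TestFish:
    def test_single_conformation_point_mass(self):
        x = np.zeros((1, 50, 3), dtype=np.float32)
        x[0, 20] = [3.2, 0, 0]
        f = fish_distances(_fake_ensemble(x), 0, 20)
        assert f.mean == pytest.approx(3.2, abs=1e-5)
        assert f.counts.sum() == 1
        assert f.counts[int(3.2 / 0.5)] == 1

    def test_mean_and_cumulative(self, rng):
        coords = rng.standard_normal((50, 30, 3)).astype(np.float32) * 2
        f = fish_distances(_fake_ensemble(coords), 3, 17)
        d = np.linalg.norm(
            coords[:, 3, :].astype(float) - coords[:, 17, :].astype(float), axis=1
        )
        assert f.mean == pytest.approx(d.mean(), rel=1e-6)
        cdf = f.cumulative()
        assert cdf[-1] == pytest.approx(1.0)
        assert np.all(np.diff(cdf) >= 0)


class TestArrangementPlacements:
    def test_insulation_pair_inside_loop(self):
        e, p = insulation_pair(LOOP, 2000, 180)
        a, b = _anchors(LOOP)
        assert a < e < b and p == e + 180 and p > b

    def test_facilitation_pair_straddles_loop(self):
        e, p = facilitation_pair(LOOP, 2000, 180)
        assert e < 970 and p > 1030 and p - e == 180

    def test_control_pair_antipodal(self):
        e, p = control_pair(LOOP, 2000, 180)
        assert (p - e) % 2000 == 180
        mid = (e + 90) % 2000
        assert min(abs(mid - 0), abs(mid - 2000)) <= 1  # opposite monomer 1000


class TestTwoLoopSummary:
    def test_intra_higher_than_inter(self):
        n = 400
        m = _uniform_map(n=n, count=2)
        l1, l2 = LoopSpec(140, 200), LoopSpec(200, 260)
        for lp in (l1, l2):
            a, b = _anchors(lp)
            idx = np.arange(a + 1, b)
            m.counts[np.ix_(idx, idx)] = 10
        out = two_loop_summary(m, [l1, l2])
        assert out["intra_over_inter"] > 1.0
        assert len(out["intra_loop_mean_frequency"]) == 2


class TestRendering:
    def test_heatmap_png(self, tmp_path, random_ring_conformation):
        from chromoloop.analysis import render_heatmap

        m = ensemble_heatmap(random_ring_conformation)
        out = tmp_path / "map.png"
        render_heatmap(m, out)
        assert out.stat().st_size > 0


class TestEnsembleXyzExport:
    def test_blocks_written(self, tmp_path, rng):
        from chromoloop.dynamics import DESK_SCHEDULE, Ensemble

        coords = rng.standard_normal((4, 30, 3)).astype(np.float32)
        ens = Ensemble(
            coords=coords,
            block_indices=np.arange(10, 14),
            params=SimulationParameters(n_monomers=30),
            schedule=DESK_SCHEDULE,
            seed=3,
        )
        paths = ens.to_xyz(tmp_path / "xyz", stride=2)
        assert len(paths) == 2 and paths[0].name == "block000010.xyz"
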