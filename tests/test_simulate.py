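import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import jensenshannon

from thymorep.cdr import classify_productivity
from thymorep.simulate import (
    JunctionTruth,
    SimulationConfig,
    apply_selection,
    assign_clone_sizes,
    draw_tra_pair,
    draw_trb_pair,
    make_junction,
    preset,
    simulate_sample,
)


def _config(**kwargs):
    base = dict(life_stage="adult", cell_type="DP", chain="TRA")
    base.update(kwargs)
    return SimulationConfig(**base)


class TestConfig:
    def test_alpha_must_exceed_one(self):
        with pytest.raises(ValueError):
            _config(clone_size_alpha=1.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            _config(insert_mean=-1.0)

    def test_nonproductive_rate_bounded(self):
        with pytest.raises(ValueError):
            _config(nonproductive_rate=1.5)


class TestPresets:
    def test_foetal_shorter_inserts(self):
        assert preset("foetal").insert_mean < preset("adult").insert_mean

    def test_hc_has_foetal_rounds(self):
        assert (
            preset("adult_hc", chain="TRA").rearrangement_rounds_mean
            == preset("foetal", chain="TRA").rearrangement_rounds_mean
        )

    def test_hc_has_adult_inserts(self):
        assert preset("adult_hc").insert_mean == preset("adult").insert_mean

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            preset("neonatal")

    def test_foetal_heavier_tail_weaker_selection(self):
        f, a = preset("foetal"), preset("adult")
        assert f.clone_size_alpha < a.clone_size_alpha
        assert f.selection_strength < a.selection_strength


class TestTraPair:
    def test_degenerate_limit_most_proximal(self, catalog):
        cfg = _config(proximal_bias=60.0, rearrangement_rounds_mean=0.0)
        rng = np.random.default_rng(0)
        n_v = len(catalog.axis("TRA", "V"))
        for _ in range(50):
            v, j = draw_tra_pair(catalog, cfg, rng)
            assert (v, j) == (n_v - 1, 0)

    def test_adult_moves_distal(self, catalog):
        rng_f = np.random.default_rng(1)
        rng_a = np.random.default_rng(1)
        f_cfg = preset("foetal", chain="TRA")
        a_cfg = preset("adult", chain="TRA")
        f = np.array([draw_tra_pair(catalog, f_cfg, rng_f) for _ in range(10000)])
        a = np.array([draw_tra_pair(catalog, a_cfg, rng_a) for _ in range(10000)])
        assert a[:, 0].mean() < f[:, 0].mean()  # adult V more 5'
        assert a[:, 1].mean() > f[:, 1].mean()  # adult J more 3'

    def test_clamping_at_bounds(self, catalog):
        cfg = _config(rearrangement_rounds_mean=1000.0)
        rng = np.random.default_rng(2)
        n_j = len(catalog.axis("TRA", "J"))
        v, j = draw_tra_pair(catalog, cfg, rng)
        assert (v, j) == (0, n_j - 1)

    def test_rounds_monotone_displacement(self, catalog):
        means_v, means_j = [], []
        for rounds in (0.0, 0.5, 1.5, 4.0):
            cfg = _config(proximal_bias=0.3, rearrangement_rounds_mean=rounds)
            rng = np.random.default_rng(3)
            draws = np.array(
                [draw_tra_pair(catalog, cfg, rng) for _ in range(4000)]
            )
            means_v.append(draws[:, 0].mean())
            means_j.append(draws[:, 1].mean())
        assert all(a >= b for a, b in zip(means_v, means_v[1:]))
        assert all(a <= b for a, b in zip(means_j, means_j[1:]))


class TestTrbPair:
    def test_cluster_weight_one(self, catalog):
        cfg = _config(chain="TRB", trbj_cluster1_weight=1.0)
        rng = np.random.default_rng(0)
        j_axis = catalog.axis("TRB", "J")
        for _ in range(100):
            _, j = draw_trb_pair(catalog, cfg, rng)
            assert j_axis[j].cluster_id == 1

    def test_cluster_weight_half_binomial(self, catalog):
        cfg = _config(chain="TRB", trbj_cluster1_weight=0.5)
        rng = np.random.default_rng(1)
        j_axis = catalog.axis("TRB", "J")
        n = 10000
        c1 = sum(
            j_axis[draw_trb_pair(catalog, cfg, rng)[1]].cluster_id == 1
            for _ in range(n)
        )
        sd = np.sqrt(0.25 * n)
        assert abs(c1 - 0.5 * n) < 3 * sd

    def test_zero_bias_uniform_v(self, catalog):
        cfg = _config(chain="TRB", proximal_bias=0.0)
        rng = np.random.default_rng(2)
        n = 10000
        n_v = len(catalog.axis("TRB", "V"))
        counts = np.bincount(
            [draw_trb_pair(catalog, cfg, rng)[0] for _ in range(n)],
            minlength=n_v,
        )
        p = stats.chisquare(counts).pvalue
        assert p > 0.001


class TestMakeJunction:
    def test_zero_config_concatenates(self, catalog):
        v = catalog.axis("TRB", "V")[0]
        j = catalog.axis("TRB", "J")[0]
        cfg = _config(chain="TRB", insert_mean=0.0, deletion_mean=0.0)
        junction, truth = make_junction(v, j, cfg, np.random.default_rng(0))
        assert junction == v.junction_seq + j.junction_seq
        assert (truth.v_deleted, truth.j_deleted, truth.insert_len) == (0, 0, 0)

    def test_insert_mean_recovered(self, catalog):
        v = catalog.axis("TRB", "V")[0]
        j = catalog.axis("TRB", "J")[0]
        cfg = _config(chain="TRB", insert_mean=4.0, deletion_mean=0.0)
        rng = np.random.default_rng(1)
        n = 10000
        draws = np.array(
            [make_junction(v, j, cfg, rng)[1].insert_len for _ in range(n)]
        )
        # geometric on {0,1,...}: var = mean * (mean + 1)
        se = np.sqrt(4.0 * 5.0 / n)
        assert abs(draws.mean() - 4.0) < 3 * se

    def test_truth_insert_invariant(self, catalog):
        v = catalog.axis("TRA", "V")[3]
        j = catalog.axis("TRA", "J")[5]
        cfg = _config(insert_mean=3.0, deletion_mean=1.0)
        rng = np.random.default_rng(2)
        for _ in range(200):
            junction, truth = make_junction(v, j, cfg, rng)
            assert truth.insert_len == len(truth.insert_seq)
            assert len(junction) == (
                len(v.junction_seq) - truth.v_deleted
                + truth.insert_len
                + len(j.junction_seq) - truth.j_deleted
            )

    def test_frame_target_controls_frame(self, catalog):
        v = catalog.axis("TRB", "V")[1]
        j = catalog.axis("TRB", "J")[1]
        cfg = _config(chain="TRB", insert_mean=2.0, deletion_mean=0.5)
        rng = np.random.default_rng(3)
        for want in (True, False):
            for _ in range(100):
                junction, _ = make_junction(v, j, cfg, rng, frame_target=want)
                assert (len(junction) % 3 == 0) == want

    def test_kind_mismatch_rejected(self, catalog):
        v = catalog.axis("TRB", "V")[0]
        with pytest.raises(ValueError):
            make_junction(v, v, _config(chain="TRB"), np.random.default_rng(0))

    def test_truth_validates(self):
        with pytest.raises(ValueError):
            JunctionTruth(0, 0, 2, "A")


class TestCloneSizes:
    def test_alpha_recovery_round_trip(self):
        from thymorep.abundance import fit_power_law

        rng = np.random.default_rng(5)
        sizes = assign_clone_sizes(50000, 3.0, rng)
        fit = fit_power_law(sizes)
        assert fit.converged
        assert abs(fit.alpha - 3.0) < 0.05

    def test_large_alpha_all_ones(self):
        sizes = assign_clone_sizes(1000, 40.0, np.random.default_rng(0))
        assert (sizes == 1).all()

    def test_alpha_one_rejected(self):
        with pytest.raises(ValueError):
            assign_clone_sizes(10, 1.0, np.random.default_rng(0))


class TestSelection:
    def _clonotypes(self, catalog, n=2000, seed=0):
        cfg = preset("adult", "DP", "TRB").replace(n_clonotypes=n, seed=seed)
        return simulate_sample(cfg, catalog).clonotypes

    def test_zero_strength_keeps_all(self, catalog):
        clonotypes = self._clonotypes(catalog, 500)
        out = apply_selection(clonotypes, "SP4", 0.0, catalog,
                              np.random.default_rng(0))
        assert out == clonotypes

    def test_dp_passthrough(self, catalog):
        clonotypes = self._clonotypes(catalog, 500)
        out = apply_selection(clonotypes, "DP", 5.0, catalog,
                              np.random.default_rng(0))
        assert out == clonotypes

    def test_no_invented_clonotypes(self, catalog):
        clonotypes = self._clonotypes(catalog, 500)
        out = apply_selection(clonotypes, "SP8", 2.0, catalog,
                              np.random.default_rng(1))
        assert set(c.key for c in out) <= set(c.key for c in clonotypes)

    def test_stronger_selection_diverges_lineages(self, catalog):
        clonotypes = self._clonotypes(catalog, 3000)
        v_names = catalog.names("TRB", "V")

        def usage(cs):
            idx = {n: i for i, n in enumerate(v_names)}
            u = np.zeros(len(v_names))
            for c in cs:
                u[idx[c.v_name]] += 1
            return u / u.sum()

        def jsd_at(strength, seed):
            rng = np.random.default_rng(seed)
            sp4 = apply_selection(clonotypes, "SP4", strength, catalog, rng)
            sp8 = apply_selection(clonotypes, "SP8", strength, catalog, rng)
            return jensenshannon(usage(sp4), usage(sp8))

        weak = np.mean([jsd_at(0.5, s) for s in range(5)])
        strong = np.mean([jsd_at(2.0, s) for s in range(5, 10)])
        assert strong > weak


class TestSimulateSample:
    def test_deterministic(self, catalog):
        cfg = preset("foetal", "DP", "TRB").replace(n_clonotypes=1000, seed=11)
        a = simulate_sample(cfg, catalog)
        b = simulate_sample(cfg, catalog)
        assert a.to_frame().equals(b.to_frame())

    def test_nonproductive_rate_binomial(self, catalog):
        cfg = preset("adult", "DP", "TRB").replace(
            n_clonotypes=10000, seed=13, nonproductive_rate=0.1
        )
        sample = simulate_sample(cfg, catalog)
        frac = np.mean([not c.productive for c in sample.clonotypes])
        sd = np.sqrt(0.1 * 0.9 / len(sample))
        assert abs(frac - 0.1) < 3 * sd

    def test_productive_have_valid_junctions(self, catalog):
        cfg = preset("foetal", "SP4", "TRA").replace(n_clonotypes=500, seed=17)
        sample = simulate_sample(cfg, catalog)
        assert len(sample) > 0
        for c in sample.clonotypes:
            assert classify_productivity(c.junction_nt)[0] == c.productive
            if c.productive:
                assert c.junction_aa.startswith("C")
                assert c.junction_aa.endswith(("F", "W"))

    def test_keys_unique(self, catalog):
        cfg = preset("foetal", "DP", "TRB").replace(n_clonotypes=2000, seed=19)
        sample = simulate_sample(cfg, catalog)
        keys = [c.key for c in sample.clonotypes]
        assert len(keys) == len(set(keys))
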