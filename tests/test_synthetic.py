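import math

import numpy as np
import pytest
import scipy.stats as st

from elevdiv.belts import assign_belts, build_grid
from elevdiv.ingest import read_occurrences, clean_occurrences
from elevdiv.synthetic import (
    ScenarioConfig,
    assign_nonnatives,
    simulate_belt_areas,
    simulate_mountain,
    simulate_occurrences,
    simulate_ranges,
    simulate_tree,
    write_mountain,
)


def belt_richness(ranges, grid):
    r = np.zeros(grid.n_belts)
    for lo, hi in ranges.values():
        r[grid.belt_index(lo) : grid.belt_index(hi) + 1] += 1
    return r


class TestTree:
    def test_tip_count_and_determinism(self):
        t1 = simulate_tree(5, seed=4)
        t2 = simulate_tree(5, seed=4)
        assert len(t1.leaf_nodes()) == 5
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_ultrametric(self):
        t = simulate_tree(30, seed=10)
        depths = []
        for leaf in t.leaf_node_iter():
            d, n = 0.0, leaf
            while n.parent_node is not None:
                d += n.edge.length
                n = n.parent_node
            depths.append(d)
        assert max(depths) - min(depths) < 1e-9
        assert all(
            (n.edge.length or 0) >= 0 for n in t.preorder_node_iter() if n is not t.seed_node
        )

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(1, seed=0)


class TestRanges:
    @pytest.mark.parametrize("scenario", ["neutral", "mid_peak", "monotonic_decrease",
                                          "filter_low", "filter_high"])
    def test_ranges_within_span(self, scenario):
        cfg = ScenarioConfig(n_species=60, scenario=scenario, seed=2)
        t = simulate_tree(60, 2)
        for lo, hi in simulate_ranges(t, cfg).values():
            assert cfg.min_elev <= lo <= hi <= cfg.max_elev

    def test_filter_high_confines_a_clade_to_top_third(self):
        cfg = ScenarioConfig(n_species=80, scenario="filter_high", seed=3)
        t = simulate_tree(80, 3)
        ranges = simulate_ranges(t, cfg)
        cutoff = cfg.min_elev + 2 * cfg.span / 3
        confined = [lab for lab, (lo, _) in ranges.items() if lo >= cutoff]
        assert len(confined) >= 0.2 * 80  # at least the chosen clade lives up top

    def test_monotonic_decrease_richness_declines(self):
        cfg = ScenarioConfig(n_species=500, scenario="monotonic_decrease", seed=7)
        t = simulate_tree(500, 7)
        g = build_grid("m", cfg.min_elev, cfg.max_elev, 100)
        rho = st.spearmanr(g.midpoints, belt_richness(simulate_ranges(t, cfg), g)).statistic
        assert rho < -0.8

    def test_reproducible_from_config_seed(self):
        cfg = ScenarioConfig(n_species=40, seed=11)
        t = simulate_tree(40, 11)
        assert simulate_ranges(t, cfg) == simulate_ranges(t, cfg)


class TestOccurrences:
    @staticmethod
    def to_records(occ):
        from elevdiv.ingest import OccurrenceRecord

        out = []
        for r in occ.itertuples():
            e = r.elevation
            if e is None or (isinstance(e, float) and math.isnan(e)):
                e = None
            out.append(OccurrenceRecord(r.taxon, r.mountain, e))
        return out

    def test_clean_run_removes_nothing(self):
        cfg = ScenarioConfig(
            n_species=50, seed=5, duplicate_rate=0.0, missing_elevation_rate=0.0
        )
        ranges = simulate_ranges(simulate_tree(50, 5), cfg)
        occ, _ = simulate_occurrences(ranges, cfg)
        _, rep = clean_occurrences(self.to_records(occ))
        assert rep.no_elevation == 0 and rep.out_of_span_dropped == 0
        # coincidental same-rounded-metre records are the only permissible dups
        assert rep.duplicates <= 0.05 * rep.input

    def test_all_missing_means_no_usable_records(self):
        cfg = ScenarioConfig(n_species=20, seed=6, missing_elevation_rate=1.0)
        ranges = simulate_ranges(simulate_tree(20, 6), cfg)
        occ, _ = simulate_occurrences(ranges, cfg)
        with pytest.raises(ValueError, match="no usable records"):
            clean_occurrences(self.to_records(occ))

    def test_duplicate_rate_binomial(self):
        rate = 0.2
        cfg = ScenarioConfig(
            n_species=200, seed=8, duplicate_rate=rate, missing_elevation_rate=0.0,
            records_per_species=20,
        )
        ranges = simulate_ranges(simulate_tree(200, 8), cfg)
        occ, truth = simulate_occurrences(ranges, cfg)
        _, rep = clean_occurrences(self.to_records(occ))
        n_base = truth["n_base_records"]
        se = math.sqrt(rate * (1 - rate) / n_base)
        # detected duplicates = injected copies + rare rounding coincidences
        assert rep.duplicates / n_base == pytest.approx(rate, abs=3 * se + 0.01)


class TestAreas:
    def test_hump_peaks_centrally_and_positive(self):
        g = build_grid("m", 0, 2000, 100)
        a = simulate_belt_areas(g, "hump", seed=3)["area_km2"].to_numpy()
        assert (a > 0).all()
        assert g.n_belts // 3 <= int(np.argmax(a)) <= 2 * g.n_belts // 3

    def test_monotone_strictly_decreasing(self):
        g = build_grid("m", 0, 1500, 100)
        a = simulate_belt_areas(g, "monotone", seed=4)["area_km2"].to_numpy()
        assert (np.diff(a) < 0).all() and (a > 0).all()


class TestNonnatives:
    def test_zero_fraction_all_native(self):
        cfg = ScenarioConfig(n_species=30, seed=1, nonnative_fraction=0.0)
        t = simulate_tree(30, 1)
        ranges = simulate_ranges(t, cfg)
        aliens, out = assign_nonnatives(t, ranges, cfg)
        assert aliens == set() and out == ranges

    def test_majority_alien_fraction_rejected(self):
        cfg = ScenarioConfig(n_species=30, seed=1, nonnative_fraction=0.6)
        t = simulate_tree(30, 1)
        ranges = simulate_ranges(t, cfg)
        with pytest.raises(ValueError, match="0.5"):
            assign_nonnatives(t, ranges, cfg)

    def test_coupling_raises_native_alien_correlation(self):
        g = build_grid("synthetic", 0, 2000, 100)
        r0, r1 = [], []
        for i in range(15):
            t = simulate_tree(300, i + 500)
            base_cfg = ScenarioConfig(n_species=300, seed=i, nonnative_fraction=0.2,
                                      nonnative_coupling=0.0)
            ranges = simulate_ranges(t, base_cfg, np.random.default_rng(i * 3 + 1))
            for coupling, acc in ((0.0, r0), (1.0, r1)):
                cfg = ScenarioConfig(n_species=300, seed=i, nonnative_fraction=0.2,
                                     nonnative_coupling=coupling)
                aliens, rr = assign_nonnatives(t, dict(ranges), cfg,
                                               np.random.default_rng(i * 3 + 2))
                nat = belt_richness({k: v for k, v in rr.items() if k not in aliens}, g)
                ali = belt_richness({k: v for k, v in rr.items() if k in aliens}, g)
                acc.append(st.pearsonr(nat, ali).statistic)
        assert np.mean(r1) > 0.4  # coupled invaders track native richness
        assert np.mean(r1) > np.mean(r0)


class TestEndToEndRecovery:
    def test_range_through_recovers_truth_exactly_without_noise(self, tmp_path):
        cfg = ScenarioConfig(
            n_species=80, seed=13, elevation_noise_sd_m=0.0,
            duplicate_rate=0.25, missing_elevation_rate=0.15,
        )
        sim = simulate_mountain(cfg)
        paths = write_mountain(sim, tmp_path)
        recs = read_occurrences(paths["occurrences"],
                                spans={cfg.mountain_id: (cfg.min_elev, cfg.max_elev)})
        cleaned, _ = clean_occurrences(recs)
        matrix = assign_belts(cleaned, sim.grid, mode="range_through")
        for sp, entry in sim.truth["species"].items():
            expected = set(entry["belts"])
            got = (
                set(np.flatnonzero(matrix.presence[sp].to_numpy()))
                if sp in matrix.presence.columns
                else set()
            )
            assert got == expected, sp


def test_write_mountain_emits_consumable_files(tmp_path):
    sim = simulate_mountain(ScenarioConfig(n_species=30, seed=21))
    paths = write_mountain(sim, tmp_path)
    from elevdiv.phylodiv import load_tree, tip_labels

    tree = load_tree(paths["tree"])
    assert len(tip_labels(tree)) == 30
    recs = read_occurrences(paths["occurrences"])
    assert len(recs) == len(sim.occurrences)
    assert paths["truth"].read_text().startswith("{")
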