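import numpy as np
import pytest
from scipy import stats

from rifteeg import (PercentChangeMap, SimConfig, base_frequency_validation,
                     largest_neighbor_cluster, neighbor_frequency_validation,
                     percent_change, selection_contrast, simulate_dataset,
                     top_k_electrodes, windowed_power)

from oracles import nx_graph, toy_montage

TOY = toy_montage()


def _pc_map(montage, values):
    """PercentChangeMap from a (participant, condition, channel) array at 14 Hz."""
    values = np.asarray(values, dtype=float)[..., None]
    return PercentChangeMap(
        pc=values, freqs=np.array([14.0]),
        participants=tuple(f"sub-{i + 1:02d}" for i in range(values.shape[0])),
        conditions=("related", "unrelated"),
        channel_names=montage.channel_names)


@pytest.fixture(scope="module")
def low_noise_pc():
    """Two participants at high SNR; topographies dominate every ranking."""
    cfg = SimConfig(n_participants=2, n_trials_per_condition=40,
                    noise_sd=0.01, alpha_amp=0.0, participant_sigma=0.0,
                    seed=12)
    ds = simulate_dataset(cfg)
    pc = percent_change(windowed_power(ds, "tagging"),
                        windowed_power(ds, "baseline"))
    return cfg, pc


class TestTopK:
    def test_exactly_the_six_large_electrodes_are_selected(self, montage):
        vals = np.zeros((1, 2, 31))
        winners = ("F3", "Fz", "C3", "Cz", "P3", "Pz")
        for c in winners:
            vals[:, :, montage.index(c)] = 100.0
        pc = _pc_map(montage, vals)
        assert top_k_electrodes(pc, "sub-01", 14.0, 6) == \
            tuple(c for c in montage.channel_names if c in winners)

    def test_k_equal_channel_count_selects_all(self, montage, rng):
        pc = _pc_map(montage, rng.standard_normal((1, 2, 31)))
        assert top_k_electrodes(pc, "sub-01", 14.0, 31) == montage.channel_names

    def test_ties_broken_by_montage_order(self, montage):
        pc = _pc_map(montage, np.ones((1, 2, 31)))
        assert top_k_electrodes(pc, "sub-01", 14.0, 6) == \
            montage.channel_names[:6]

    def test_conditions_averaged_before_ranking(self, montage):
        vals = np.zeros((1, 2, 31))
        vals[0, 0, montage.index("F3")] = 10.0   # related only
        vals[0, 1, montage.index("P4")] = 30.0   # unrelated only, larger
        pc = _pc_map(montage, vals)
        assert top_k_electrodes(pc, "sub-01", 14.0, 1) == ("P4",)

    def test_off_grid_frequency_rejected(self, montage):
        pc = _pc_map(montage, np.zeros((1, 2, 31)))
        with pytest.raises(ValueError):
            top_k_electrodes(pc, "sub-01", 13.5, 6)

    def test_high_snr_selection_recovers_interaction_support(self, low_noise_pc):
        cfg, pc = low_noise_pc
        expected = set(np.array(cfg.montage.channel_names)
                       [np.argsort(cfg.topo_im)[-6:]])
        for participant in pc.participants:
            assert set(top_k_electrodes(pc, participant, 14.0, 6)) == expected


class TestLargestNeighborCluster:
    def test_fully_connected_selection_returned_whole(self):
        assert largest_neighbor_cluster(("A", "B", "C", "D", "E", "F"), TOY) \
            == ("A", "B", "C", "D", "E", "F")

    def test_largest_component_wins(self, montage):
        got = largest_neighbor_cluster(("O1", "Oz", "O2", "POz", "F7", "F3"),
                                       montage)
        assert set(got) == {"O1", "Oz", "O2", "POz"}

    def test_size_tie_broken_by_largest_value(self, montage):
        # {F3, Fz} and {O1, Oz} are two far-apart components of equal size
        values = {"F3": 1.0, "Fz": 2.0, "O1": 9.0, "Oz": 3.0}
        assert largest_neighbor_cluster(("F3", "Fz", "O1", "Oz"), montage,
                                        values=values) == ("O1", "Oz")
        # without values the tie goes to montage order
        assert largest_neighbor_cluster(("F3", "Fz", "O1", "Oz"), montage) \
            == ("F3", "Fz")

    def test_agrees_with_networkx_components_on_all_selections(self):
        import itertools

        import networkx as nx

        g = nx_graph(TOY)
        for r in range(1, 7):
            for sel in itertools.combinations(TOY.channel_names, r):
                comps = list(nx.connected_components(g.subgraph(sel)))
                biggest = max(len(c) for c in comps)
                got = largest_neighbor_cluster(sel, TOY)
                assert len(got) == biggest
                assert set(got) in [set(c) for c in comps]

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            largest_neighbor_cluster((), TOY)


class TestSelectionContrast:
    def test_equal_conditions_give_zero_t_and_d(self, montage, rng):
        vals = rng.standard_normal((5, 1, 31))
        pc = _pc_map(montage, np.repeat(vals, 2, axis=1))
        res = selection_contrast(pc, montage, freq=14.0)
        assert res.t == 0.0 and res.cohens_d == 0.0 and res.p == 1.0

    def test_matches_longhand_t_and_d(self, montage):
        # cluster means per participant: related - unrelated = [1,1,2,2]
        related = np.array([1.0, 2.0, 3.0, 4.0])
        unrelated = np.array([0.0, 1.0, 1.0, 2.0])
        vals = np.zeros((4, 2, 31))
        vals[:, 0, :] = related[:, None]
        vals[:, 1, :] = unrelated[:, None]
        res = selection_contrast(_pc_map(montage, vals), montage, freq=14.0)
        assert res.t == pytest.approx(5.196152422706632)
        assert res.cohens_d == pytest.approx(2.598076211353316)
        assert res.p == pytest.approx(0.013846832988859045)
        assert res.df == 3

    def test_default_simulation_detects_negative_contrast(self, small_dataset,
                                                          small_cfg):
        pc = percent_change(windowed_power(small_dataset, "tagging"),
                            windowed_power(small_dataset, "baseline"))
        res = selection_contrast(pc, small_cfg.montage, freq=14.0)
        assert res.t < 0  # related < unrelated, the generative ground truth
        assert res.clusters[res.mean_pc.index[0]]  # non-empty cluster
        for participant, cluster in res.clusters.items():
            assert set(cluster) <= set(res.top_k[participant])

    def test_missing_condition_rejected(self, montage, rng):
        pc = _pc_map(montage, rng.standard_normal((3, 2, 31)))
        pc.conditions = ("related", "related")
        with pytest.raises(ValueError):
            selection_contrast(pc, montage, freq=14.0)


class TestValidations:
    def test_peak_most_pronounced_at_14hz(self, small_dataset, small_cfg):
        pc = percent_change(windowed_power(small_dataset, "tagging"),
                            windowed_power(small_dataset, "baseline"))
        table = neighbor_frequency_validation(pc, small_cfg.montage)
        peak = table.loc[table["is_peak"], "frequency_hz"].item()
        assert peak == 14.0

    def test_no_dominant_frequency_without_interaction(self):
        cfg = SimConfig(n_participants=4, n_trials_per_condition=10,
                        g_related=0.0, g_unrelated=0.0, seed=21)
        ds = simulate_dataset(cfg)
        pc = percent_change(windowed_power(ds, "tagging"),
                            windowed_power(ds, "baseline"))
        table = neighbor_frequency_validation(pc, cfg.montage)
        # express as tagging/baseline power ratios: all should hover near 1
        ratio = 1.0 + table["group_mean_percent_change"] / 100.0
        assert ratio.max() / ratio.median() < 2.0

    def test_missing_grid_frequency_rejected(self, small_dataset, small_cfg):
        spec_t = windowed_power(small_dataset, "tagging", f_lo=1, f_hi=15)
        spec_b = windowed_power(small_dataset, "baseline", f_lo=1, f_hi=15)
        pc = percent_change(spec_t, spec_b)
        with pytest.raises(ValueError):
            neighbor_frequency_validation(pc, small_cfg.montage)

    def test_base_frequency_selection_concentrates_on_tag_topographies(
            self, low_noise_pc):
        cfg, pc = low_noise_pc
        counts = base_frequency_validation(pc, cfg.montage)
        names = np.array(cfg.montage.channel_names)
        top_visual = set(names[np.argsort(cfg.topo_visual)[-6:]])
        at68 = counts[68.0]
        assert at68[at68 > 0].index.isin(top_visual).all()
        # auditory selections sit on above-average auditory weights
        at54 = counts[54.0]
        w = dict(zip(names, cfg.topo_audio))
        sel_w = [w[c] for c in at54[at54 > 0].index]
        assert np.mean(sel_w) > cfg.topo_audio.mean()

    def test_equal_topographies_make_selections_coincide(self, low_noise_pc):
        cfg, _ = low_noise_pc
        cfg2 = SimConfig(n_participants=2, n_trials_per_condition=40,
                         noise_sd=0.01, alpha_amp=0.0, participant_sigma=0.0,
                         seed=12, topo_audio=cfg.topo_visual,
                         topo_visual=cfg.topo_visual)
        ds = simulate_dataset(cfg2)
        pc = percent_change(windowed_power(ds, "tagging"),
                            windowed_power(ds, "baseline"))
        counts = base_frequency_validation(pc, cfg2.montage)
        assert (counts[54.0] == counts[68.0]).all()

    def test_k1_allows_singleton_clusters(self, low_noise_pc):
        cfg, pc = low_noise_pc
        res = selection_contrast(pc, cfg.montage, freq=14.0, k=1)
        assert all(len(c) == 1 for c in res.clusters.values())
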