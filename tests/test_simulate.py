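import numpy as np
import pandas as pd
import pytest
import scipy.stats

from seronet.panel import default_panel
from seronet.simulate import (
    ConfigError,
    GroundTruth,
    SyntheticCohortConfig,
    config_from_dict,
    config_from_file,
    config_to_dict,
    generate_cohort,
    ground_truth_edges,
    save_ground_truth,
)


class TestConfigValidation:
    def test_defaults_valid(self):
        config = SyntheticCohortConfig()
        assert config.n_group0 == 52 and config.n_group1 == 27
        assert len(config.panel) == 34
        assert len(config.elevated_analytes) == 8

    def test_unknown_block_analyte_rejected(self):
        with pytest.raises(ConfigError, match="not in panel"):
            SyntheticCohortConfig(
                correlation_blocks_group0=[(frozenset({"IL6", "NOPE"}), 0.5)]
            )

    def test_unknown_elevated_analyte_rejected(self):
        with pytest.raises(ConfigError, match="not in panel"):
            SyntheticCohortConfig(elevated_analytes=("IL6", "NOPE"))

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ConfigError, match="overlap"):
            SyntheticCohortConfig(
                correlation_blocks_group0=[
                    (frozenset({"IL6", "IL10"}), 0.5),
                    (frozenset({"IL10", "IL13"}), 0.5),
                ]
            )

    def test_block_rho_bounds(self):
        with pytest.raises(ConfigError, match="correlation"):
            SyntheticCohortConfig(
                correlation_blocks_group0=[(frozenset({"IL6", "IL10"}), 1.0)]
            )

    def test_correlation_matrices_are_psd(self):
        config = SyntheticCohortConfig()
        for group in (0, 1):
            eigmin = np.linalg.eigvalsh(config.correlation_matrix(group)).min()
            assert eigmin > -1e-10


class TestGroundTruthEdges:
    def test_no_blocks_empty(self):
        config = SyntheticCohortConfig(
            correlation_blocks_group0=[], correlation_blocks_group1=[]
        )
        truth = ground_truth_edges(config, 0.6)
        assert not truth.true_edges_group0 and not truth.true_edges_group1

    def test_triangle_block(self):
        config = SyntheticCohortConfig(
            correlation_blocks_group0=[(frozenset({"IL6", "IL10", "IL13"}), 0.9)],
            correlation_blocks_group1=[],
        )
        truth = ground_truth_edges(config, 0.6)
        assert truth.true_edges_group0 == frozenset(
            {
                frozenset({"IL6", "IL10"}),
                frozenset({"IL6", "IL13"}),
                frozenset({"IL10", "IL13"}),
            }
        )

    def test_two_disjoint_blocks_pair_count(self):
        config = SyntheticCohortConfig(
            correlation_blocks_group0=[
                (frozenset({"IL6", "IL10", "IL13"}), 0.9),
                (frozenset({"TNFa", "IFNa", "IFNg", "IL4"}), 0.9),
            ],
            correlation_blocks_group1=[],
        )
        truth = ground_truth_edges(config, 0.6)
        assert len(truth.true_edges_group0) == 3 + 6  # C(3,2) + C(4,2)

    def test_level_filters_weak_blocks(self):
        config = SyntheticCohortConfig(
            correlation_blocks_group0=[
                (frozenset({"IL6", "IL10"}), 0.9),
                (frozenset({"TNFa", "IFNa"}), 0.3),
            ],
            correlation_blocks_group1=[],
        )
        truth = ground_truth_edges(config, 0.6)
        assert truth.true_edges_group0 == frozenset({frozenset({"IL6", "IL10"})})


class TestGenerateCohort:
    def test_same_seed_bit_identical(self):
        c1, t1 = generate_cohort(SyntheticCohortConfig(seed=5))
        c2, t2 = generate_cohort(SyntheticCohortConfig(seed=5))
        pd.testing.assert_frame_equal(c1.abundance, c2.abundance)
        assert (c1.toxicity == c2.toxicity).all()
        assert t1 == t2

    def test_different_seeds_differ(self):
        c1, _ = generate_cohort(SyntheticCohortConfig(seed=5))
        c2, _ = generate_cohort(SyntheticCohortConfig(seed=6))
        assert not c1.abundance.equals(c2.abundance)

    def test_shapes_and_labels(self):
        cohort, _ = generate_cohort(SyntheticCohortConfig(seed=1))
        assert cohort.abundance.shape == (79, 34)
        assert cohort.group_sizes() == (52, 27)
        assert set(cohort.grade_class) == {"G0G1", "G2G3"}

    def test_censoring_creates_zeros(self):
        cohort, _ = generate_cohort(
            SyntheticCohortConfig(seed=1, lod_censor_fraction=0.1)
        )
        k = int(np.floor(0.1 * 79))
        assert (cohort.abundance == 0).sum().min() == k

    def test_no_censoring_all_positive(self):
        cohort, _ = generate_cohort(
            SyntheticCohortConfig(seed=1, lod_censor_fraction=0.0)
        )
        assert (cohort.abundance > 0).all().all()

    def test_null_config_group_medians_similar(self):
        # shift 0, no blocks: Mann-Whitney p is uniform under repetition
        config = SyntheticCohortConfig(
            seed=0, shift_log_units=0.0,
            correlation_blocks_group0=[], correlation_blocks_group1=[],
            lod_censor_fraction=0.0,
        )
        pvals = []
        for seed in range(80):
            cohort, _ = generate_cohort(
                SyntheticCohortConfig(
                    seed=seed, shift_log_units=0.0,
                    correlation_blocks_group0=[], correlation_blocks_group1=[],
                    lod_censor_fraction=0.0,
                )
            )
            v = np.log(cohort.abundance["IL6"].to_numpy())
            g0 = v[(cohort.toxicity == 0).to_numpy()]
            g1 = v[(cohort.toxicity == 1).to_numpy()]
            pvals.append(scipy.stats.mannwhitneyu(g1, g0, alternative="two-sided").pvalue)
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_block_yields_high_sample_rho(self):
        # a 3-analyte block at 0.95 gives sample Spearman > 0.6 essentially always
        config_kwargs = dict(
            shift_log_units=0.0,
            correlation_blocks_group0=[(frozenset({"IL6", "IL10", "IL13"}), 0.95)],
            correlation_blocks_group1=[],
            lod_censor_fraction=0.0,
        )
        hits = trials = 0
        for seed in range(60):
            cohort, _ = generate_cohort(SyntheticCohortConfig(seed=seed, **config_kwargs))
            frame = np.log(cohort.group_frame(0))
            for a, b in (("IL6", "IL10"), ("IL6", "IL13"), ("IL10", "IL13")):
                rho = scipy.stats.spearmanr(frame[a], frame[b]).statistic
                hits += rho > 0.6
                trials += 1
        assert hits / trials >= 0.99

    def test_draws_independent_of_panel_column_order(self):
        panel = default_panel()
        shuffled = type(panel)(list(reversed(panel.analytes)))
        c1, _ = generate_cohort(SyntheticCohortConfig(seed=3))
        c2, _ = generate_cohort(SyntheticCohortConfig(seed=3, panel=shuffled))
        pd.testing.assert_frame_equal(
            c1.abundance, c2.abundance[c1.abundance.columns]
        )


def test_ground_truth_tsv_round_trip(tmp_path):
    config = SyntheticCohortConfig(seed=2)
    truth = ground_truth_edges(config, 0.6)
    path = save_ground_truth(truth, config, tmp_path / "truth.tsv")
    frame = pd.read_csv(path, sep="\t")
    edges0 = {
        frozenset((a, b))
        for a, b in frame.loc[frame["group"] == 0, ["analyte_a", "analyte_b"]].itertuples(index=False)
    }
    assert edges0 == set(truth.true_edges_group0)
    assert set(frame["planted_rho"]) == {0.9}


def test_config_dict_round_trip(tmp_path):
    config = SyntheticCohortConfig(seed=13, shift_log_units=1.1)
    restored = config_from_dict(config_to_dict(config))
    assert restored.seed == 13
    assert restored.shift_log_units == 1.1
    assert restored.correlation_blocks_group0 == config.correlation_blocks_group0
    import json

    path = tmp_path / "config.json"
    path.write_text(json.dumps(config_to_dict(config)))
    assert config_from_file(path).elevated_analytes == config.elevated_analytes
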