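import numpy as np
import pytest

from pvstrat.contingency import count_stratum, expected_count
from pvstrat.errors import ConfigError
from pvstrat.icsr_model import Sex
from pvstrat.synthetic_data import (
    DEFAULT_DRUG_CATALOG,
    PlantedSignal,
    SimulationConfig,
    default_config,
    generate,
    true_ic,
    truth_table,
)


class TestGenerate:
    def test_same_seed_gives_identical_datasets(self):
        cfg = default_config(n_reports=3000, seed=17)
        a = generate(cfg)
        b = generate(cfg)
        assert a.reports == b.reports

    def test_different_seeds_differ(self):
        a = generate(default_config(n_reports=3000, seed=17))
        b = generate(default_config(n_reports=3000, seed=18))
        assert a.reports != b.reports

    def test_zero_reports_gives_empty_dataset(self):
        ds = generate(default_config(n_reports=0))
        assert ds.n_reports == 0

    def test_reports_have_one_drug_and_nonempty_reactions(self):
        ds = generate(default_config(n_reports=2000, seed=9))
        assert all(len(r.drugs) == 1 for r in ds.reports)
        assert all(len(r.reactions) >= 1 for r in ds.reports)

    def test_case_ids_are_sequential_and_unique(self):
        ds = generate(default_config(n_reports=100, seed=9))
        assert len({r.case_id for r in ds.reports}) == 100
        assert ds.reports[0].case_id < ds.reports[1].case_id

    def test_planted_male_signal_hits_target_ratio_band(self):
        # rho_male = 8 should put the male observed/expected ratio near
        # 8 / (1 + f_drug * 7), well inside [6, 10]; the female stratum
        # stays null within [0.8, 1.25]
        cfg = default_config(
            n_reports=200_000,
            seed=11,
            signals=[PlantedSignal("dupilumab", "conjunctivitis", 8.0, 1.0)],
        )
        ds = generate(cfg)
        cm = count_stratum(ds, "dupilumab", "conjunctivitis", "male")
        assert 6.0 <= cm.n_observed / expected_count(cm) <= 10.0
        cf = count_stratum(ds, "dupilumab", "conjunctivitis", "female")
        assert 0.8 <= cf.n_observed / expected_count(cf) <= 1.25

    def test_zero_rho_pair_never_co_occurs(self):
        cfg = default_config(
            n_reports=50_000,
            seed=13,
            signals=[PlantedSignal("dupilumab", "headache", 0.0, 0.0)],
        )
        ds = generate(cfg)
        assert all(len(r.reactions) >= 1 for r in ds.reports)
        for stratum in ("male", "female"):
            assert count_stratum(ds, "dupilumab", "headache", stratum).n_observed == 0

    def test_drug_marginals_match_catalog_within_three_se(self):
        n = 50_000
        ds = generate(default_config(n_reports=n, seed=23))
        counts = {d: 0 for d in DEFAULT_DRUG_CATALOG}
        for r in ds.reports:
            counts[next(iter(r.drugs))] += 1
        for drug, p in DEFAULT_DRUG_CATALOG.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[drug] / n - p) <= 3 * se

    def test_uniform_reaction_catalog_gives_symmetric_marginals(self):
        n = 50_000
        pts = [f"pt{i}" for i in range(20)]
        cfg = SimulationConfig(
            n_reports=n,
            drug_catalog={"d1": 0.5, "d2": 0.5},
            reaction_catalog={pt: 0.05 for pt in pts},
            reactions_per_report_mean=2.0,
            seed=29,
        )
        ds = generate(cfg)
        mentions = np.zeros(20)
        total = 0
        for r in ds.reports:
            for pt in r.reactions:
                mentions[pts.index(pt)] += 1
                total += 1
        share = mentions / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert np.all(np.abs(share - 0.05) <= 3 * se)

    def test_sex_mix_matches_probabilities(self):
        n = 50_000
        ds = generate(default_config(n_reports=n, seed=31))
        frac_f = sum(1 for r in ds.reports if r.sex is Sex.FEMALE) / n
        assert abs(frac_f - 0.51) <= 3 * np.sqrt(0.51 * 0.49 / n)


class TestTrueIc:
    def test_unplanted_pair_is_zero(self):
        cfg = default_config(n_reports=10)
        assert true_ic(cfg, "dupilumab", "headache", "male") == 0.0

    def test_log2_of_planted_rho(self):
        cfg = default_config(
            n_reports=10,
            signals=[PlantedSignal("dupilumab", "headache", 8.0, 0.5)],
        )
        assert true_ic(cfg, "dupilumab", "headache", "male") == 3.0
        assert true_ic(cfg, "dupilumab", "headache", "female") == -1.0

    def test_unknown_pair_raises(self):
        cfg = default_config(n_reports=10)
        with pytest.raises(KeyError):
            true_ic(cfg, "nosuchdrug", "headache", "male")

    def test_truth_table_lists_all_signals(self):
        cfg = default_config(
            n_reports=10,
            signals=[PlantedSignal("dupilumab", "headache", 2.0, 1.0)],
        )
        table = truth_table(cfg)
        assert len(table) == 1
        assert table.loc[0, "true_ic_male"] == 1.0
        assert table.loc[0, "true_ic_female"] == 0.0


class TestConfigValidation:
    def test_sex_probs_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="sex_probs"):
            default_config(n_reports=10, sex_probs=(0.5, 0.5, 0.1))

    def test_signal_drug_must_exist(self):
        with pytest.raises(ConfigError, match="drug"):
            default_config(
                n_reports=10, signals=[PlantedSignal("ghost", "headache", 2.0, 1.0)]
            )

    def test_negative_rho_rejected(self):
        with pytest.raises(ConfigError, match="rho"):
            default_config(
                n_reports=10,
                signals=[PlantedSignal("dupilumab", "headache", -1.0, 1.0)],
            )

    def test_unknown_yaml_field_is_named(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "n_reports: 10\n"
            "drug_catalog: {d: 1.0}\n"
            "reaction_catalog: {x: 1.0}\n"
            "bogus_field: 3\n"
        )
        with pytest.raises(ConfigError, match="bogus_field"):
            SimulationConfig.from_yaml(path)

    def test_dict_round_trip(self):
        cfg = default_config(
            n_reports=10, signals=[PlantedSignal("dupilumab", "headache", 2.0, 1.0)]
        )
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg
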