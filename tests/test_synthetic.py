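"""Synthetic cohort generator: dynamics, ranges, missingness calibration."""

import numpy as np
import pytest
from scipy import stats

from moodsig.encoding import CLASSES, DEFAULT_RANGES, INSTRUMENTS
from moodsig.synthetic import (
    CohortConfig,
    GroupDynamics,
    MissingnessConfig,
    amoss_like_config,
    empirical_missing_rates,
    generate_cohort,
    inject_missing,
    missingness_only_config,
    simulate_cohort,
)


class TestGenerate:
    def test_scores_within_instrument_ranges(self):
        streams, _ = generate_cohort(amoss_like_config(seed=0))
        bounds = np.array([DEFAULT_RANGES[n] for n in INSTRUMENTS])
        for s in streams:
            assert np.all(s.scores >= 0)
            assert np.all(s.scores <= bounds)
            assert np.all(s.scores == np.rint(s.scores))

    def test_same_seed_reproducible(self):
        a, _ = generate_cohort(amoss_like_config(seed=42))
        b, _ = generate_cohort(amoss_like_config(seed=42))
        for sa, sb in zip(a, b):
            assert sa.participant_id == sb.participant_id
            np.testing.assert_array_equal(sa.scores, sb.scores)

    def test_group_sizes_and_labels(self):
        streams, _ = generate_cohort(amoss_like_config(seed=0))
        counts = {g: sum(1 for s in streams if s.diagnosis == g) for g in CLASSES}
        assert counts == {"BD": 53, "HC": 52, "BPD": 34}

    def test_zero_innovation_gives_constant_scores(self):
        dyn = GroupDynamics(baseline=(2.0, 5.0, 80.0, 3.0),
                            innovation_sd=(0.0, 0.0, 0.0, 0.0))
        cfg = CohortConfig(n_per_group={"HC": 3}, weeks=20,
                           dynamics={g: dyn for g in CLASSES}, seed=0)
        streams, _ = generate_cohort(cfg)
        for s in streams:
            assert np.all(s.scores == s.scores[0])

    def test_zero_hazard_bd_matches_hc_dynamics(self):
        # with episodes off and shared dynamics, BD and HC QIDS means are
        # indistinguishable at two-sample-test level
        dyn = GroupDynamics(baseline=(2.0, 8.0, 75.0, 5.0),
                            innovation_sd=(1.0, 2.0, 5.0, 1.5),
                            episode_hazard=0.0)
        cfg = CohortConfig(n_per_group={"BD": 50, "HC": 50}, weeks=52,
                           dynamics={g: dyn for g in CLASSES}, seed=9)
        streams, _ = generate_cohort(cfg)
        bd = [s.scores[:, 1].mean() for s in streams if s.diagnosis == "BD"]
        hc = [s.scores[:, 1].mean() for s in streams if s.diagnosis == "HC"]
        assert stats.ttest_ind(bd, hc).pvalue > 0.01


class TestInjectMissing:
    def test_no_missing_when_rates_zero(self):
        cfg = CohortConfig(n_per_group={"HC": 3, "BD": 3, "BPD": 3}, weeks=20,
                           missingness=MissingnessConfig(
                               base_rate={g: 0.0 for g in CLASSES}),
                           seed=0)
        streams = simulate_cohort(cfg)
        assert not any(s.missing_mask.any() for s in streams)

    def test_rate_one_blanks_everything(self):
        cfg = CohortConfig(n_per_group={"HC": 2, "BD": 2, "BPD": 2}, weeks=10,
                           missingness=MissingnessConfig(
                               base_rate={g: 1.0 for g in CLASSES}),
                           seed=0)
        streams = simulate_cohort(cfg)
        assert all(s.missing_mask.all() for s in streams)
        from moodsig.encoding import encode_missing
        with pytest.raises(ValueError, match="missing"):
            encode_missing(streams[0])

    def test_empirical_rates_match_configuration(self):
        cfg = CohortConfig(
            n_per_group={"HC": 30, "BD": 30, "BPD": 30}, weeks=52, seed=4,
            missingness=MissingnessConfig(
                base_rate={"HC": 0.05, "BD": 0.25, "BPD": 0.40}),
        )
        rates = empirical_missing_rates(simulate_cohort(cfg))
        for g, target in (("HC", 0.05), ("BD", 0.25), ("BPD", 0.40)):
            assert abs(rates[g] - target) < 0.03

    def test_calibration_tightens_with_size(self):
        errs = []
        for n, weeks in ((5, 20), (40, 80)):
            cfg = CohortConfig(
                n_per_group={g: n for g in CLASSES}, weeks=weeks, seed=8,
                missingness=MissingnessConfig(base_rate={g: 0.3 for g in CLASSES}),
            )
            rates = empirical_missing_rates(simulate_cohort(cfg))
            errs.append(max(abs(r - 0.3) for r in rates.values()))
        assert errs[1] <= errs[0] + 0.01

    def test_whole_week_mode_blanks_rows(self):
        cfg = CohortConfig(
            n_per_group={"BPD": 5}, weeks=40, seed=0,
            missingness=MissingnessConfig(
                base_rate={g: 0.4 for g in CLASSES}, whole_week=True),
        )
        for s in simulate_cohort(cfg):
            mask = s.missing_mask
            assert np.all(mask.any(axis=1) == mask.all(axis=1))

    def test_mnar_links_missingness_to_distress(self):
        cfg = amoss_like_config(seed=6, mnar_coef=2.0,
                                n_per_group={"BD": 40, "HC": 0, "BPD": 0})
        streams, distress = generate_cohort(cfg)
        missing = inject_missing(streams, cfg, distress=distress)
        # weeks in the top distress tercile should miss more often
        hi, lo = [], []
        for s in missing:
            z = distress[s.participant_id]
            m = s.missing_mask.any(axis=1)
            hi.append(m[z > np.quantile(z, 2 / 3)].mean())
            lo.append(m[z < np.quantile(z, 1 / 3)].mean())
        assert np.mean(hi) > np.mean(lo) + 0.05

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            MissingnessConfig(base_rate={"HC": 1.5})


class TestGroupSignalDial:
    def test_score_channels_uninformative_when_dynamics_shared(self):
        """With identical dynamics, per-participant mean scores carry no group
        signal (permutation test on the QIDS means)."""
        streams, _ = generate_cohort(missingness_only_config(seed=10))
        means = np.array([s.scores[:, 1].mean() for s in streams])
        labels = np.array([s.diagnosis for s in streams])
        rng = np.random.default_rng(0)

        def spread(lab):
            return np.var([means[lab == g].mean() for g in CLASSES])

        observed = spread(labels)
        null = [spread(rng.permutation(labels)) for _ in range(500)]
        p = np.mean([n >= observed for n in null])
        assert p > 0.05
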