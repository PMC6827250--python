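import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alginseq import (
    IncompleteSeriesError,
    Mixture,
    NMRReadout,
    NoiseModel,
    SequencingModel,
    TruncationSeries,
    consistency_check,
    forward_readout,
    generate_series,
    joint_under_independence,
    marginals_from_series,
    sequence_small,
    table_percentages,
)


class TestMarginals:
    def test_dp4_series(self, udp4_series):
        p = marginals_from_series(udp4_series)
        assert p == pytest.approx([1 / 4.2, 0.0, 0.0], abs=1e-12)

    def test_dp5_series(self, udp5_series):
        p = marginals_from_series(udp5_series)
        assert p == pytest.approx([3.5 / 4.5, 1.5 / 2.5, 0.0, 0.0])

    def test_missing_levels_reported(self):
        series = TruncationSeries(6, {0: NMRReadout(1, 1, 0, 1), 2: NMRReadout(1, 1, 0, 1)})
        with pytest.raises(IncompleteSeriesError) as exc:
            marginals_from_series(series)
        assert exc.value.missing == (1, 3)

    def test_round_trip_marginals_from_synthetic_series(self):
        mix = Mixture.from_fractions(
            {"ΔGGMMG": 0.3, "ΔMGMMG": 0.25, "ΔGMMMG": 0.25, "ΔMMMMG": 0.2}
        )
        series = generate_series(mix, NoiseModel(cv=0.0))
        p = marginals_from_series(series)
        truth = [
            sum(f for ch, f in mix.entries.items() if ch.residues[i] == "G")
            for i in range(mix.dp - 1)
        ]
        assert p == pytest.approx(truth, abs=1e-12)


class TestJoint:
    def test_udp5_reconstruction(self, udp5_series):
        res = SequencingModel(udp5_series).fit()
        assert res.percentages() == {
            "ΔGGMM": 46.7, "ΔGMMM": 31.1, "ΔMGMM": 13.3, "ΔMMMM": 8.9,
        }

    def test_udp4_reconstruction(self, udp4_series):
        res = SequencingModel(udp4_series).fit()
        assert res.percentages() == {"ΔMMM": 76.0, "ΔGMM": 24.0}

    def test_degenerate_marginals_collapse(self):
        comp, removed = joint_under_independence([1.0, 1.0, 1.0])
        assert comp == {"ΔGGG": 1.0}
        assert removed == 0.0

    def test_prune_bound_and_renormalization(self):
        p = [0.9, 0.9, 0.9]
        thr = 0.01
        comp, removed = joint_under_independence(p, prune_threshold=thr)
        assert removed <= thr * 2 ** len(p)
        assert math.fsum(comp.values()) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0.02, 0.98), min_size=1, max_size=5))
    def test_factorizing_round_trip(self, p):
        """Marginal extraction then independence joint is the identity on factorizing mixtures."""
        comp, _ = joint_under_independence(p, prune_threshold=0.0)
        mix = Mixture.from_fractions(comp, renormalize=True)
        series = generate_series(mix, NoiseModel(cv=0.0))
        model = SequencingModel(series)
        p_rec = model.marginals() if mix.dp > 2 else [model.marginals()[0]]
        assert np.asarray(p_rec) == pytest.approx(np.asarray(p), abs=1e-9)
        res = model.fit(prune_threshold=0.0)
        for seq, f in comp.items():
            assert res.composition[seq] == pytest.approx(f, abs=1e-9)

    def test_moment_matching_for_arbitrary_mixture(self):
        """Even for correlated mixtures the reconstruction reproduces the observed marginals."""
        mix = Mixture.from_fractions({"ΔGGM": 0.5, "ΔMMM": 0.3, "ΔGMM": 0.2})
        series = generate_series(mix, NoiseModel(cv=0.0))
        res = SequencingModel(series).fit(prune_threshold=0.0)
        rec = res.to_mixture()
        p_obs = marginals_from_series(series)
        p_rec = marginals_from_series(generate_series(rec, NoiseModel(cv=0.0)))
        assert p_rec == pytest.approx(p_obs, abs=1e-12)


class TestSequenceSmall:
    def test_dp2_printed_ratio(self):
        res = sequence_small(NMRReadout(3.4, 1.0, 0.0, 0.0), 2)
        assert res.percentages() == {"ΔG": 77.0, "ΔM": 23.0}

    def test_dp3_printed_ratio_with_pure_g_reducing_end(self):
        res = sequence_small(NMRReadout(6.7, 1.0, 1.0, 0.0), 3)
        assert res.percentages() == {"ΔGG": 87.0, "ΔMG": 13.0}

    def test_dp3_even_split_pure_m_end(self):
        res = sequence_small(NMRReadout(1.0, 1.0, 0.0, 1.0), 3)
        assert res.percentages() == {"ΔGM": 50.0, "ΔMM": 50.0}

    def test_larger_dp_rejected(self):
        with pytest.raises(ValueError):
            sequence_small(NMRReadout(1, 1, 0, 1), 4)


class TestConsistency:
    def test_self_consistency_of_independence_joint(self, udp5_series):
        res = SequencingModel(udp5_series).fit()
        report = consistency_check(res)
        assert report.max_residual == pytest.approx(0.0, abs=1e-9)
        assert not report.flagged
        assert "not" in report.note and "identifiable" in report.note

    def test_anticorrelated_mixture_returns_independent_joint(self):
        """Perfectly anti-correlated positions are invisible to marginal data."""
        mix = Mixture.from_fractions({"ΔGM": 0.5, "ΔMG": 0.5})
        series = generate_series(mix, NoiseModel(cv=0.0))
        res = SequencingModel(series).fit()
        assert res.composition == pytest.approx(
            {"ΔGG": 0.25, "ΔGM": 0.25, "ΔMG": 0.25, "ΔMM": 0.25}
        )
        report = consistency_check(res, series)
        assert report.max_residual == pytest.approx(0.0, abs=1e-12)
        assert "identifiable" in str(report)

    def test_summary_states_assumption_and_numbers(self, udp4_series):
        res = SequencingModel(udp4_series).fit()
        text = res.summary()
        assert "ΔMMM" in text and "76" in text
        assert "independence" in text


class TestNoisyRecovery:
    def test_recovered_fractions_under_area_noise(self, udp5_mixture):
        """5% CV multiplicative noise: MAE < 0.03, ΔGGMM centred with SD < 3 points."""
        rng = np.random.default_rng(20260)
        errs, ggmm = [], []
        truth = udp5_mixture.as_str_dict()
        for _ in range(200):
            series = generate_series(udp5_mixture, NoiseModel(cv=0.05), rng=rng)
            res = SequencingModel(series).fit(prune_threshold=0.0)
            for seq, f in truth.items():
                errs.append(abs(res.composition.get(seq, 0.0) - f))
            ggmm.append(100 * res.composition.get("ΔGGMM", 0.0))
        assert np.mean(errs) < 0.03
        assert abs(np.mean(ggmm) - 46.7) < 1.0
        assert np.std(ggmm) < 3.0


def test_table_percentages_rounding_convention():
    assert table_percentages({"ΔG": 0.773, "ΔM": 0.227}) == {"ΔG": 77.0, "ΔM": 23.0}
    assert table_percentages({"a": 0.4667, "b": 0.3111, "c": 0.2222}) == {
        "a": 46.7, "b": 31.1, "c": 22.2,
    }
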