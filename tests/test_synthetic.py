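import numpy as np
import pytest

from alginseq import (
    AlginateModel,
    GlycanChain,
    Mixture,
    NoiseModel,
    SequencingModel,
    fixture_chromatogram,
    generate_chains,
    generate_series,
    integrate_chromatogram,
)


class TestChainGenerator:
    def test_pure_function_of_seed(self):
        model = AlginateModel.mixed(length=(30, 80))
        a = generate_chains(model, 20, seed=9)
        b = generate_chains(model, 20, seed=9)
        assert a == b
        assert a != generate_chains(model, 20, seed=10)

    def test_poly_g_preset_is_g_rich(self):
        chains = generate_chains(AlginateModel.poly_g(), 50, seed=1)
        res = "".join("".join(c.residues) for c in chains)
        assert res.count("G") / len(res) >= 0.9

    def test_poly_m_preset_is_m_rich(self):
        chains = generate_chains(AlginateModel.poly_m(), 50, seed=1)
        res = "".join("".join(c.residues) for c in chains)
        assert res.count("M") / len(res) >= 0.9

    def test_zero_stay_probabilities_alternate(self):
        model = AlginateModel(init_g=0.5, g_stay=0.0, m_stay=0.0, length=40)
        for chain in generate_chains(model, 10, seed=4):
            s = "".join(chain.residues)
            assert "MM" not in s and "GG" not in s

    def test_mean_block_length_matches_geometric_expectation(self):
        model = AlginateModel(init_g=0.5, g_stay=0.8, m_stay=0.8, length=100_000)
        (chain,) = generate_chains(model, 1, seed=12)
        s = "".join(chain.residues)
        blocks = []
        run = 1
        for a, b in zip(s, s[1:]):
            if a == b:
                run += 1
            else:
                blocks.append(run)
                run = 1
        blocks.append(run)
        mean = np.mean(blocks)
        se = np.std(blocks) / np.sqrt(len(blocks))
        assert abs(mean - 5.0) < 3 * se + 0.05

    def test_empirical_g_fraction_near_model_expectation(self):
        model = AlginateModel(init_g=0.5, g_stay=0.7, m_stay=0.7, length=200)
        chains = generate_chains(model, 100, seed=77)
        res = "".join("".join(c.residues) for c in chains)
        g = res.count("G") / len(res)
        # stationary G fraction is 0.5; 3 SE of a conservative binomial bound
        assert abs(g - model.stationary_g) < 3 * 0.5 / np.sqrt(len(res) / 7)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            AlginateModel(init_g=1.2)


class TestSeriesGenerator:
    def test_zero_noise_series_inverts_to_print_rounding(self, udp5_mixture):
        # the published fractions are rounded to 0.1%, so they factorise only
        # to that precision; the noiseless round trip matches within it
        series = generate_series(udp5_mixture, NoiseModel(cv=0.0))
        res = SequencingModel(series).fit()
        for seq, f in udp5_mixture.as_str_dict().items():
            assert res.composition[seq] == pytest.approx(f, abs=5e-4)
        assert res.percentages() == {
            "ΔGGMM": 46.7, "ΔMGMM": 13.3, "ΔGMMM": 31.1, "ΔMMMM": 8.9,
        }

    def test_noise_is_seeded(self, udp5_mixture):
        s1 = generate_series(udp5_mixture, NoiseModel(cv=0.1, seed=5))
        s2 = generate_series(udp5_mixture, NoiseModel(cv=0.1, seed=5))
        assert s1.readouts == s2.readouts


class TestChromatogram:
    def test_integrator_recovers_printed_size_ratio(self):
        """23:52:18.6:4:2.4 across DP2-DP6 is recovered within 1 %."""
        ratio = {2: 23.0, 3: 52.0, 4: 18.6, 5: 4.0, 6: 2.4}
        total = sum(ratio.values())
        props = {d: v / total for d, v in ratio.items()}
        trace = fixture_chromatogram(props)
        report, overlaps = integrate_chromatogram(trace)
        assert overlaps == []
        for d, v in ratio.items():
            got = report.loc[report["species"] == d, "molar_percent"].item()
            assert abs(got - 100 * props[d]) < 1.0

    def test_even_split(self):
        trace = fixture_chromatogram({2: 0.5, 3: 0.5})
        report, _ = integrate_chromatogram(trace)
        assert report["molar_percent"].to_numpy() == pytest.approx([50.0, 50.0], abs=0.5)

    def test_single_species(self):
        trace = fixture_chromatogram({4: 1.0})
        report, overlaps = integrate_chromatogram(trace)
        assert len(report) == 1
        assert report.loc[0, "molar_percent"] == pytest.approx(100.0)
        assert overlaps == []

    def test_overlapping_peaks_flagged(self):
        trace = fixture_chromatogram(
            {2: 0.5, 3: 0.5}, centres={2: 10.0, 3: 10.4}, sigma_ml=0.25
        )
        _, overlaps = integrate_chromatogram(trace, centres={2: 10.0, 3: 10.4}, sigma_ml=0.25)
        assert (2, 3) in overlaps

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            fixture_chromatogram({2: 0.5, 3: 0.4})
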