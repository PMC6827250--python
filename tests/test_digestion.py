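import math
from collections import Counter

import pytest

from alginseq import (
    BlockedSubstrateError,
    DigestError,
    EndoRateTable,
    ExoRateProfile,
    Mixture,
    Monomer,
    SimulationWarning,
    endo_cleave,
    exo_step,
    parse_sequence,
    simulate_digest,
    truncate,
)
from alginseq.io import save_trajectory


class TestEndoCleave:
    def test_saturated_parent(self):
        up, down = endo_cleave(parse_sequence("GGMM"), 2)
        assert str(up) == "GG" and str(down) == "ΔM"

    def test_unsaturated_parent(self):
        up, down = endo_cleave(parse_sequence("ΔGGMM"), 1)
        assert str(up) == "ΔG" and str(down) == "ΔMM"

    def test_label_stays_on_downstream_fragment(self):
        up, down = endo_cleave(parse_sequence("GGMM-2AB"), 2)
        assert up.label == "free" and down.label == "2AB"

    def test_ring_conservation(self):
        parent = parse_sequence("ΔGMGMG")
        for bond in range(1, len(parent.residues)):
            up, down = endo_cleave(parent, bond)
            assert up.dp + down.dp == parent.dp

    def test_delta_count_increases_by_one(self):
        parent = parse_sequence("GMGM")
        up, down = endo_cleave(parent, 2)
        assert sum(c.unsaturated for c in (up, down)) == sum([parent.unsaturated]) + 1

    def test_bond_out_of_range(self):
        with pytest.raises(DigestError):
            endo_cleave(parse_sequence("GM"), 2)


class TestExoStep:
    def test_unsaturated_chain_releases_udp1(self):
        released, rem = exo_step(parse_sequence("ΔGM"))
        assert released is Monomer.UDP1 and str(rem) == "ΔM"
        released, rem = exo_step(rem)
        assert released is Monomer.UDP1 and rem is Monomer.SAT_M

    def test_saturated_dp2_boundary(self):
        released, rem = exo_step(parse_sequence("MM"))
        assert released is Monomer.SAT_M and rem is Monomer.SAT_M

    def test_saturated_chain_first_cut(self):
        released, rem = exo_step(parse_sequence("GMM"))
        assert released is Monomer.SAT_G and str(rem) == "ΔM"

    def test_labelled_ladder_stops_at_labelled_disaccharide(self):
        chain = parse_sequence("ΔMMMM-2AB")
        released = []
        for _ in range(3):
            r, chain = exo_step(chain)
            released.append(r)
        assert released == [Monomer.UDP1] * 3
        assert str(chain) == "ΔM-2AB"
        with pytest.raises(BlockedSubstrateError):
            exo_step(chain)

    def test_monomer_chain_rejected(self):
        with pytest.raises(DigestError):
            exo_step(parse_sequence("Δ"))

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_exhaustive_digestion_of_unsaturated_dp_n(self, n):
        """Δ-DP n resolves into n monomers, n-1 of them unsaturated."""
        chain = parse_sequence("Δ" + "M" * (n - 1))
        released = Counter()
        while not isinstance(chain, Monomer):
            r, chain = exo_step(chain)
            released[r] += 1
        released[chain] += 1
        assert sum(released.values()) == n
        assert released[Monomer.UDP1] == n - 1
        assert released[Monomer.SAT_M] == 1


class TestTruncate:
    def test_table_aggregation_one_cut(self, udp5_mixture):
        out = truncate(udp5_mixture, 1)
        assert out.as_str_dict() == pytest.approx({"ΔGMM": 0.600, "ΔMMM": 0.400})

    def test_two_cuts_collapse(self, udp5_mixture):
        assert truncate(udp5_mixture, 2).as_str_dict() == {"ΔMM": 1.0}

    def test_zero_cuts_identity(self, udp5_mixture):
        assert truncate(udp5_mixture, 0) is udp5_mixture

    def test_over_digestion(self, udp5_mixture):
        with pytest.raises(DigestError):
            truncate(udp5_mixture, 4)

    def test_saturated_mixture_rejected(self):
        with pytest.raises(DigestError):
            truncate(Mixture.from_fractions({"GGM": 1.0}), 1)


class TestSimulateDigest:
    def test_ring_conservation_along_trajectory(self):
        pool = [parse_sequence("GMGMGMGM")] * 5 + [parse_sequence("ΔGGMMGG")] * 3
        traj = simulate_digest(
            pool,
            endo=EndoRateTable.g_preferring(),
            exo=ExoRateProfile.size_dependent(),
            endo_mU=50, exo_mU=50, t_end=math.inf, seed=11,
            calibration=1.0, record="events",
        )
        rings = {s.total_rings() for s in traj}
        assert rings == {traj[0].total_rings()}

    def test_fixed_seed_fixes_serialized_trajectory(self, tmp_path):
        pool = [parse_sequence("GMGMGMGM")] * 4
        paths = []
        for i in (1, 2):
            traj = simulate_digest(
                pool, endo=EndoRateTable.g_preferring(), exo=ExoRateProfile.size_dependent(),
                endo_mU=30, exo_mU=30, t_end=5.0, seed=42, calibration=1.0, record="events",
            )
            p = tmp_path / f"run{i}.tsv"
            save_trajectory(traj, p, seed=42)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_endo_only_never_releases_monomers(self):
        pool = [parse_sequence("GGGGGGGGGG")] * 10
        traj = simulate_digest(
            pool, endo=EndoRateTable.g_preferring(), endo_mU=100,
            t_end=math.inf, seed=3, calibration=1.0, record="events",
        )
        assert all(not s.monomers for s in traj)
        # min fragment sizes >= 2: nothing smaller than a disaccharide appears
        assert all(ch.dp >= 2 for s in traj for ch in s.chains)

    def test_exo_only_no_intermediate_accumulation(self):
        """Exo digestion of a polymer pool gives monomers + shrinking parents only."""
        pool = [parse_sequence("GM" * 10)] * 6
        traj = simulate_digest(
            pool, exo=ExoRateProfile.size_dependent(), exo_mU=100,
            t_end=math.inf, seed=7, calibration=1.0, record="events",
        )
        n0 = traj[0].chain_count()
        for s in traj:
            assert s.chain_count() <= n0
        final = traj[-1]
        assert not final.chains
        assert sum(final.monomers.values()) == 20 * 6

    def test_labelled_pool_absorbs_at_labelled_disaccharide(self):
        pool = [parse_sequence("MMMMM-2AB")] * 8
        traj = simulate_digest(
            pool, exo=ExoRateProfile.size_dependent(), exo_mU=100,
            t_end=math.inf, seed=5, calibration=1.0,
        )
        final = traj[-1]
        assert set(map(str, final.chains)) == {"ΔM-2AB"}
        assert final.chains[parse_sequence("ΔM-2AB")] == 8

    def test_zero_propensity_warns_and_returns_initial_state(self):
        pool = [parse_sequence("GM")]
        with pytest.warns(SimulationWarning):
            traj = simulate_digest(
                pool, endo=EndoRateTable.g_preferring(), endo_mU=10,
                t_end=5.0, seed=1,
            )
        assert traj[-1].chains == traj[0].chains

    def test_exhaustive_exo_monomer_counts(self):
        n0 = 5
        pool = [parse_sequence("ΔMMM")] * n0
        traj = simulate_digest(
            pool, exo=ExoRateProfile.flat(), exo_mU=100, t_end=math.inf, seed=2,
            calibration=1.0,
        )
        final = traj[-1]
        # Δ-DP4 resolves into 3 unsaturated + 1 saturated monomer per chain
        assert final.monomers[Monomer.UDP1] == 3 * n0
        assert final.monomers[Monomer.SAT_M] == n0
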