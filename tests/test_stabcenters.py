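import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gjdock.core import AnalysisParameters, GJDockError
from gjdock.stabcenters import (
    classify_trans_gj,
    detect_scs_frame,
    filter_extracellular,
    is_stabilization_center,
    residue_contact,
    sc_timeseries,
)
from gjdock.synthetic import (
    deterministic_schedule,
    make_contact_probe,
    make_sc_fixture,
    make_trajectory,
)

from conftest import random_toy_structure
from oracle import (
    brute_best_triplet_count,
    brute_contact,
    brute_detect_scs,
    brute_is_sc,
)


class TestResidueContact:
    def test_two_carbons_just_inside_vdw_plus_tolerance(self):
        # C-C threshold: 1.70 + 1.70 + 1.0 = 4.40 Å
        ok, d = residue_contact(make_contact_probe(4.3), ("A", 10), ("B", 10))
        assert ok and d == pytest.approx(4.3)

    def test_two_carbons_outside_threshold(self):
        ok, d = residue_contact(make_contact_probe(4.5), ("A", 10), ("B", 10))
        assert not ok and d == pytest.approx(4.5)

    def test_threshold_depends_on_elements(self):
        # N-N threshold: 1.55 + 1.55 + 1.0 = 4.10 Å
        s = make_contact_probe(4.2, element="N")
        ok, _ = residue_contact(s, ("A", 10), ("B", 10))
        assert not ok
        ok, _ = residue_contact(make_contact_probe(4.0, element="N"),
                                ("A", 10), ("B", 10))
        assert ok

    @given(st.integers(min_value=0, max_value=10_000))
    def test_multi_atom_residues_match_exhaustive_check(self, seed):
        rng = np.random.default_rng(seed)
        s = random_toy_structure(rng, n_chains=2, n_res=6)
        for ra in [("A", 2), ("A", 5)]:
            for rb in [("B", 1), ("B", 4)]:
                got = residue_contact(s, ra, rb)
                want = brute_contact(s, ra, rb)
                assert got[0] == want[0]
                assert got[1] == pytest.approx(want[1])


class TestIsStabilizationCenter:
    def test_planted_cross_chain_pair_is_sc(self, sc_default):
        s, m = sc_default
        (a, b), = [tuple(map(tuple, p)) for p in m["planted_sc"]]
        assert is_stabilization_center(s, ("A", 10), ("B", 10))

    def test_contact_with_splayed_flanks_is_not_sc(self, sc_default):
        s, _ = sc_default
        ok, _ = residue_contact(s, ("C", 10), ("D", 10))
        assert ok
        assert not is_stabilization_center(s, ("C", 10), ("D", 10))

    def test_same_chain_pair_five_apart_fails_separation(self):
        s, m = make_sc_fixture("crit1-fail")
        ok, _ = residue_contact(s, ("E", 8), ("E", 13))
        assert ok  # geometry is tight...
        assert not is_stabilization_center(s, ("E", 8), ("E", 13))  # ...but 5 < 10

    def test_best_triplet_of_six_contacts_fails(self):
        s, _ = make_sc_fixture("six-of-nine")
        # independent oracle: the best 4x4x4x4 flank selection yields exactly 6
        best = brute_best_triplet_count(
            s, ("F", 10), ("G", 10),
            la=[6, 7, 8, 9], ua=[11, 12, 13, 14],
            lb=[6, 7, 8, 9], ub=[11, 12, 13, 14])
        assert best == 6
        assert not is_stabilization_center(s, ("F", 10), ("G", 10))

    def test_sc_relation_is_symmetric(self, sc_default):
        s, _ = sc_default
        for pair in [(("A", 10), ("B", 10)), (("C", 10), ("D", 10)),
                     (("A", 9), ("B", 10))]:
            assert is_stabilization_center(s, *pair) == \
                is_stabilization_center(s, *pair[::-1])

    def test_chain_terminus_without_flank_fails(self):
        # residue 1 has no left flanking tetrapeptide at all
        s, _ = make_sc_fixture("default")
        assert not is_stabilization_center(s, ("A", 1), ("B", 1))

    def test_enlarging_tolerance_never_removes_an_sc(self, sc_default):
        s, _ = sc_default
        loose = AnalysisParameters(sc_vdw_tolerance=1.6)
        for pair in [(("A", 10), ("B", 10)), (("A", 9), ("B", 9))]:
            if is_stabilization_center(s, *pair):
                assert is_stabilization_center(s, *pair, params=loose)


class TestDetectScsFrame:
    def test_only_the_planted_pair_is_detected(self, sc_default):
        s, _ = sc_default
        found = {(p.res_a[:2], p.res_b[:2]) for p in detect_scs_frame(s)}
        assert found == {(("A", 10), ("B", 10))}

    def test_straight_glycine_chain_has_no_scs(self):
        from gjdock.core import Structure
        n = 12
        s = Structure(
            chain_ids=np.array(["A"] * n), res_nums=np.arange(1, n + 1),
            res_names=np.array(["GLY"] * n), names=np.array(["CA"] * n),
            elements=np.array(["C"] * n),
            coords=np.outer(np.arange(n), [3.8, 0, 0]))
        assert detect_scs_frame(s) == []

    def test_empty_scope_yields_empty_list(self, sc_default):
        s, _ = sc_default
        assert detect_scs_frame(s, scope=set()) == []

    def test_trans_gj_pairs_annotated_on_docked_model(self, connexon_closed12):
        s, m = connexon_closed12
        found = detect_scs_frame(s)
        trans = {tuple(sorted((p.res_a[:2], p.res_b[:2])))
                 for p in found if p.is_trans_gj}
        expected = {tuple(sorted((tuple(a), tuple(b))))
                    for a, b in m["expected"]["trans_gj_sc_pairs"]}
        assert trans == expected
        labels = {p.subunit_pair_label for p in found if p.is_trans_gj}
        assert labels == {"A-J", "B-I", "C-H", "D-G", "E-L", "F-K"}

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=10)
    def test_matches_exhaustive_bruteforce_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        s = random_toy_structure(rng, n_chains=2, n_res=18)
        got = {tuple(sorted((p.res_a[:2], p.res_b[:2])))
               for p in detect_scs_frame(s)}
        want = {tuple(sorted(p)) for p in brute_detect_scs(s)}
        assert got == want


class TestClassifyTransGj:
    def test_canonical_docking_pair(self):
        assert classify_trans_gj("A", "J") == ("trans-GJ", "A-J")

    def test_non_canonical_cross_pair_keeps_literal_label(self):
        cls, label = classify_trans_gj("A", "K")
        assert cls == "trans-GJ" and label == "A-K"

    def test_intra_hc_and_intra_subunit(self):
        assert classify_trans_gj("A", "B")[0] == "inter-subunit-intra-HC"
        assert classify_trans_gj("C", "C")[0] == "intra-subunit"

    def test_unknown_chain_raises(self):
        with pytest.raises(GJDockError):
            classify_trans_gj("A", "Z")


class TestScTimeseries:
    def test_deterministic_half_on_schedule_recovers_half(self, sc_default):
        s, m = sc_default
        sched = {"sc_pair": deterministic_schedule(40, 0.5)}
        traj, _ = make_trajectory(s, jitter_sigma=0.0, schedule=sched,
                                  n_frames=40,
                                  interactions=m["interactions"])
        table, _ = sc_timeseries(traj)
        assert len(table) == 1
        assert table["fraction"].iloc[0] == 0.5
        assert table["n_frames_present"].iloc[0] == 20

    def test_single_frame_fractions_are_zero_or_one(self, sc_default):
        s, m = sc_default
        traj, _ = make_trajectory(s, n_frames=1,
                                  interactions=m["interactions"])
        table, _ = sc_timeseries(traj)
        assert set(table["fraction"]) <= {0.0, 1.0}

    def test_reported_min_distance_matches_per_frame_oracle(self, sc_default):
        s, m = sc_default
        traj, _ = make_trajectory(s, jitter_sigma=0.05, n_frames=5, seed=4,
                                  interactions=m["interactions"])
        table, _ = sc_timeseries(traj)
        row = table.iloc[0]
        per_frame = [brute_contact(traj.frame(i),
                                   (row.chain_a, row.res_a),
                                   (row.chain_b, row.res_b))[1]
                     for i in range(traj.n_frames)]
        assert row.d_min == pytest.approx(min(per_frame))
        assert row.d_max == pytest.approx(max(per_frame))


class TestFilterExtracellular:
    @pytest.fixture()
    def table(self):
        import pandas as pd
        rows = [
            dict(chain_a="A", res_a=50, name_a="GLY", chain_b="J", res_b=190,
                 name_b="GLY", fraction=0.05),
            dict(chain_a="A", res_a=50, name_a="GLY", chain_b="J", res_b=190,
                 name_b="GLY", fraction=0.01),
            dict(chain_a="A", res_a=100, name_a="GLY", chain_b="A", res_b=150,
                 name_b="GLY", fraction=0.9),
        ]
        return pd.DataFrame(rows)

    def test_kept_removed_by_fraction_and_region(self, table):
        out = filter_extracellular(table)
        assert len(out) == 1
        assert out.iloc[0]["fraction"] == 0.05

    def test_threshold_is_inclusive_at_two_percent(self, table):
        table.loc[1, "fraction"] = 0.02
        out = filter_extracellular(table)
        assert len(out) == 2
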