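import numpy as np
import pytest

from gjdock.core import AnalysisParameters, GJDockError, Trajectory
from gjdock.interactions import (
    assign_disulfides,
    detect_cys_cys_hbonds,
    detect_cys_interface_hbonds,
    detect_disulfides,
    detect_trans_gj_hbonds,
    hbond_timeseries,
    hydrogen_attachment,
)
from gjdock.synthetic import (
    deterministic_schedule,
    make_hbond_probe,
    make_toy_connexon,
    make_trajectory,
)

from oracle import brute_cys_cys_hbonds, brute_trans_gj_hbonds


class TestTransGjDetector:
    def test_bond_just_inside_cutoff(self):
        bonds = detect_trans_gj_hbonds(make_hbond_probe("trans_gj", 2.4))
        assert len(bonds) == 1
        b = bonds[0]
        assert b.distance == pytest.approx(2.4)
        assert b.donor[2] == "NE2" and b.acceptor[2] == "OE1"
        assert b.subunit_pair_label == "A-J"

    def test_bond_just_outside_cutoff(self):
        assert detect_trans_gj_hbonds(make_hbond_probe("trans_gj", 2.6)) == []

    def test_intra_hc_pairs_excluded_by_default(self):
        s = make_hbond_probe("trans_gj", 2.0)
        s.chain_ids[s.chain_ids == "J"] = "B"  # move acceptor into HC1
        s._res_index = None
        assert detect_trans_gj_hbonds(s) == []
        intra = detect_trans_gj_hbonds(s, cross_hc_only=False)
        assert len(intra) == 1

    def test_missing_hydrogens_is_an_error(self):
        s = make_hbond_probe("trans_gj", 2.4)
        s2 = s[~s.is_hydrogen]
        with pytest.raises(GJDockError, match="hydrogens are required"):
            detect_trans_gj_hbonds(s2)

    def test_matches_bruteforce_on_jittered_interface(self, connexon_open12):
        s, _ = connexon_open12
        rng = np.random.default_rng(11)
        jittered = s.with_coords(s.coords + rng.normal(scale=0.3,
                                                       size=s.coords.shape))
        got = {(b.donor, b.acceptor)
               for b in detect_trans_gj_hbonds(jittered)}
        want = {((str(jittered.chain_ids[d]), int(jittered.res_nums[d]),
                  str(jittered.names[d])),
                 (str(jittered.chain_ids[a]), int(jittered.res_nums[a]),
                  str(jittered.names[a])))
                for d, h, a in brute_trans_gj_hbonds(jittered)}
        assert got == want

    def test_count_monotone_in_cutoff(self, connexon_open12):
        s, _ = connexon_open12
        counts = [len(detect_trans_gj_hbonds(
            s, params=AnalysisParameters(hbond_HA_cutoff=c)))
            for c in (1.5, 2.5, 3.5, 5.0)]
        assert counts == sorted(counts)


class TestCysCysDetector:
    def test_boundary_distances(self):
        assert len(detect_cys_cys_hbonds(make_hbond_probe("cys_cys", 4.2))) == 1
        assert detect_cys_cys_hbonds(make_hbond_probe("cys_cys", 4.4)) == []

    def test_dozen_bonds_on_open_two_hexamer_model(self, connexon_open12):
        s, _ = connexon_open12
        bonds = detect_cys_cys_hbonds(s)
        assert len(bonds) == 12  # one donor + one acceptor geometry per subunit
        # each bond is the 65C thiol donating to its own subunit's 187C
        for b in bonds:
            assert b.donor[1] == 65 and b.acceptor[1] == 187
            assert b.donor[0] == b.acceptor[0]

    def test_oxidized_cys_contribute_nothing(self, connexon_closed12):
        s, _ = connexon_closed12
        assert detect_cys_cys_hbonds(s) == []

    def test_matches_bruteforce(self, connexon_open12):
        s, _ = connexon_open12
        got = {(b.donor, b.hydrogen, b.acceptor)
               for b in detect_cys_cys_hbonds(s)}
        ref = {((str(s.chain_ids[d]), int(s.res_nums[d]), str(s.names[d])),
                (str(s.chain_ids[h]), int(s.res_nums[h]), str(s.names[h])),
                (str(s.chain_ids[a]), int(s.res_nums[a]), str(s.names[a])))
               for d, h, a in brute_cys_cys_hbonds(s)}
        assert got == ref

    def test_scope_restricts_cys_residues(self, connexon_open12):
        s, _ = connexon_open12
        only_a = {("A", 65), ("A", 187)}
        bonds = detect_cys_cys_hbonds(s, scope=only_a)
        assert len(bonds) == 1 and bonds[0].donor[0] == "A"


class TestCysInterfaceDetector:
    def test_both_criteria_met(self):
        s = make_hbond_probe("cys_interface", 3.1, s_heavy_distance=4.0)
        bonds = detect_cys_interface_hbonds(s)
        assert len(bonds) == 1
        b = bonds[0]
        assert b.distance == pytest.approx(3.1)
        assert b.distance_secondary == pytest.approx(4.0)
        assert b.donor[2] == "SG" and b.acceptor[2] == "O"

    def test_hydrogen_criterion_alone_fails(self):
        s = make_hbond_probe("cys_interface", 3.3, s_heavy_distance=4.0)
        assert detect_cys_interface_hbonds(s) == []

    def test_sulphur_criterion_alone_fails(self):
        s = make_hbond_probe("cys_interface", 3.1, s_heavy_distance=4.2)
        assert detect_cys_interface_hbonds(s) == []


class TestAuditInvariant:
    def test_no_detector_returns_a_bond_violating_its_cutoffs(self,
                                                              connexon_open12):
        s, _ = connexon_open12
        p = AnalysisParameters()
        for b in detect_trans_gj_hbonds(s, params=p):
            assert b.distance < p.hbond_HA_cutoff
        for b in detect_cys_cys_hbonds(s, params=p):
            assert b.distance < p.cys_cys_SH_cutoff
        for b in detect_cys_interface_hbonds(s, params=p):
            assert b.distance < p.cys_iface_H_cutoff
            assert b.distance_secondary < p.cys_iface_S_heavy_cutoff


class TestHbondTimeseries:
    def test_scheduled_bond_presence_fraction(self, connexon_open12):
        s, m = connexon_open12
        sched = {"cys_cys_hbonds": deterministic_schedule(20, 0.5)}
        traj, _ = make_trajectory(s, schedule=sched, n_frames=20,
                                  interactions=m["interactions"])
        counts, presence, _ = hbond_timeseries(traj, detect_cys_cys_hbonds)
        assert (counts["n_bonds"] > 0).mean() == 0.5
        assert counts["n_bonds"].max() == 12

    def test_counting_restricted_to_first_hexamer(self, connexon_open12):
        s, m = connexon_open12
        traj, _ = make_trajectory(s, n_frames=1,
                                  interactions=m["interactions"])
        all_counts, _, _ = hbond_timeseries(traj, detect_cys_cys_hbonds,
                                            chains_counted="all")
        half_counts, _, _ = hbond_timeseries(traj, detect_cys_cys_hbonds,
                                             chains_counted="ABCDEF")
        assert all_counts["n_bonds"].iloc[0] == 12
        assert half_counts["n_bonds"].iloc[0] == 6  # G-L bonds excluded

    def test_presence_matrix_counts_subunit_pairs(self, connexon_open12):
        s, m = connexon_open12
        traj, _ = make_trajectory(s, n_frames=2,
                                  interactions=m["interactions"])
        _, presence, _ = hbond_timeseries(traj, detect_trans_gj_hbonds)
        assert list(presence.columns) == ["58Q-58Q"]
        assert (presence["58Q-58Q"] == 6).all()  # on all six subunit pairs


class TestDisulfides:
    def test_dodecamer_has_36_canonical_bonds(self, connexon_closed12):
        s, _ = connexon_closed12
        bonds = detect_disulfides(s)
        assert len(bonds) == 36
        assert all(b.canonical for b in bonds)
        assert all(b.sg_sg_distance == pytest.approx(2.05, abs=1e-6)
                   for b in bonds)

    def test_hexamer_has_18_bonds(self, connexon_closed6):
        s, _ = connexon_closed6
        assert len(detect_disulfides(s)) == 18

    def test_open_geometry_has_none(self, connexon_open12):
        s, _ = connexon_open12
        assert detect_disulfides(s) == []

    def test_typical_bond_length_detected_loose_pair_not(self):
        from gjdock.synthetic import make_contact_probe
        s = make_contact_probe(2.05, element="S")
        s.names[:] = "SG"
        s.res_names[:] = "CYS"
        s._res_index = None
        assert len(detect_disulfides(s)) == 1
        s2 = make_contact_probe(3.5, element="S")
        s2.names[:] = "SG"
        s2.res_names[:] = "CYS"
        s2._res_index = None
        assert detect_disulfides(s2) == []

    def test_assign_closed_records_and_strips_thiol_h(self, connexon_open6):
        s, _ = connexon_open6
        out, bonds = assign_disulfides(s, mode="closed")
        assert len(bonds) == 18
        assert all(b.state == "closed" for b in bonds)
        assert not any(n in ("HG1", "HG") for n in out.names)

    def test_assign_open_adds_thiol_h_everywhere(self, connexon_closed6):
        s, _ = connexon_closed6
        out, bonds = assign_disulfides(s, mode="open")
        assert bonds == []
        attach = hydrogen_attachment(out)
        sg_idx = [i for i in range(len(out))
                  if str(out.names[i]) == "SG"]
        assert all(any(str(out.names[h]) == "HG1" for h in attach.get(i, ()))
                   for i in sg_idx)
        # HG1 sits 1.34 Å from SG, opposed to CB
        for i in sg_idx:
            hs = [h for h in attach[i] if str(out.names[h]) == "HG1"]
            d = np.linalg.norm(out.coords[hs[0]] - out.coords[i])
            assert d == pytest.approx(1.34, abs=1e-6)

    def test_assign_then_detect_finds_three_per_chain(self, connexon_closed6):
        s, _ = connexon_closed6
        out, _ = assign_disulfides(s, mode="closed")
        bonds = detect_disulfides(out)
        per_chain = {}
        for b in bonds:
            per_chain[b.chain_a] = per_chain.get(b.chain_a, 0) + 1
        assert per_chain == {c: 3 for c in "ABCDEF"}

    def test_missing_canonical_cys_names_chain_and_residue(self,
                                                           connexon_closed6):
        s, _ = connexon_closed6
        pruned = s[~((s.chain_ids == "B") & (s.res_nums == 61))]
        with pytest.raises(GJDockError, match="chain B.*61"):
            assign_disulfides(pruned, mode="closed")
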