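import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from gjdock.core import ConnexinAnnotation, GJDockError, Trajectory
from gjdock.geometry import (
    build_hc_hc,
    clash_report,
    extracellular_rmsd_series,
    kabsch_superpose,
    translate_chains,
)
from gjdock.synthetic import make_contact_probe

from oracle import brute_clashes


class TestKabsch:
    def test_identical_clouds_give_zero_rmsd_identity_rotation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        res = kabsch_superpose(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_rotated_copy_superposes_exactly(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        res = kabsch_superpose(x @ rot.T + [3, -2, 5], x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_independent_svd_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(size=(10, 3))
        reference = rng.normal(size=(10, 3))
        res = kabsch_superpose(mobile, reference)
        # oracle: scipy's least-squares rotation on centred clouds
        mc = mobile - mobile.mean(0)
        rc = reference - reference.mean(0)
        rot, rssd = Rotation.align_vectors(rc, mc)
        assert np.allclose(res.rotation, rot.as_matrix(), atol=1e-8)
        assert res.rmsd == pytest.approx(rssd / np.sqrt(10), abs=1e-9)
        # the transform is proper and actually optimal
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(GJDockError, match=">= 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(GJDockError, match="collinear"):
            kabsch_superpose(line, line)


@pytest.fixture()
def closed6(connexon_closed6):
    return connexon_closed6[0]


class TestExtracellularRmsd:

    def test_identical_frames_give_zero_series(self, closed6):
        traj = Trajectory(closed6, np.stack([closed6.coords] * 3))
        assert np.allclose(extracellular_rmsd_series(traj), 0.0)

    def test_uniform_extracellular_shift_gives_exactly_that_rmsd(self, closed6):
        ann = ConnexinAnnotation()
        shifted = closed6.coords.copy()
        ec = ann.extracellular_mask(closed6.res_nums) & closed6.heavy_mask
        shifted[ec] += [1.0, 0.0, 0.0]
        traj = Trajectory(closed6, np.stack([closed6.coords, shifted]))
        series = extracellular_rmsd_series(traj)
        assert series[0] == 0.0
        # TM atoms untouched -> alignment is identity -> closed form 1.0 Å
        assert series[1] == pytest.approx(1.0, abs=1e-9)

    def test_rigid_whole_frame_motion_is_removed(self, closed6):
        rot = Rotation.from_euler("xyz", [13, -7, 40], degrees=True).as_matrix()
        moved = closed6.coords @ rot.T + [4.0, -1.0, 2.5]
        traj = Trajectory(closed6, np.stack([closed6.coords, moved]))
        series = extracellular_rmsd_series(traj)
        assert series[1] == pytest.approx(0.0, abs=1e-8)

    def test_missing_regions_are_reported(self, sc_default):
        s, _ = sc_default  # toy strands carry no connexin numbering
        traj = Trajectory(s, s.coords[None])
        with pytest.raises(GJDockError, match="missing residues"):
            extracellular_rmsd_series(traj)


class TestTranslateChains:
    def test_offset_is_exact(self, connexon_closed6):
        s, _ = connexon_closed6
        out = translate_chains(s, ["A", "B"], 3.0)
        mask = np.isin(s.chain_ids, ["A", "B"])
        assert np.all(out.coords[mask, 2] - s.coords[mask, 2] == 3.0)
        assert np.array_equal(out.coords[~mask], s.coords[~mask])

    def test_zero_offset_is_identity(self, connexon_closed6):
        s, _ = connexon_closed6
        assert np.array_equal(translate_chains(s, ["A"], 0.0).coords, s.coords)

    def test_inverse_restores_coordinates(self, connexon_closed6):
        s, _ = connexon_closed6
        back = translate_chains(translate_chains(s, ["C"], 5.0), ["C"], -5.0)
        assert np.allclose(back.coords, s.coords, atol=1e-12)

    def test_intra_group_distances_preserved(self, connexon_closed6):
        s, _ = connexon_closed6
        out = translate_chains(s, ["A"], 7.3)
        mask = s.chain_ids == "A"
        d0 = np.linalg.norm(s.coords[mask][:50, None] - s.coords[mask][None, :50],
                            axis=-1)
        d1 = np.linalg.norm(out.coords[mask][:50, None]
                            - out.coords[mask][None, :50], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)

    def test_unknown_chain_rejected(self, connexon_closed6):
        s, _ = connexon_closed6
        with pytest.raises(GJDockError, match="Z"):
            translate_chains(s, ["Z"], 1.0)


class TestClashReport:
    def test_pair_inside_cutoff_is_reported(self):
        s = make_contact_probe(1.9)
        clashes = clash_report(s, ["A"], ["B"], cutoff=2.0)
        assert len(clashes) == 1
        assert clashes[0][2] == pytest.approx(1.9)

    def test_cutoff_is_strict(self):
        s = make_contact_probe(2.0)
        assert clash_report(s, ["A"], ["B"], cutoff=2.0) == []

    def test_overlapping_groups_rejected(self, connexon_closed6):
        s, _ = connexon_closed6
        with pytest.raises(GJDockError, match="overlap"):
            clash_report(s, ["A", "B"], ["B", "C"])

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_bruteforce_enumeration(self, seed):
        from conftest import random_toy_structure
        rng = np.random.default_rng(seed)
        s = random_toy_structure(rng, n_chains=2, n_res=12)
        got = clash_report(s, ["A"], ["B"], cutoff=3.0)
        want = brute_clashes(s, {"A"}, {"B"}, cutoff=3.0)
        assert [(a, b) for a, b, _ in got] == [(a, b) for a, b, _ in want]
        assert np.allclose([d for *_, d in got], [d for *_, d in want])


class TestBuildHcHc:
    def test_self_alignment_superposes_exactly(self, connexon_closed12):
        tpl, _ = connexon_closed12
        sub = tpl[np.isin(tpl.chain_ids, list("ABCDEF"))]
        merged, log = build_hc_hc(sub, tpl)
        assert max(log.per_chain_rmsd.values()) == pytest.approx(0.0, abs=1e-9)
        assert sorted(merged.chains()) == list("ABCDEFGHIJKL")
        # copy 1 lands exactly on the template's A-F half
        half = np.isin(merged.chain_ids, list("ABCDEF"))
        tpl_half = np.isin(tpl.chain_ids, list("ABCDEF"))
        assert np.allclose(merged.coords[half], tpl.coords[tpl_half],
                           atol=1e-9)

    def test_serials_continue_across_copies(self, connexon_closed6,
                                            connexon_closed12):
        hc, _ = connexon_closed6
        tpl, _ = connexon_closed12
        merged, _ = build_hc_hc(hc, tpl)
        n1 = len(hc)
        assert merged.serials[0] == 1
        assert merged.serials[n1 - 1] == n1
        assert merged.serials[n1] == n1 + 1  # second copy numbering continues
        assert merged.serials[-1] == 2 * n1

    def test_interface_clashes_are_reported_not_resolved(self,
                                                         connexon_closed6,
                                                         connexon_closed12):
        hc, _ = connexon_closed6
        tpl, _ = connexon_closed12
        squeezed = translate_chains(tpl, list("ABCDEF"), 3.0)  # force overlap
        merged, log = build_hc_hc(hc, squeezed)
        assert isinstance(log.clashes, list)
        # output geometry follows the template, clashes included
        assert sorted(merged.chains()) == list("ABCDEFGHIJKL")

    def test_wrong_template_chain_count_rejected(self, connexon_closed6,
                                                 connexon_closed12):
        hc, _ = connexon_closed6
        tpl, _ = connexon_closed12
        eleven = tpl[tpl.chain_ids != "L"]
        with pytest.raises(GJDockError, match="12 chains"):
            build_hc_hc(hc, eleven)

    def test_wrong_hc_chain_count_rejected(self, connexon_closed12):
        tpl, _ = connexon_closed12
        with pytest.raises(GJDockError, match="6 chains"):
            build_hc_hc(tpl, tpl)
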