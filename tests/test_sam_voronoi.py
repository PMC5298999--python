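"""Power-diagram restriction geometry, interfaces and shelling orders."""

import math

import numpy as np
import pytest

from igvor import fixtures as fx
from igvor.sam_voronoi import (SAMBall, build_sam, compute_restrictions,
                               extract_interface, shelling_orders,
                               union_volume_oracle)
from igvor.structure_model import AtomRecord

from conftest import brute_force_shelling, shrake_rupley_areas


def _carbon(aid, x, y, z, partner="Ig", chain="H"):
    name = "HOH" if partner == "water" else "ALA"
    return AtomRecord(atom_id=aid, element="C" if partner != "water" else "O",
                      center=(x, y, z), r_vdw=1.7 if partner != "water" else 1.52,
                      residue_name=name, residue_seq="1", chain_id=chain,
                      partner=partner,
                      region="water" if partner == "water" else "constant/outside-V")


class TestBuildSam:
    def test_probe_expansion_and_order(self):
        atoms = [_carbon(f"a{i}", 2.0 * i, 0, 0) for i in range(10)]
        balls = build_sam(atoms, r_w=1.4)
        assert len(balls) == 10
        assert [b.atom_id for b in balls] == [a.atom_id for a in atoms]
        assert all(b.radius_expanded == pytest.approx(3.10) for b in balls)

    def test_zero_probe_keeps_vdw_radii(self):
        balls = build_sam([_carbon("a", 0, 0, 0)], r_w=0.0)
        assert balls[0].radius_expanded == pytest.approx(1.70)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_sam([])


class TestRestrictions:
    def test_single_ball_closed_form(self):
        r = compute_restrictions([SAMBall("a", (0, 0, 0), 2.0)])["a"]
        assert r.volume_bound == pytest.approx(4 / 3 * math.pi * 8, rel=1e-12)
        assert r.exposed_area_bound == pytest.approx(4 * math.pi * 4, rel=1e-12)
        assert r.neighbors == set()

    @pytest.mark.parametrize("d, r1, r2", [
        (2.0, 2.0, 2.0), (2.1, 1.7, 1.4), (0.9, 1.9, 1.2), (3.05, 1.6, 1.6),
    ])
    def test_two_ball_matches_closed_forms(self, d, r1, r2):
        """Restriction volumes and cap areas of two overlapping spheres
        agree with the lens/cap closed forms to 1e-6 relative."""
        t = fx.make_two_ball(d, r1, r2).truths
        res = compute_restrictions([SAMBall("a", (0, 0, 0), r1),
                                    SAMBall("b", (d, 0, 0), r2)])
        v1, v2 = t["restriction_volumes"]
        a1, a2 = t["exposed_areas"]
        assert res["a"].volume_bound == pytest.approx(v1, rel=1e-6)
        assert res["b"].volume_bound == pytest.approx(v2, rel=1e-6)
        assert res["a"].exposed_area_bound == pytest.approx(a1, rel=1e-6)
        assert res["b"].exposed_area_bound == pytest.approx(a2, rel=1e-6)
        total = res["a"].volume_bound + res["b"].volume_bound
        assert total == pytest.approx(t["union_volume"], rel=1e-6)

    def test_disjoint_balls_are_isolated(self):
        res = compute_restrictions([SAMBall("a", (0, 0, 0), 1.5),
                                    SAMBall("b", (10, 0, 0), 1.5)])
        for r in res.values():
            assert r.volume_bound == pytest.approx(4 / 3 * math.pi * 1.5 ** 3)
            assert r.neighbors == set()

    def test_neighbor_relation_symmetric(self):
        balls = fx.random_cluster(12, seed=5)
        res = compute_restrictions(balls)
        for aid, r in res.items():
            for b in r.neighbors:
                assert aid in res[b].neighbors

    def test_coincident_centers_resolved_deterministically(self):
        balls = [SAMBall("a", (0, 0, 0), 2.0), SAMBall("b", (0, 0, 0), 2.0)]
        res1 = compute_restrictions(balls)
        res2 = compute_restrictions(list(reversed(balls)))
        for aid in ("a", "b"):
            assert res1[aid].volume_bound == pytest.approx(res2[aid].volume_bound)
        total = res1["a"].volume_bound + res1["b"].volume_bound
        assert total == pytest.approx(4 / 3 * math.pi * 8, rel=1e-6)


class TestUnionVolumeOracle:
    def test_single_ball(self):
        est, se = union_volume_oracle([SAMBall("a", (0, 0, 0), 2.0)],
                                      n_samples=10 ** 6, seed=0)
        assert abs(est - 33.510) <= 3 * se

    def test_two_ball_overlap_matches_closed_form(self):
        t = fx.make_two_ball(2.0, 2.0, 2.0).truths
        est, se = union_volume_oracle([SAMBall("a", (0, 0, 0), 2.0),
                                       SAMBall("b", (2.0, 0, 0), 2.0)],
                                      n_samples=400_000, seed=1)
        assert abs(est - t["union_volume"]) <= 3 * se

    def test_empty_set(self):
        assert union_volume_oracle([]) == (0.0, 0.0)


class TestConservationProperties:
    def test_volume_conservation_on_random_fixtures(self):
        """Sum of restriction volumes equals the Monte-Carlo union volume
        within 3 standard errors, over 20 random clusters."""
        failures = 0
        for seed in range(20):
            balls = fx.random_cluster(10 + seed % 5, seed=seed)
            res = compute_restrictions(balls)
            total = sum(r.volume_bound for r in res.values())
            est, se = union_volume_oracle(balls, n_samples=60_000, seed=seed)
            if abs(total - est) > 3 * se:
                failures += 1
        # 3-SE outliers occur with prob ~0.003 per fixture; none expected,
        # one tolerated across 20 draws
        assert failures <= 1

    def test_exposed_areas_match_surface_sampling_oracle(self):
        """Per-cluster total exposed area within 1% of a Shrake-Rupley
        style point-count oracle."""
        for seed in (3, 11):
            balls = fx.random_cluster(12, seed=seed)
            res = compute_restrictions(balls)
            centers = np.array([b.center for b in balls])
            radii = np.array([b.radius_expanded for b in balls])
            oracle = shrake_rupley_areas(centers, radii, n_points=30_000)
            exact = np.array([res[b.atom_id].exposed_area_bound for b in balls])
            assert exact.sum() == pytest.approx(oracle.sum(), rel=0.01)


class TestInterface:
    def test_symmetric_overlap_single_atoms(self):
        f = fx.make_two_ball(2.0, 2.0, 2.0)
        im = extract_interface(f.structure())
        assert len(im.interface_ig) == len(im.interface_ag) == 1
        assert im.bsa_side("Ig") > 0
        assert im.bsa_side("Ig") == pytest.approx(im.bsa_side("Ag"), rel=1e-9)

    def test_far_partners_give_empty_interface(self):
        f = fx.make_two_ball(30.0, 2.0, 2.0)
        im = extract_interface(f.structure())
        assert im.n_interface == 0
        assert im.direct_pairs == set()

    def test_water_bridge_counts_both_flanks(self):
        """A sandwiched water links the partners with zero direct pairs."""
        f = fx.make_water_bridge()
        im = extract_interface(f.structure())
        assert len(im.direct_pairs) == f.truths["n_direct"]
        waters = {w for _, w in im.water_mediated_pairs}
        assert len(waters) == f.truths["n_interfacial_waters"]
        assert len(im.interface_ig) == 1 and len(im.interface_ag) == 1

    def test_superset_of_atoms_losing_accessibility(self, slab_water):
        """Every partner atom losing exposed area on complexation belongs
        to the Voronoi interface."""
        s, im = slab_water
        interface = im.interface_ig | im.interface_ag
        for a in s.atoms:
            if a.partner == "water":
                continue
            r = im.restrictions[a.atom_id]
            lost = r.exposed_area_unbound - r.exposed_area_bound
            if lost > 1e-6:
                assert a.atom_id in interface, a.atom_id

    def test_bsa_additivity(self, slab):
        s, im = slab
        bsa_ig = sum(im.per_atom_bsa[a] for a in im.interface_ig)
        assert im.bsa_side("Ig") == pytest.approx(bsa_ig, rel=1e-12)
        assert im.bsa_side("Ig") + im.bsa_side("Ag") >= 0
        assert all(v >= 0 for v in im.per_atom_bsa.values())

    def test_rigid_motion_invariance(self):
        """Rotation + translation changes no area, volume, contact or SO."""
        from scipy.spatial.transform import Rotation
        import dataclasses
        f = fx.make_slab_complex()
        s1 = f.structure()
        im1 = extract_interface(s1)
        rot = Rotation.from_euler("zyx", [31.0, -54.0, 117.0], degrees=True)
        shift = np.array([7.3, -2.1, 11.9])
        s2 = f.structure()
        s2.atoms = [dataclasses.replace(
            a, center=tuple(rot.apply(np.array(a.center)) + shift))
            for a in s2.atoms]
        im2 = extract_interface(s2)
        assert im1.direct_pairs == im2.direct_pairs
        assert im1.shelling_order == im2.shelling_order
        for aid in im1.per_atom_bsa:
            assert im2.per_atom_bsa[aid] == pytest.approx(
                im1.per_atom_bsa[aid], rel=1e-6, abs=1e-6)
        for aid, r in im1.restrictions.items():
            assert im2.restrictions[aid].volume_bound == pytest.approx(
                r.volume_bound, rel=1e-6)

    def test_so_lipschitz_across_patch_edges(self, slab):
        """|SO(a)-SO(b)| <= 1 for contact-neighbouring same-partner
        interface atoms."""
        s, im = slab
        partner = {a.atom_id: a.partner for a in s.atoms}
        for aid, so in im.shelling_order.items():
            for b in im.restrictions[aid].neighbors:
                if b in im.shelling_order and partner[b] == partner[aid]:
                    assert abs(so - im.shelling_order[b]) <= 1


class TestShellingOrders:
    @pytest.mark.parametrize("shape, n", [("path", 5), ("disk", 7),
                                          ("two-component", 2)])
    def test_matches_hand_computed_and_brute_force(self, shape, n):
        f = fx.make_patch_fixture(shape, n)
        t = f.truths
        so = shelling_orders(t["patch"], t["graph"], t["boundary"])
        assert so == t["expected_so"]
        assert so == brute_force_shelling(t["patch"], t["graph"], t["boundary"])

    def test_empty_patch(self):
        assert shelling_orders(set(), {}, set()) == {}

    def test_single_atom_patch(self):
        assert shelling_orders({"a"}, {"a": set()}, {"a"}) == {"a": 1}
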