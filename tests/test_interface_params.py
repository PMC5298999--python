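"""Descriptor derivation: BSA averages, IVW-IPL, ANSO, NIS, regions."""

import logging

import numpy as np
import pytest

from igvor import fixtures as fx
from igvor.interface_params import (UndefinedDescriptorError, anso,
                                    bsa_averages, compute_descriptor,
                                    descriptor_table, ivw_ipl, nis_charged)
from igvor.sam_voronoi import (InterfaceModel, RestrictionGeometry,
                               extract_interface)
from igvor.structure_model import AtomRecord, ComplexStructure


def _im(atoms_so_vol, ig=(), ag=(), bsa=None):
    """Hand-built InterfaceModel from {atom: (SO, Vol)} plus side sets."""
    restrictions = {a: RestrictionGeometry(a, volume_bound=v,
                                           exposed_area_bound=5.0)
                    for a, (_, v) in atoms_so_vol.items()}
    return InterfaceModel(
        interface_ig=set(ig), interface_ag=set(ag),
        direct_pairs=set(), water_mediated_pairs=set(),
        per_atom_bsa=bsa or {}, restrictions=restrictions,
        shelling_order={a: so for a, (so, _) in atoms_so_vol.items()})


class TestBsaAverages:
    def test_plain_division(self):
        im = _im({f"i{k}": (1, 10.0) for k in range(50)} | {"g0": (1, 10.0)},
                 ig=[f"i{k}" for k in range(50)], ag=["g0"],
                 bsa={f"i{k}": 10.0 for k in range(50)} | {"g0": 3.0})
        avg_ig, avg_ag = bsa_averages(im)
        assert avg_ig == pytest.approx(10.0)
        assert avg_ag == pytest.approx(3.0)

    def test_symmetric_fixture_equal_sides(self):
        f = fx.make_two_ball(2.0, 2.0, 2.0)
        im = extract_interface(f.structure())
        avg_ig, avg_ag = bsa_averages(im)
        assert avg_ig == pytest.approx(avg_ag, rel=1e-9)

    def test_empty_side_is_undefined_not_zero(self):
        im = _im({"a": (1, 5.0)}, ig=["a"], ag=[])
        with pytest.raises(UndefinedDescriptorError):
            bsa_averages(im)

    def test_small_convex_ligand_buries_more_per_atom(self):
        """A compact convex antigen shows higher bsa̅_Ag and lower bsa̅_Ig
        than an extended flat one against the same antibody patch."""
        small = fx.make_slab_complex(ag_atoms=1, gap=4.0, nx=6)
        flat = fx.make_slab_complex(ag_atoms=5, gap=4.0, nx=6,
                                    ag_layout="plate")
        ig_small, ag_small = bsa_averages(extract_interface(small.structure()))
        ig_flat, ag_flat = bsa_averages(extract_interface(flat.structure()))
        assert ag_small > ag_flat
        assert ig_small < ig_flat


class TestIvwIplAnso:
    EXAMPLE = {"a": (1, 10.0), "b": (1, 20.0), "c": (2, 5.0)}

    def test_hand_arithmetic(self):
        im = _im(self.EXAMPLE, ig=["a", "b", "c"], ag=[])
        assert ivw_ipl(im) == pytest.approx(0.1 + 0.05 + 0.4)

    def test_product_form_flag(self):
        im = _im(self.EXAMPLE, ig=["a", "b", "c"])
        assert ivw_ipl(im, form="product") == pytest.approx(10 + 20 + 10)

    def test_empty_filter_is_zero(self):
        im = _im(self.EXAMPLE, ig=["a", "b", "c"])
        assert ivw_ipl(im, set()) == 0.0

    def test_anso_normalization_and_identity(self):
        im = _im(self.EXAMPLE, ig=["a", "b", "c"])
        A = {"a", "b", "c"}
        assert anso(im, A) == pytest.approx(0.55 / 3)
        assert anso(im, A) * len(A) == pytest.approx(ivw_ipl(im, A))

    def test_uniform_patch_anso_is_inverse_volume(self):
        im = _im({f"u{k}": (1, 8.0) for k in range(7)},
                 ig=[f"u{k}" for k in range(7)])
        assert anso(im, {f"u{k}" for k in range(7)}) == pytest.approx(1 / 8.0)

    def test_empty_set_undefined(self):
        im = _im(self.EXAMPLE, ig=["a"])
        with pytest.raises(UndefinedDescriptorError):
            anso(im, set())

    def test_zero_volume_interface_atom_is_hard_error(self):
        im = _im({"a": (1, 0.0)}, ig=["a"])
        with pytest.raises(ValueError, match="zero restriction volume"):
            ivw_ipl(im)


def _nis_structure(n_res, charged_idx, interface_idx):
    """Structure of single-atom residues + matching InterfaceModel."""
    atoms, so_vol, bsa = [], {}, {}
    for i in range(n_res):
        name = "LYS" if i in charged_idx else "SER"
        aid = f"r{i}"
        atoms.append(AtomRecord(atom_id=aid, element="C", center=(3.0 * i, 0, 0),
                                r_vdw=1.7, residue_name=name, residue_seq=str(i),
                                chain_id="H", partner="Ig",
                                region="constant/outside-V"))
        so_vol[aid] = (1, 10.0)
    s = ComplexStructure(atoms=atoms, heavy_chain_id="H")
    im = _im(so_vol, ig=[f"r{i}" for i in interface_idx])
    return s, im


class TestNisCharged:
    def test_toy_fraction(self):
        s, im = _nis_structure(10, charged_idx={0, 1, 2}, interface_idx=set())
        assert nis_charged(s, im) == pytest.approx(0.3)

    def test_all_interface_is_undefined(self):
        s, im = _nis_structure(4, charged_idx={0}, interface_idx={0, 1, 2, 3})
        with pytest.raises(UndefinedDescriptorError):
            nis_charged(s, im)

    def test_removing_a_surface_lysine_recounts(self):
        s, im = _nis_structure(10, charged_idx={0, 1, 2}, interface_idx=set())
        s2 = ComplexStructure(atoms=[a for a in s.atoms if a.atom_id != "r0"],
                              heavy_chain_id="H")
        assert nis_charged(s2, im) == pytest.approx(2 / 9)


class TestRegionDecomposition:
    def test_partition_additivity(self, slab_water):
        """Region BSAs and IVW-IPLs over Ig regions sum to the Ig-side
        totals to 1e-6 relative."""
        s, im = slab_water
        d = compute_descriptor(s, im)
        ig_regions = [r for r in d.per_region
                      if r.startswith("V") or r == "constant/outside-V"]
        bsa_sum = sum(d.per_region[r].bsa for r in ig_regions)
        assert bsa_sum == pytest.approx(d.bsa_ig, rel=1e-6)
        ivw_sum = sum(d.per_region[r].ivw_ipl for r in ig_regions)
        assert ivw_sum == pytest.approx(ivw_ipl(im, im.interface_ig), rel=1e-6)
        # whole interface = Ig-side + Ag-side contributions
        total = ivw_sum + d.per_region["antigen"].ivw_ipl
        assert total == pytest.approx(d.ivw_ipl, rel=1e-6)

    def test_anso_is_mean_of_so_over_vol_not_ratio_of_means(self, slab):
        s, im = slab
        d = compute_descriptor(s, im)
        rs = d.per_region["VH-CDR3"]
        assert rs.n_atoms > 0
        assert rs.anso == pytest.approx(rs.ivw_ipl / rs.n_atoms, rel=1e-12)
        # the decomposed means are reported but their ratio is NOT the anso
        assert rs.mean_so is not None and rs.mean_vol is not None


class TestDescriptorTable:
    def _pairs(self, n=3):
        out = []
        for gap in np.linspace(3.8, 4.4, n):
            f = fx.make_slab_complex(gap=float(gap))
            s = f.structure()
            s.name = f"slab-{gap:.2f}"
            out.append((s, extract_interface(s)))
        return out

    def test_three_fixtures_three_rows_stable_columns(self):
        df = descriptor_table(self._pairs(3))
        assert len(df) == 3
        for col in ("complex_id", "bsa_avg_ig", "bsa_avg_ag", "ivw_ipl",
                    "nis_charged", "VH_CDR3_bsa", "VH_CDR3_anso"):
            assert col in df.columns
        assert list(df.columns[:9]) == [
            "complex_id", "n_interface_ig", "n_interface_ag", "bsa_ig",
            "bsa_ag", "bsa_avg_ig", "bsa_avg_ag", "ivw_ipl", "nis_charged"]

    def test_failing_complex_logged_not_fatal(self, caplog):
        pairs = self._pairs(2)
        broken = fx.make_two_ball(30.0, 2.0, 2.0)  # empty interface
        s = broken.structure()
        pairs.append((s, extract_interface(s)))
        with caplog.at_level(logging.ERROR):
            df = descriptor_table(pairs)
        assert len(df) == 2
        assert any("descriptor failed" in r.message for r in caplog.records)

    def test_bsa_vs_interface_size_positively_correlated(self):
        """Across fixtures of growing interfaces, BSA tracks |I|."""
        df = descriptor_table(self._pairs(5))
        bsa = df.bsa_ig + df.bsa_ag
        n = df.n_interface_ig + df.n_interface_ag
        if n.nunique() > 1:
            assert np.corrcoef(bsa, n)[0, 1] > 0
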