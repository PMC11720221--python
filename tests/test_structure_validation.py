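"""Structural re-validation tests: slab geometry, numbering, glycans,
orientation, confidence filtering and verdict combination."""

import numpy as np
import pytest

import biotite.structure as struc

from glycotopo.io_annotations import GlycanClass, GlycoSite, SiteStatus
from glycotopo.structure_validation import (
    DEFAULT_BOND_CUTOFF,
    MembraneSlab,
    NumberingMap,
    Orientation,
    SlabClass,
    StructureError,
    StructureModel,
    Verdict,
    build_numbering_map,
    detect_covalent_glycans,
    filter_confident_model,
    map_position,
    read_slab,
    read_structure,
    side_chain_orientation,
    slab_classify,
    verify_site,
    write_structure,
)
from glycotopo.synthetic_data import generate_helix
from glycotopo.topology_mapping import LocationLabel, SiteLocation


def make_site(position, residue="T", accession="P00001"):
    return GlycoSite(
        accession=accession,
        position=position,
        residue=residue,
        glycan_class=GlycanClass.O_GLCNAC if residue in "ST" else GlycanClass.N_LINKED,
        status=SiteStatus.REPORTED,
    )


def single_atom_model(z, atom_name="CA", res_name="THR", res_id=1, chain="A"):
    atoms = struc.array(
        [
            struc.Atom([0.0, 0.0, z], chain_id=chain, res_id=res_id,
                       res_name=res_name, atom_name=atom_name, element="C",
                       hetero=False)
        ]
    )
    return StructureModel(atoms)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestReadStructure:
    def test_generator_truth_counts(self, tmp_path, bundle):
        model, slab, truth = bundle
        path = tmp_path / "bundle.pdb"
        write_structure(model, path)
        parsed = read_structure(path)
        assert len(parsed) == len(model)
        assert set(parsed.chain_ids) == {"A", "X"}
        # 4 helices x 30 residues, 2 atoms each, + 3 NAG x 2 atoms
        assert len(parsed) == 4 * 30 * 2 + 3 * 2
        assert int((parsed.atoms.res_name == "NAG").sum()) == 6

    def test_zero_atom_file_warns(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n", encoding="utf-8")
        with pytest.warns(UserWarning, match="no atoms"):
            model = read_structure(path)
        assert len(model) == 0

    def test_cross_format_identity(self, tmp_path, bundle):
        model, _, _ = bundle
        pdb_path, cif_path = tmp_path / "m.pdb", tmp_path / "m.cif"
        write_structure(model, pdb_path)
        write_structure(model, cif_path)
        from_pdb = read_structure(pdb_path)
        from_cif = read_structure(cif_path)
        # PDB columns carry 3 decimals; identical at that precision
        assert np.allclose(from_pdb.atoms.coord, from_cif.atoms.coord, atol=1e-3)
        assert list(from_pdb.atoms.res_name) == list(from_cif.atoms.res_name)

    def test_unparseable_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.cif"
        path.write_text("this is not a structure\n\x00\x01", encoding="utf-8")
        with pytest.raises(StructureError):
            read_structure(path)

    def test_unknown_extension(self, tmp_path):
        path = tmp_path / "x.xyz"
        path.write_text("", encoding="utf-8")
        with pytest.raises(StructureError, match="infer"):
            read_structure(path)


class TestNumberingMap:
    def test_signal_peptide_shift(self):
        num_map = build_numbering_map(signal_peptide=(1, 18))
        assert map_position(num_map, 206) == 188

    def test_identity(self):
        num_map = build_numbering_map()
        assert map_position(num_map, 42) == 42

    def test_removed_region_is_none(self):
        num_map = build_numbering_map(signal_peptide=(1, 18))
        assert map_position(num_map, 10) is None

    def test_explicit_pairs_override(self):
        num_map = build_numbering_map(pairs=[(100, 77)])
        assert map_position(num_map, 100) == 77
        assert map_position(num_map, 101) == 101

    def test_pairs_must_be_injective(self):
        with pytest.raises(ValueError, match="injective"):
            build_numbering_map(pairs=[(1, 5), (2, 5)])

    def test_constant_offset(self):
        num_map = build_numbering_map(offset=-3)
        assert map_position(num_map, 10) == 7


class TestSlabClassify:
    def test_mid_slab(self):
        model = single_atom_model(0.0)
        assert slab_classify(model, MembraneSlab(), "A", 1) is SlabClass.MEMBRANE

    def test_inclusive_boundary(self):
        model = single_atom_model(15.0)
        assert slab_classify(model, MembraneSlab(), "A", 1) is SlabClass.MEMBRANE

    def test_outside_and_inside(self):
        assert slab_classify(single_atom_model(15.1), MembraneSlab(), "A", 1) is SlabClass.OUTSIDE
        assert slab_classify(single_atom_model(-15.1), MembraneSlab(), "A", 1) is SlabClass.INSIDE

    def test_helix_against_coordinate_enumeration(self):
        # 30-residue ideal helix spans -21.75..21.75 along z
        helix = generate_helix(30)
        model = StructureModel(helix)
        slab = MembraneSlab()
        for res_id in range(1, 31):
            z = float(model.atom_coord("A", res_id, "CA")[2])
            expected = (
                SlabClass.MEMBRANE
                if -15.0 <= z <= 15.0
                else (SlabClass.OUTSIDE if z > 15.0 else SlabClass.INSIDE)
            )
            assert slab_classify(model, slab, "A", res_id) is expected

    def test_monotone_along_normal(self):
        # raising the axial coordinate never moves a label from O toward I
        order = {SlabClass.INSIDE: 0, SlabClass.MEMBRANE: 1, SlabClass.OUTSIDE: 2}
        labels = [
            order[slab_classify(single_atom_model(z), MembraneSlab(), "A", 1)]
            for z in np.linspace(-30, 30, 121)
        ]
        assert labels == sorted(labels)

    def test_missing_atom_raises(self):
        model = single_atom_model(0.0, atom_name="CB")
        with pytest.raises(StructureError, match="CA"):
            slab_classify(model, MembraneSlab(), "A", 1)

    def test_any_atom_policy(self):
        atoms = struc.array(
            [
                struc.Atom([0, 0, 20.0], chain_id="A", res_id=1, res_name="THR",
                           atom_name="CA", element="C", hetero=False),
                struc.Atom([0, 0, 14.0], chain_id="A", res_id=1, res_name="THR",
                           atom_name="OG1", element="O", hetero=False),
            ]
        )
        model = StructureModel(atoms)
        assert slab_classify(model, MembraneSlab(), "A", 1) is SlabClass.OUTSIDE
        assert slab_classify(model, MembraneSlab(), "A", 1, atom_policy="any") is SlabClass.MEMBRANE


class TestDetectCovalentGlycans:
    def test_planted_links_recovered(self, bundle):
        model, _, truth = bundle
        links = detect_covalent_glycans(model)
        got = {(l.glycan_res_id, l.protein_res_id, l.protein_atom) for l in links}
        expected = {
            (d["glycan_res_id"], d["protein_res_id"], d["protein_atom"])
            for d in truth.glycan_links
        }
        assert got == expected
        assert all(abs(l.distance - 1.45) < 1e-3 for l in links)

    def test_no_glycans_empty(self):
        model = StructureModel(generate_helix(10))
        assert detect_covalent_glycans(model) == []

    def test_distant_glycan_not_reported(self):
        atoms = struc.array(
            [
                struc.Atom([0, 0, 0], chain_id="A", res_id=1, res_name="ASN",
                           atom_name="ND2", element="N", hetero=False),
                struc.Atom([3.0, 0, 0], chain_id="X", res_id=900, res_name="NAG",
                           atom_name="C1", element="C", hetero=True),
            ]
        )
        assert detect_covalent_glycans(StructureModel(atoms), bond_cutoff=2.0) == []

    def test_matches_brute_force_all_pairs(self, bundle):
        model, _, _ = bundle
        a = model.atoms
        expected = set()
        from glycotopo.structure_validation import ACCEPTOR_ATOMS, GLYCAN_RESNAMES

        for i in range(a.array_length()):
            if a.res_name[i] not in GLYCAN_RESNAMES or a.atom_name[i] != "C1":
                continue
            best = None
            for j in range(a.array_length()):
                if ACCEPTOR_ATOMS.get(str(a.res_name[j])) != str(a.atom_name[j]):
                    continue
                d = float(np.linalg.norm(a.coord[i] - a.coord[j]))
                if best is None or d < best[0]:
                    best = (d, int(a.res_id[j]))
            if best and best[0] <= DEFAULT_BOND_CUTOFF:
                expected.add((int(a.res_id[i]), best[1]))
        got = {(l.glycan_res_id, l.protein_res_id) for l in detect_covalent_glycans(model)}
        assert got == expected

    def test_nearest_acceptor_only(self):
        atoms = struc.array(
            [
                struc.Atom([0, 0, 0], chain_id="A", res_id=1, res_name="ASN",
                           atom_name="ND2", element="N", hetero=False),
                struc.Atom([1.8, 0, 0], chain_id="A", res_id=2, res_name="SER",
                           atom_name="OG", element="O", hetero=False),
                struc.Atom([1.4, 0, 0], chain_id="X", res_id=900, res_name="NAG",
                           atom_name="C1", element="C", hetero=True),
            ]
        )
        links = detect_covalent_glycans(StructureModel(atoms))
        assert len(links) == 1
        assert links[0].protein_res_id == 2  # nearest wins (0.4 vs 1.4)


class TestSideChainOrientation:
    def test_planted_outward_is_lipid_facing(self, bundle):
        model, slab, truth = bundle
        segs = [tuple(s) for s in truth.tm_segments]
        for key, wanted in truth.orientations.items():
            chain, res_id = key.split(":")
            got = side_chain_orientation(model, slab, segs, chain, int(res_id))
            assert got.value == wanted

    def test_axial_side_chain_is_ambiguous(self):
        # side-chain vector parallel to the membrane normal: no in-plane part
        atoms = []
        for res_id, x in ((1, 8.0), (2, -8.0)):
            atoms.append(struc.Atom([x, 0, 0], chain_id="A", res_id=res_id,
                                    res_name="THR", atom_name="CA", element="C",
                                    hetero=False))
        atoms.append(struc.Atom([8.0, 0, 1.5], chain_id="A", res_id=1,
                                res_name="THR", atom_name="CB", element="C",
                                hetero=False))
        model = StructureModel(struc.array(atoms))
        segs = [("A", 1, 1), ("A", 2, 2)]
        got = side_chain_orientation(model, MembraneSlab(), segs, "A", 1)
        assert got is Orientation.AMBIGUOUS

    def test_glycine_warns_and_is_ambiguous(self, bundle):
        model, slab, truth = bundle
        atoms = model.atoms
        # strip the side chain of residue 20
        keep = ~((atoms.res_id == 20) & (atoms.atom_name != "CA"))
        stripped = StructureModel(atoms[keep])
        segs = [tuple(s) for s in truth.tm_segments]
        with pytest.warns(UserWarning, match="side-chain"):
            got = side_chain_orientation(stripped, slab, segs, "A", 20)
        assert got is Orientation.AMBIGUOUS

    def test_requires_two_segments(self, bundle):
        model, slab, truth = bundle
        with pytest.raises(ValueError, match="2 TM segments"):
            side_chain_orientation(model, slab, [tuple(truth.tm_segments[0])], "A", 10)


class TestFilterConfidentModel:
    def make_model(self, confidences):
        atoms = []
        for i, c in enumerate(confidences, start=1):
            atoms.append(struc.Atom([0, 0, float(i)], chain_id="A", res_id=i,
                                    res_name="ALA", atom_name="CA", element="C",
                                    hetero=False))
        arr = struc.array(atoms)
        arr.set_annotation("b_factor", np.array(confidences, dtype=float))
        return StructureModel(arr)

    def test_all_above(self):
        model = self.make_model([90.0] * 5)
        assert filter_confident_model(model, ("A", 1, 5)) is True

    def test_exactly_70_fails_strict(self):
        model = self.make_model([90.0, 70.0, 90.0])
        assert filter_confident_model(model, ("A", 1, 3)) is False

    def test_planted_dip(self):
        model = self.make_model([95.0, 92.0, 40.0, 91.0])
        assert filter_confident_model(model, ("A", 1, 4)) is False
        assert filter_confident_model(model, ("A", 1, 2)) is True

    def test_region_outside_model(self):
        model = self.make_model([90.0] * 3)
        with pytest.raises(StructureError, match="not present"):
            filter_confident_model(model, ("A", 10, 20))


class TestVerifySite:
    def location(self, site, label):
        dist = {LocationLabel.IN_TM: 0, LocationLabel.INTERFACE: 2}.get(label)
        return SiteLocation(site, label, dist)

    def test_expected_tm_but_outside_slab(self, bundle):
        model, _, truth = bundle
        # shrink the slab so an end-of-helix residue pops outside
        slab = MembraneSlab(lower=-5.0, upper=5.0)
        res_id = 1  # helix end, |z| = 21.75
        site = GlycoSite(accession="SYN", position=res_id, residue="T",
                         glycan_class=GlycanClass.O_GLCNAC, status=SiteStatus.REPORTED)
        # rename for identity match
        model.atoms.res_name[model.atoms.res_id == res_id] = "THR"
        verdict = verify_site(site, self.location(site, LocationLabel.IN_TM), model, slab)
        assert verdict.verdict is Verdict.RELOCATED_EXTRAMEMBRANE

    def test_expected_interface_but_mid_slab(self, bundle):
        model, slab, truth = bundle
        res_id = 15  # helix middle, z ~ 0
        model.atoms.res_name[model.atoms.res_id == res_id] = "ASN"
        site = make_site(res_id, residue="N")
        verdict = verify_site(site, self.location(site, LocationLabel.INTERFACE), model, slab)
        assert verdict.verdict is Verdict.ON_TM_HELIX

    def test_residue_mismatch(self, bundle):
        model, slab, _ = bundle
        site = make_site(20, residue="T")  # structure has LEU at 20
        verdict = verify_site(site, self.location(site, LocationLabel.IN_TM), model, slab)
        assert verdict.verdict is Verdict.RESIDUE_MISMATCH
        assert verdict.glycan_found is False

    def test_unresolved_when_absent(self, bundle):
        model, slab, _ = bundle
        site = make_site(9999)
        verdict = verify_site(site, self.location(site, LocationLabel.IN_TM), model, slab)
        assert verdict.verdict is Verdict.UNRESOLVED

    def test_unresolved_inside_signal_peptide(self, bundle):
        model, slab, _ = bundle
        num_map = build_numbering_map(signal_peptide=(1, 18))
        site = make_site(10)
        verdict = verify_site(site, self.location(site, LocationLabel.IN_TM),
                              model, slab, num_map)
        assert verdict.verdict is Verdict.UNRESOLVED

    def test_confirmed_with_glycan(self, bundle):
        model, slab, truth = bundle
        # residue 5 is a planted ASN glycan acceptor in mid-membrane? z of res 5
        site = GlycoSite(accession="SYN", position=5, residue="N",
                         glycan_class=GlycanClass.N_LINKED, status=SiteStatus.REPORTED)
        verdict = verify_site(site, self.location(site, LocationLabel.IN_TM), model, slab)
        assert verdict.glycan_found is True
        expected_class = truth.slab_classes["A:5"]
        assert verdict.slab_class.value == expected_class

    def test_glycan_absent_audit(self, bundle):
        model, slab, _ = bundle
        model.atoms.res_name[model.atoms.res_id == 22] = "THR"
        model.atoms.atom_name[
            (model.atoms.res_id == 22) & (model.atoms.atom_name == "CB")
        ] = "OG1"
        site = make_site(22, residue="T")
        verdict = verify_site(site, self.location(site, LocationLabel.IN_TM),
                              model, slab, require_glycan=True)
        assert verdict.verdict is Verdict.GLYCAN_ABSENT


class TestRigidMotionInvariance:
    def test_labels_links_orientations_preserved(self, bundle):
        model, slab, truth = bundle
        rng = np.random.default_rng(7)
        segs = [tuple(s) for s in truth.tm_segments]
        for _ in range(3):
            rotation = random_rotation(rng)
            translation = rng.uniform(-50, 50, size=3)
            moved = model.transformed(rotation, translation)
            moved_slab = slab.transformed(rotation, translation)
            for key, expected in truth.slab_classes.items():
                chain, res_id = key.split(":")
                got = slab_classify(moved, moved_slab, chain, int(res_id))
                assert got.value == expected
            got_links = {
                (l.glycan_res_id, l.protein_res_id)
                for l in detect_covalent_glycans(moved)
            }
            assert got_links == {
                (d["glycan_res_id"], d["protein_res_id"]) for d in truth.glycan_links
            }
            for key, wanted in truth.orientations.items():
                chain, res_id = key.split(":")
                got = side_chain_orientation(moved, moved_slab, segs, chain, int(res_id))
                assert got.value == wanted


class TestSlabSidecar:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "slab.yaml"
        path.write_text("normal: [0, 0, 1]\nlower: -12.5\nupper: 13.0\n", encoding="utf-8")
        slab = read_slab(path)
        assert slab.lower == -12.5 and slab.upper == 13.0

    def test_bad_slab_rejected(self):
        with pytest.raises(ValueError):
            MembraneSlab(lower=10.0, upper=-10.0)
        with pytest.raises(ValueError):
            MembraneSlab(normal=(0, 0, 0))
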