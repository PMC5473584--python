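"""Dictionary building, bond attachment, reduction and end-to-end encoding."""

import numpy as np
import pytest

from mmtfkit import codec_registry as reg
from mmtfkit import container
from mmtfkit.encoder_pipeline import (
    FULL,
    REDUCED,
    Atom,
    Chain,
    Group,
    Model,
    RawStructure,
    attach_inter_group_bonds,
    build_group_dictionary,
    classify_group,
    encode_structure,
    reduce_structure,
    to_raw_structure,
)
from mmtfkit.structure_model import decode_structure
from mmtfkit.synthetic import FixtureSpec, make_structure
from tests.conftest import make_peptide


def single_chain(groups):
    return RawStructure(models=[Model(chains=[Chain("A", groups=groups)])])


class TestBuildGroupDictionary:
    def test_identical_residues_collapse(self, templates):
        raw = make_peptide(("ALA",) * 10, templates=templates)
        entries, indices = build_group_dictionary(raw, templates)
        assert len(entries) == 1
        assert indices == [0] * 10

    def test_serine_entry_carries_template_chemistry(self, templates):
        raw = make_peptide(("SER",), templates=templates)
        entries, _ = build_group_dictionary(raw, templates)
        (entry,) = entries
        tmpl = templates["SER"]
        assert entry.atom_names == tmpl.atom_names
        assert entry.elements == tmpl.elements
        assert entry.formal_charges == tmpl.formal_charges
        assert entry.single_letter_code == "S"
        assert entry.chem_comp_type == "L-PEPTIDE LINKING"
        # every template bond appears, expressed as index pairs
        named = {
            frozenset(
                (entry.atom_names[entry.intra_bond_atoms[2 * k]],
                 entry.atom_names[entry.intra_bond_atoms[2 * k + 1]])
            )
            for k in range(entry.bond_count)
        }
        assert named == {frozenset(p) for p in tmpl.bond_pairs}

    def test_atom_order_exception_makes_new_entry(self, templates):
        normal = Group("ALA", 1, [
            Atom("N", "N", 0, 0, 0), Atom("CA", "C", 1, 0, 0),
            Atom("C", "C", 2, 0, 0), Atom("O", "O", 3, 0, 0),
            Atom("CB", "C", 1, 1, 0),
        ])
        scrambled = Group("ALA", 2, [
            Atom("CB", "C", 5, 1, 0), Atom("N", "N", 4, 0, 0),
            Atom("CA", "C", 5, 0, 0), Atom("C", "C", 6, 0, 0),
            Atom("O", "O", 7, 0, 0),
        ])
        entries, indices = build_group_dictionary(single_chain([normal, scrambled]), templates)
        assert len(entries) == 2
        assert indices == [0, 1]

    def test_missing_template_warns_and_leaves_bonds_empty(self):
        group = Group("XYZ", 1, [Atom("C1", "C", 0, 0, 0), Atom("C2", "C", 1, 0, 0)])
        with pytest.warns(UserWarning, match="XYZ"):
            entries, _ = build_group_dictionary(single_chain([group]), {})
        assert entries[0].intra_bond_orders == []

    def test_dictionary_expansion_soundness(self, small_fixture, templates):
        entries, indices = build_group_dictionary(small_fixture, templates)
        for group, idx in zip(small_fixture.iter_groups(), indices):
            entry = entries[idx]
            assert [a.name for a in group.atoms] == entry.atom_names
            assert [a.element for a in group.atoms] == entry.elements
            assert [a.formal_charge for a in group.atoms] == entry.formal_charges


class TestAttachInterGroupBonds:
    def test_backbone_inference_on_peptide(self, peptide3):
        bonds = attach_inter_group_bonds(peptide3)
        assert len(bonds) == 2  # two C-N links for three residues

    def test_explicit_disulfide_kept(self, templates):
        raw = make_peptide(("CYS", "GLY", "CYS"), templates=templates)
        # SG atoms: CYS has 6 atoms (N CA C O CB SG); SG at local index 5
        sg1, sg2 = 5, 6 + 4 + 5  # second CYS offset by CYS+GLY atoms
        raw.inter_bonds.append((sg1, sg2, 1))
        bonds = attach_inter_group_bonds(raw)
        assert (sg1, sg2, 1) in bonds
        assert len(bonds) == 3  # disulfide + 2 backbone links

    def test_duplicate_link_stored_once(self, peptide3):
        raw = peptide3
        raw.inter_bonds = [(0, 5, 1), (5, 0, 1), (0, 5, 1)]
        bonds = attach_inter_group_bonds(raw, infer_backbone=False)
        assert len(bonds) == 1

    def test_dangling_reference_rejected(self, peptide3):
        from mmtfkit.structure_model import IntegrityError

        peptide3.inter_bonds = [(0, 10**6, 1)]
        with pytest.raises(IntegrityError):
            attach_inter_group_bonds(peptide3)

    def test_distance_cap_blocks_chain_breaks(self, templates):
        raw = make_peptide(("GLY", "ALA"), templates=templates)
        # move the second residue far away: no inferred bond
        for atom in raw.models[0].chains[0].groups[1].atoms:
            atom.x += 500.0
        assert attach_inter_group_bonds(raw) == []


class TestReduceStructure:
    def test_peptide_keeps_one_atom_per_residue(self, templates):
        raw = make_peptide(("GLY", "ALA", "SER", "ALA", "GLY"), templates=templates)
        reduced = reduce_structure(raw)
        assert reduced.num_atoms == 5
        for group in reduced.iter_groups():
            assert [a.name for a in group.atoms] == ["CA"]

    def test_nucleotide_and_ligand(self, templates):
        u = templates["U"]
        lig = templates["LIG"]
        nuc = Group("U", 1, [
            Atom(n, e, float(i), 0.0, 0.0)
            for i, (n, e) in enumerate(zip(u.atom_names, u.elements))
        ])
        ligand = Group("LIG", 1, [
            Atom(n, e, float(i), 5.0, 0.0)
            for i, (n, e) in enumerate(zip(lig.atom_names, lig.elements))
        ])
        raw = RawStructure(models=[Model(chains=[
            Chain("A", groups=[nuc]), Chain("B", groups=[ligand])])])
        reduced = reduce_structure(raw)
        atoms = list(reduced.iter_atoms())
        assert len(atoms) == 1 + 12
        assert atoms[0].name == "P"

    def test_waters_removed(self, templates):
        raw = make_structure(FixtureSpec(seed=0, residues_per_chain=2, n_waters=5))
        reduced = reduce_structure(raw)
        assert all(g.name != "HOH" for g in reduced.iter_groups())

    def test_peptide_without_ca_dropped_with_warning(self, templates):
        broken = Group("ALA", 1, [
            Atom("N", "N", 0, 0, 0), Atom("C", "C", 1, 0, 0),
            Atom("CA", "C", 2, 0, 0), Atom("O", "O", 3, 0, 0),
        ])
        del broken.atoms[2]  # no CA left, still classified other-wise
        # need N, CA, C for peptide classification; craft group with CA missing
        # but classified as peptide via name-independent atom check is not
        # possible, so use a nucleotide lacking P instead for the same rule
        nuc = Group("U", 1, [Atom("C1'", "C", 0, 0, 0), Atom("O3'", "O", 1, 0, 0)])
        assert classify_group(nuc) == "nucleotide"
        with pytest.warns(UserWarning, match="no P atom"):
            reduced = reduce_structure(single_chain([nuc]))
        assert reduced.num_atoms == 0

    @pytest.mark.parametrize("seed", [0, 3])
    def test_idempotence(self, seed, templates):
        raw = make_structure(FixtureSpec(seed=seed, n_models=2, residues_per_chain=3,
                                         n_ligands=1, n_waters=2))
        once = reduce_structure(raw)
        twice = reduce_structure(once)
        assert [a.name for a in twice.iter_atoms()] == [a.name for a in once.iter_atoms()]
        assert [(a.x, a.y, a.z) for a in twice.iter_atoms()] == [
            (a.x, a.y, a.z) for a in once.iter_atoms()
        ]
        assert twice.inter_bonds == once.inter_bonds

    def test_reduced_never_larger(self, small_fixture):
        assert reduce_structure(small_fixture).num_atoms <= small_fixture.num_atoms


class TestEncodeStructure:
    def test_constant_occupancy_single_pair(self, templates):
        raw = make_structure(FixtureSpec(seed=4, residues_per_chain=10,
                                         occupancy_pattern="constant"))
        doc = encode_structure(raw, templates=templates)
        _, column = reg.unpack_record(doc.occupancies)
        assert column.tolist() == [100, raw.num_atoms]

    def test_full_profile_grid_coordinates_exact(self, small_fixture, templates):
        doc = encode_structure(small_fixture, FULL, templates)
        s = decode_structure(doc)
        originals = np.array([(a.x, a.y, a.z) for a in small_fixture.iter_atoms()])
        decoded = np.column_stack([s.x, s.y, s.z])
        assert np.array_equal(originals, decoded)
        b_orig = np.array([a.b_factor for a in small_fixture.iter_atoms()])
        assert np.array_equal(b_orig, s.b_factors)

    def test_reduced_profile_half_quantum_bound(self, small_fixture, templates):
        doc = encode_structure(small_fixture, REDUCED, templates)
        s = decode_structure(doc)
        reduced = reduce_structure(small_fixture)
        originals = np.array([(a.x, a.y, a.z) for a in reduced.iter_atoms()])
        decoded = np.column_stack([s.x, s.y, s.z])
        # half of the 0.1 A quantum, plus float representation noise
        assert np.max(np.abs(originals - decoded)) <= 0.05 + 1e-9

    def test_document_always_validates(self, templates):
        for seed in range(4):
            raw = make_structure(FixtureSpec(seed=seed, n_models=seed % 2 + 1,
                                             residues_per_chain=3, n_ligands=seed % 2))
            for profile in (FULL, REDUCED):
                doc = encode_structure(raw, profile, templates)
                assert container.validate(doc) == []

    def test_coordinate_overflow_raises(self, templates):
        from mmtfkit.codec_core import RangeError

        raw = single_chain([Group("HOH", 1, [Atom("O", "O", 3.0e6, 0, 0)])])
        with pytest.raises(RangeError):
            encode_structure(raw, FULL, templates)

    def test_round_trip_through_raw(self, small_fixture, templates):
        from mmtfkit.container import deserialize, serialize

        doc = encode_structure(small_fixture, templates=templates)
        s = decode_structure(deserialize(serialize(doc)))
        rebuilt = to_raw_structure(s)
        doc2 = encode_structure(rebuilt, templates=templates)
        assert serialize(doc2) == serialize(doc)

    def test_sequence_indices_polymer_only(self, templates):
        raw = make_structure(FixtureSpec(seed=2, residues_per_chain=3, n_ligands=1))
        doc = encode_structure(raw, templates=templates)
        s = decode_structure(doc)
        polymer = s.sequence_indices[:3]
        assert polymer.tolist() == [0, 1, 2]
        assert s.sequence_indices[3] == -1  # ligand group
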