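"""Hierarchy semantics, combining, caching, and serialization."""

import xml.etree.ElementTree as ET

import pytest

from torsionforge.chem import perceive, torsion_type_groups
from torsionforge.energy import TorsionTerm
from torsionforge.errors import CoverageError, InputError
from torsionforge.forcefield import (
    GENERIC_TORSION_SMIRKS,
    ForceField,
    ParameterCache,
    TorsionParameterRecord,
    add_bespoke,
    assign_torsions,
    combine,
    default_base_forcefield,
    read_ff,
    write_ff,
)
from torsionforge.fragment import fragment_molecule
from torsionforge.smirks import generate_smirks


def _bespoke_record(smirks, k=1.0, rec_id="t-b1"):
    return TorsionParameterRecord(
        smirks=smirks,
        terms=(TorsionTerm(k, 3, 0.0),),
        id=rec_id,
        source="bespoke",
    )


@pytest.fixture(scope="module")
def biphenyl_pattern(biphenyl):
    frag, _ = fragment_molecule(biphenyl)[0]
    (group,) = torsion_type_groups(frag.molecule, frag.target_bond)
    return generate_smirks(biphenyl, frag, group).smarts


class TestRecordValidation:
    def test_duplicate_periodicities_rejected(self):
        with pytest.raises(InputError):
            TorsionParameterRecord(
                smirks=GENERIC_TORSION_SMIRKS,
                terms=(TorsionTerm(1.0, 2, 0.0), TorsionTerm(0.5, 2, 0.0)),
                id="bad",
            )

    def test_smirks_must_have_four_maps(self):
        with pytest.raises(InputError):
            TorsionParameterRecord(smirks="[*:1]~[*:2]", terms=(), id="bad")


class TestAssignment:
    def test_generic_covers_everything(self, aspirin):
        ff = default_base_forcefield()
        assignment = assign_torsions(ff, aspirin)
        assert assignment
        assert all(r.id == "t-generic" for r in assignment.values())

    def test_bespoke_wins_over_generic(self, biphenyl, biphenyl_pattern):
        ff = add_bespoke(default_base_forcefield(), [_bespoke_record(biphenyl_pattern)])
        assignment = assign_torsions(ff, biphenyl)
        central = [r for q, r in assignment.items()
                   if set(q.central_bond) == set((5, 6))]
        assert central and all(r.id == "t-b1" for r in central)
        # all other quartets still take the generic record
        others = [r for q, r in assignment.items() if set(q.central_bond) != {5, 6}]
        assert others and all(r.id == "t-generic" for r in others)

    def test_bespoke_specificity_no_cross_chemistry_match(self, biphenyl_pattern):
        pyridine_biaryl = perceive("c1ccncc1-c1ccccc1")
        ff = add_bespoke(default_base_forcefield(), [_bespoke_record(biphenyl_pattern)])
        assignment = assign_torsions(ff, pyridine_biaryl)
        assert all(r.id == "t-generic" for r in assignment.values())

    def test_unmatched_quartet_raises_coverage_error(self, biphenyl, biphenyl_pattern):
        only_bespoke = ForceField(torsions=[_bespoke_record(biphenyl_pattern)])
        with pytest.raises(CoverageError):
            assign_torsions(only_bespoke, perceive("CCO"))


class TestHierarchyEditing:
    def test_bespoke_appended_at_bottom(self, biphenyl_pattern):
        ff = add_bespoke(default_base_forcefield(), [_bespoke_record(biphenyl_pattern)])
        assert ff.torsions[-1].source == "bespoke"
        assert ff.torsions[0].source == "base"

    def test_base_after_bespoke_rejected(self, biphenyl_pattern):
        with pytest.raises(InputError, match="bottom"):
            ForceField(
                torsions=[
                    _bespoke_record(biphenyl_pattern),
                    default_base_forcefield().torsions[0],
                ]
            )

    def test_combine_idempotent(self, biphenyl_pattern):
        ff = add_bespoke(default_base_forcefield(), [_bespoke_record(biphenyl_pattern)])
        assert len(combine([ff, ff]).torsions) == len(ff.torsions)

    def test_combine_associative_on_disjoint_records(self, biphenyl_pattern):
        base = default_base_forcefield()
        ff1 = add_bespoke(base, [_bespoke_record(biphenyl_pattern, k=1.0, rec_id="a")])
        other = "[#6:1]-[#6:2]-[#8:3]-[#1:4]"
        ff2 = add_bespoke(base, [_bespoke_record(other, k=2.0, rec_id="b")])
        left = combine([combine([ff1, ff2]), base])
        right = combine([ff1, combine([ff2, base])])
        assert [(r.smirks, r.terms) for r in left.torsions] == [
            (r.smirks, r.terms) for r in right.torsions
        ]

    def test_shared_core_records_appear_once(self, biphenyl_pattern):
        base = default_base_forcefield()
        core = _bespoke_record(biphenyl_pattern, k=1.5, rec_id="core")
        ffs = [add_bespoke(base, [core]) for _ in range(16)]
        merged = combine(ffs)
        assert sum(1 for r in merged.torsions if r.smirks == biphenyl_pattern) == 1

    def test_conflicting_terms_same_smirks_error(self, biphenyl_pattern):
        base = default_base_forcefield()
        ff1 = add_bespoke(base, [_bespoke_record(biphenyl_pattern, k=1.0)])
        ff2 = add_bespoke(base, [_bespoke_record(biphenyl_pattern, k=2.0)])
        with pytest.raises(InputError, match="conflict"):
            combine([ff1, ff2])

    def test_different_base_rejected(self, biphenyl_pattern):
        ff1 = default_base_forcefield()
        ff2 = default_base_forcefield()
        ff2.name = "other-base"
        with pytest.raises(InputError):
            combine([ff1, ff2])


class TestParameterCache:
    def test_store_then_lookup_hit(self):
        mol = perceive("CCCC")
        cache = ParameterCache()
        terms = (TorsionTerm(1.1, 3, 0.0),)
        cache.store(mol, (0, 1, 2, 3), terms)
        assert cache.lookup(mol, (0, 1, 2, 3)) == terms

    def test_renumbered_isomorph_hits(self):
        """Same graph, different atom numbering -> same canonical key."""
        from rdkit import Chem

        from torsionforge.chem import Molecule

        mol = perceive("CCCO")
        perm = list(range(mol.n_atoms))[::-1]
        renumbered = Molecule(Chem.RenumberAtoms(mol.rdmol, perm))
        inv = {old: new for new, old in enumerate(perm)}
        quartet = (0, 1, 2, 3)
        mapped_quartet = tuple(inv[a] for a in quartet)
        cache = ParameterCache()
        terms = (TorsionTerm(0.9, 2, 180.0),)
        cache.store(mol, quartet, terms)
        assert cache.lookup(renumbered, mapped_quartet) == terms

    def test_different_driven_bond_misses(self):
        # butan-1-ol: the C-C-C-C and C-C-C-O torsions are inequivalent
        mol = perceive("CCCCO")
        cache = ParameterCache()
        cache.store(mol, (0, 1, 2, 3), (TorsionTerm(1.0, 3, 0.0),))
        assert cache.lookup(mol, (1, 2, 3, 4)) is None

    def test_symmetry_equivalent_bond_hits(self):
        # pentane: the two C-C-C-C torsions map onto each other under the
        # molecule's mirror automorphism, so reuse is correct
        mol = perceive("CCCCC")
        cache = ParameterCache()
        terms = (TorsionTerm(1.0, 3, 0.0),)
        cache.store(mol, (0, 1, 2, 3), terms)
        assert cache.lookup(mol, (1, 2, 3, 4)) == terms


class TestSerialization:
    def test_json_round_trip(self, tmp_path, biphenyl_pattern):
        ff = add_bespoke(default_base_forcefield(), [_bespoke_record(biphenyl_pattern)])
        path = str(tmp_path / "ff.json")
        write_ff(ff, path)
        back = read_ff(path)
        assert back.name == ff.name
        assert [(r.smirks, r.terms, r.source) for r in back.torsions] == [
            (r.smirks, r.terms, r.source) for r in ff.torsions
        ]

    def test_minimal_handwritten_fixture_parses(self, tmp_path):
        path = tmp_path / "mini.json"
        path.write_text(
            '{"name": "mini", "torsions": [{"id": "t1", '
            '"smirks": "[*:1]~[*:2]~[*:3]~[*:4]", '
            '"terms": [{"k": 0.0, "n": 3, "phase": 0.0}]}]}'
        )
        ff = read_ff(str(path))
        assert len(ff.torsions) == 1

    def test_out_of_order_file_rejected(self, tmp_path, biphenyl_pattern):
        path = tmp_path / "bad.json"
        path.write_text(
            '{"name": "bad", "torsions": ['
            f'{{"id": "b", "smirks": "{biphenyl_pattern}", "source": "bespoke",'
            ' "terms": [{"k": 1.0, "n": 3, "phase": 0.0}]},'
            ' {"id": "g", "smirks": "[*:1]~[*:2]~[*:3]~[*:4]", "source": "base",'
            ' "terms": [{"k": 0.0, "n": 3, "phase": 0.0}]}]}'
        )
        with pytest.raises(InputError, match="bad.json"):
            read_ff(str(path))

    def test_schema_violation_names_offending_node(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text('{"name": "x", "torsions": [{"id": "t1"}]}')
        with pytest.raises(InputError, match="torsions\\[0\\]"):
            read_ff(str(path))

    def test_xml_export_offxml_layout(self, tmp_path, biphenyl_pattern):
        ff = add_bespoke(default_base_forcefield(), [_bespoke_record(biphenyl_pattern)])
        path = str(tmp_path / "ff.offxml")
        write_ff(ff, path)
        root = ET.parse(path).getroot()
        propers = root.find("ProperTorsions")
        assert propers is not None
        entries = list(propers)
        assert len(entries) == len(ff.torsions)
        assert entries[-1].get("smirks") == biphenyl_pattern
        assert "kilocalorie" in entries[-1].get("k1")
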