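import pytest

from specplot import (
    Atom,
    Bond,
    DegenerateGeometryError,
    Molecule,
    MolfileDialectError,
    ParseError,
    depict,
    format_molfile,
    parse_molfile,
)
from specplot.fixtures import BENZENE, ETHANOL, URACIL, make_molfiles


def _counts(fragment):
    return len(fragment.findall("line")), len(fragment.findall("text"))


class TestParse:
    def test_counts_line_fixed_columns(self, molfile_corpus):
        mol = parse_molfile(molfile_corpus["benzene"])
        assert len(mol.atoms) == 6 and len(mol.bonds) == 6

    def test_single_atom_no_bonds(self, molfile_corpus):
        mol = parse_molfile(molfile_corpus["methane"])
        assert len(mol.atoms) == 1 and mol.bonds == ()

    def test_ethanol_elements_and_bonds(self, molfile_corpus):
        mol = parse_molfile(molfile_corpus["ethanol"])
        assert [a.element for a in mol.atoms] == ["C", "C", "O"]
        assert [(b.a1, b.a2, b.order) for b in mol.bonds] == [(1, 2, 1), (2, 3, 1)]

    def test_agrees_with_rdkit_on_valid_corpus(self, molfile_corpus):
        Chem = pytest.importorskip("rdkit.Chem")
        for stem in ("ethanol", "benzene", "uracil", "methane"):
            ours = parse_molfile(molfile_corpus[stem])
            ref = Chem.MolFromMolBlock(molfile_corpus[stem], sanitize=False)
            assert ref is not None, stem
            assert len(ours.atoms) == ref.GetNumAtoms()
            assert len(ours.bonds) == ref.GetNumBonds()
            assert [a.element for a in ours.atoms] == [
                at.GetSymbol() for at in ref.GetAtoms()
            ]

    @pytest.mark.parametrize(
        "stem,err",
        [
            ("corrupt-truncated", ParseError),
            ("corrupt-badcounts", ParseError),
            ("corrupt-v3000", MolfileDialectError),
        ],
    )
    def test_corrupted_variants_raise_documented_errors(self, molfile_corpus, stem, err):
        with pytest.raises(err):
            parse_molfile(molfile_corpus[stem])

    def test_bond_index_out_of_range(self, molfile_corpus):
        bad = molfile_corpus["ethanol"].replace("  2  3  1", "  2  9  1")
        with pytest.raises(ParseError, match="out of range"):
            parse_molfile(bad)

    def test_missing_m_end(self, molfile_corpus):
        with pytest.raises(ParseError, match="M  END"):
            parse_molfile(molfile_corpus["ethanol"].replace("M  END", ""))

    def test_charges_from_chg_property_line(self):
        mol = Molecule((Atom("N", 0.0, 0.0, 1), Atom("O", 1.0, 0.0, -1)), (Bond(1, 2, 1),))
        parsed = parse_molfile(format_molfile(mol))
        assert [a.charge for a in parsed.atoms] == [1, -1]

    def test_writer_parser_roundtrip(self):
        for mol in (ETHANOL, BENZENE, URACIL):
            again = parse_molfile(format_molfile(mol))
            assert again.atoms == mol.atoms
            assert again.bonds == mol.bonds


class TestDepict:
    def test_two_carbons_single_bond(self):
        mol = Molecule((Atom("C", 0.0, 0.0), Atom("C", 1.0, 0.0)), (Bond(1, 2, 1),))
        lines, texts = _counts(depict(mol, 100))
        assert (lines, texts) == (1, 0)

    def test_benzene_line_count_is_sum_of_bond_orders(self):
        lines, texts = _counts(depict(BENZENE, 200))
        assert lines == 9  # 3 single + 2*3 double
        assert texts == 0

    def test_carbon_oxygen_bond_has_one_label(self):
        mol = Molecule((Atom("C", 0.0, 0.0), Atom("O", 1.0, 0.0)), (Bond(1, 2, 1),))
        lines, texts = _counts(depict(mol, 100))
        assert (lines, texts) == (1, 1)

    def test_label_count_equals_heteroatoms_plus_charged(self):
        mol = Molecule(
            (Atom("C", 0.0, 0.0, 1), Atom("C", 1.0, 0.0), Atom("N", 0.5, 1.0)),
            (Bond(1, 2, 1), Bond(2, 3, 1)),
        )
        frag = depict(mol, 150)
        texts = frag.findall("text")
        assert len(texts) == 2  # charged carbon + nitrogen
        assert {t.text for t in texts} == {"C+", "N"}

    def test_aromatic_code_draws_solid_plus_dashed(self):
        mol = Molecule((Atom("C", 0.0, 0.0), Atom("C", 1.0, 0.0)), (Bond(1, 2, 4),))
        frag = depict(mol, 100)
        lines = frag.findall("line")
        assert len(lines) == 2
        assert sum(1 for ln in lines if ln.get("stroke-dasharray")) == 1

    @pytest.mark.parametrize("dx,dy,scale", [(10.0, -3.5, 1.0), (0.0, 0.0, 2.0), (7.25, 4.0, 0.25)])
    def test_invariant_under_translation_and_uniform_scaling(self, dx, dy, scale):
        import xml.etree.ElementTree as ET

        moved = Molecule(
            tuple(Atom(a.element, a.x * scale + dx, a.y * scale + dy, a.charge)
                  for a in URACIL.atoms),
            URACIL.bonds,
        )
        a = ET.tostring(depict(URACIL, 200))
        b = ET.tostring(depict(moved, 200))
        assert a == b

    def test_degenerate_geometry_rejected(self):
        mol = Molecule((Atom("C", 1.0, 1.0), Atom("C", 1.0, 1.0)), (Bond(1, 2, 1),))
        with pytest.raises(DegenerateGeometryError):
            depict(mol, 100)
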