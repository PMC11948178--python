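import csv

import pytest

from adcbiotx.chem import (
    DEFAULT_BIOTRANSFORMATIONS,
    HYDROLYSIS,
    AttachmentError,
    MALEIMIDE_SMARTS,
    StructureParseError,
    enumerate_cleavages,
    expand_library,
    export_library,
    parse_smiles,
    parse_structure,
    read_library,
)
from adcbiotx.masses import format_formula, formula_mass
from adcbiotx.simulate import make_toy_linker_payload
from adcbiotx.structures import synthetic_pbd_linker_payload


class TestParseStructure:
    def test_ethanol_acyclic(self, ethanol_molblock):
        g = parse_structure(ethanol_molblock, 0)
        assert len(g.atoms) == 3
        assert sum(b[3] for b in g.bonds) == 0  # no ring bonds

    def test_benzene_all_ring_bonds(self, benzene_molblock):
        g = parse_structure(benzene_molblock, 0)
        assert len(g.bonds) == 6
        assert all(b[3] for b in g.bonds)

    def test_maleimide_attachment_pattern_matches_one_atom(
        self, nmethylmaleimide_molblock
    ):
        g = parse_structure(nmethylmaleimide_molblock, MALEIMIDE_SMARTS)
        symbol, _h, _q = g.atoms[g.attachment_atom]
        assert symbol == "C"

    def test_malformed_mol_block_names_the_line(self):
        with pytest.raises(StructureParseError, match="line 4"):
            parse_structure("name\n\n\nnot-a-counts-line\n", 0)

    def test_disconnected_structure_rejected(self):
        with pytest.raises(StructureParseError, match="disconnected"):
            parse_smiles("CC.CC", 0)

    def test_ambiguous_attachment_pattern_rejected(self, ethanol_molblock):
        with pytest.raises(AttachmentError, match="matched 2"):
            parse_structure(ethanol_molblock, "[C:1]")

    def test_out_of_range_attachment_index_rejected(self, ethanol_molblock):
        with pytest.raises(AttachmentError):
            parse_structure(ethanol_molblock, 99)


class TestEnumerateCleavages:
    def test_linear_chain_has_no_valid_two_cuts(self, butane_graph):
        products = enumerate_cleavages(butane_graph, max_bonds=2)
        assert len(products) == 3
        assert all(p.n_broken == 1 for p in products)
        formulas = sorted(format_formula(p.retained_formula) for p in products)
        assert formulas == ["C2H6", "C3H8", "CH4"]

    def test_star_yields_one_cuts_and_two_cuts(self, neopentane_star_graph):
        products = enumerate_cleavages(neopentane_star_graph, max_bonds=2)
        assert len(products) == 6
        assert sum(p.n_broken == 1 for p in products) == 3
        assert sum(p.n_broken == 2 for p in products) == 3

    def test_pure_ring_has_no_cleavages(self, benzene_molblock):
        g = parse_structure(benzene_molblock, 0)
        assert enumerate_cleavages(g) == []

    def test_monotone_in_max_bonds(self):
        g = synthetic_pbd_linker_payload()
        one = {p.broken_bonds for p in enumerate_cleavages(g, max_bonds=1)}
        two = {p.broken_bonds for p in enumerate_cleavages(g, max_bonds=2)}
        assert one <= two

    def test_ring_safety_on_polycyclic_structure(self):
        g = synthetic_pbd_linker_payload()
        ring_bonds = {k for k, b in enumerate(g.bonds) if b[3]}
        for p in enumerate_cleavages(g, max_bonds=2):
            assert not (p.broken_bonds & ring_bonds)
            assert g.attachment_atom in p.retained_atoms

    def test_mass_closure(self):
        g = synthetic_pbd_linker_payload()
        parent = formula_mass(g.formula, "monoisotopic")
        h = formula_mass("H", "monoisotopic")
        for p in enumerate_cleavages(g, max_bonds=2):
            retained = formula_mass(p.retained_formula, "monoisotopic")
            lost = formula_mass(p.loss_formula, "monoisotopic")
            assert retained + lost - p.n_broken * h == pytest.approx(parent, abs=1e-6)

    def test_matches_bruteforce_on_toy_structures(self, bruteforce_oracle):
        for seed in range(30):
            mol = make_toy_linker_payload(3 + seed % 10, seed)
            g = parse_structure(mol, 0)
            ours = sorted(
                tuple(sorted(p.retained_formula.items()))
                for p in enumerate_cleavages(g, max_bonds=2)
            )
            assert ours == bruteforce_oracle(g, 2), f"seed {seed}"

    def test_duplicate_formula_flagging(self):
        # symmetric molecule: both terminal cuts retain the same formula
        g = parse_smiles("CC(C)C", 1)  # attachment at the branch centre
        products = enumerate_cleavages(g, max_bonds=1)
        dup = [p for p in products if format_formula(p.retained_formula) == "C3H8"]
        assert len(dup) >= 2
        assert all(p.duplicate_formula for p in dup)


class TestExpandLibrary:
    def test_cardinality_law(self):
        g = parse_smiles("N" + "CN" * 23, 0)  # 47-atom chain -> 46 cleavages
        cleavages = enumerate_cleavages(g, max_bonds=2)
        assert len(cleavages) == 46
        library = expand_library(g, cleavages)
        assert len(library) == 4 * 46 + 3 == 187

    def test_parent_only_expansion(self):
        g = parse_smiles("NCCO", 0)
        library = expand_library(g, [])
        assert len(library) == 3
        assert {e.name for e in library} == {
            "hydrolysis",
            "deamidation",
            "hydrolysis+deamidation",
        }

    def test_single_cleavage_expansion(self):
        g = parse_smiles("NCCCO", 0)
        cleavages = enumerate_cleavages(g, max_bonds=1)[:1]
        library = expand_library(g, cleavages)
        assert len(library) == 4 * 1 + 3

    def test_hydrolysis_entry_delta(self):
        g = parse_smiles("NCCO", 0)
        library = expand_library(g, [])
        hyd = next(e for e in library if e.name == "hydrolysis")
        parent_mono = formula_mass(g.formula, "monoisotopic")
        assert hyd.neutral_mono_mass - parent_mono == pytest.approx(18.0106, abs=1e-4)

    def test_nonphysical_entries_skipped(self, caplog):
        # nitrogen-free parent: deamidation (-N) cannot apply anywhere
        g = parse_smiles("CCCO", 0)
        library = expand_library(g, [])
        assert {e.name for e in library} == {"hydrolysis"}

    def test_names_unique_after_disambiguation(self):
        g = parse_smiles("CC(C)C", 1)
        library = expand_library(g, enumerate_cleavages(g, max_bonds=2))
        names = [e.name for e in library]
        assert len(names) == len(set(names))


class TestLibraryIO:
    def test_round_trip(self, tmp_path):
        g = synthetic_pbd_linker_payload()
        library = expand_library(g, enumerate_cleavages(g, max_bonds=1))
        path = export_library(library, tmp_path / "lib.csv")
        back = read_library(path)
        assert len(back) == len(library)
        for orig, re in zip(library, back):
            assert re.name == orig.name
            assert re.neutral_mono_mass == pytest.approx(orig.neutral_mono_mass, abs=1e-6)
            assert re.neutral_avg_mass == pytest.approx(orig.neutral_avg_mass, abs=1e-6)
            assert re.delta_formula == orig.delta_formula

    def test_row_count_matches_entries(self, tmp_path):
        g = parse_smiles("N" + "CN" * 23, 0)
        library = expand_library(g, enumerate_cleavages(g, max_bonds=2))
        path = export_library(library, tmp_path / "lib.csv")
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        assert len(rows) == 187 + 1  # header + entries

    def test_empty_library_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_library([], tmp_path / "lib.csv")


def test_default_biotransformation_deltas_consistent():
    for mod in DEFAULT_BIOTRANSFORMATIONS:
        assert mod.mono_delta == pytest.approx(
            formula_mass(mod.formula_delta, "monoisotopic"), abs=1e-9
        )
    assert HYDROLYSIS.mono_delta == pytest.approx(18.010565, abs=1e-5)
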