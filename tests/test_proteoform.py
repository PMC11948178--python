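import itertools

import pytest

from adcbiotx.masses import formula_mass
from adcbiotx.proteoform import (
    CandidateConfig,
    CombinatorialBoundError,
    ProteinChain,
    apply_fixed_mods,
    chain_mass,
    enumerate_candidates,
    export_candidates,
    format_label,
    glycan_mass,
    parse_label,
    read_candidates,
    read_chains_fasta,
)
from adcbiotx.simulate import hydrolysis_entry


def chain(seq, ds=0, sites=0, cid="LC"):
    return ProteinChain(cid, seq, n_intrachain_disulfides=ds, n_conjugation_sites=sites)


class TestChainMass:
    @pytest.mark.parametrize(
        "seq, ds, expected",
        [
            ("G", 0, 75.03203),
            ("GG", 0, 132.05349),
            ("CC", 1, 222.01329),  # 2 x 103.00919 (Cys residue) + water - H2
        ],
    )
    def test_monoisotopic(self, seq, ds, expected):
        assert chain_mass(chain(seq, ds)) == pytest.approx(expected, abs=1e-4)

    def test_invalid_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            chain("GGXG")


class TestFixedMods:
    def test_both_rules_stack(self):
        assert apply_fixed_mods(chain("QSVK")) == pytest.approx(-145.12151, abs=1e-4)

    def test_neither_rule_fires(self):
        assert apply_fixed_mods(chain("ASV")) == 0.0

    def test_pyroglu_only(self):
        assert apply_fixed_mods(chain("QSV")) == pytest.approx(-17.026549, abs=1e-5)

    def test_rules_are_switchable(self):
        assert apply_fixed_mods(chain("QSVK"), c_term_lysine_loss=False) == pytest.approx(
            -17.026549, abs=1e-5
        )
        assert apply_fixed_mods(chain("QSVK"), pyroglutamate=False) == pytest.approx(
            -128.09496, abs=1e-4
        )


class TestGlycans:
    def test_g0f_mass(self):
        assert glycan_mass("G0F") == pytest.approx(1444.5339, abs=1e-3)

    def test_none_is_zero(self):
        assert glycan_mass("none") == 0.0

    def test_g1f_adds_one_hexose_over_g0f(self):
        assert glycan_mass("G1F") - glycan_mass("G0F") == pytest.approx(
            162.05282, abs=1e-4
        )

    def test_unknown_glycan_rejected(self):
        with pytest.raises(ValueError, match="unknown glycan"):
            glycan_mass("G9")


CONJ = (1427.6748, 1428.598)  # synthetic PBD-class linker-payload mass pair


class TestEnumerateCandidates:
    def test_lc_single_site_hydrolysis_library(self):
        lc = chain("QSVK", sites=1)
        cands = enumerate_candidates(
            lc, CONJ, [hydrolysis_entry(CONJ)], CandidateConfig(dar_range=(0, 1))
        )
        assert {c.label for c in cands} == {"LC", "LC + 1Cys", "LC + 1PL", "LC + 1PL + 1H2O"}

    def test_bare_chain_only(self):
        lc = chain("QSVK", sites=0)
        cands = enumerate_candidates(
            lc, CONJ, [], CandidateConfig(dar_range=(0,), allow_cysteinylation=False)
        )
        assert len(cands) == 1
        assert cands[0].label == "LC"

    def test_hc_dar3_hydrolysis_ladder(self):
        hc = chain("ASV", sites=3, cid="HC")
        cands = enumerate_candidates(
            hc,
            CONJ,
            [hydrolysis_entry(CONJ)],
            CandidateConfig(dar_range=(3,), glycans=("G0F",), allow_cysteinylation=False),
        )
        labels = {c.label for c in cands}
        assert labels == {
            "HC + 3PL + G0F",
            "HC + 3PL + 1H2O + G0F",
            "HC + 3PL + 2H2O + G0F",
            "HC + 3PL + 3H2O + G0F",
        }

    @pytest.mark.parametrize("sites", [1, 2, 3, 4])
    @pytest.mark.parametrize("n_glycans", [1, 2])
    def test_count_law_vs_bruteforce(self, sites, n_glycans):
        # hydrolysis-only library: sum over dar of (caps options)*(dar+1)*glycans
        expected = sum(
            (sites - d + 1) * (d + 1) * n_glycans for d in range(sites + 1)
        )
        hc = chain("ASV", sites=sites, cid="HC")
        glycans = ("none", "G0F")[:n_glycans]
        cands = enumerate_candidates(
            hc,
            CONJ,
            [hydrolysis_entry(CONJ)],
            CandidateConfig(dar_range=tuple(range(sites + 1)), glycans=glycans),
        )
        assert len(cands) == expected

    def test_additivity_of_candidate_masses(self):
        hc = chain("QAVCK", ds=1, sites=3, cid="HC")
        cands = enumerate_candidates(
            hc,
            CONJ,
            [hydrolysis_entry(CONJ)],
            CandidateConfig(dar_range=(0, 1, 2, 3), glycans=("none", "G0F")),
        )
        base = chain_mass(hc) + apply_fixed_mods(hc)
        cys = formula_mass("C3H5NO2S")
        water = formula_mass("H2O")
        for c in cands:
            n_h2o = sum(1 for m in c.conjugate_mods if m == "hydrolysis")
            expected = (
                base
                + c.dar * CONJ[0]
                + n_h2o * water
                + c.caps * cys
                + glycan_mass(c.glycan)
            )
            assert c.theo_mono_mass == pytest.approx(expected, abs=1e-6), c.label

    def test_avg_mass_exceeds_mono(self):
        hc = chain("ACDEFGHIK", ds=1, sites=2, cid="HC")
        for c in enumerate_candidates(hc, CONJ, [], CandidateConfig(dar_range=(0, 1, 2))):
            assert c.theo_avg_mass > c.theo_mono_mass

    def test_sorted_and_deduplicated(self):
        hc = chain("ASV", sites=2, cid="HC")
        cands = enumerate_candidates(hc, CONJ, [hydrolysis_entry(CONJ)])
        masses = [c.theo_avg_mass for c in cands]
        assert masses == sorted(masses)
        labels = [c.label for c in cands]
        assert len(labels) == len(set(labels))

    def test_combinatorial_bound(self):
        hc = chain("ASV", sites=3, cid="HC")
        big_library = [hydrolysis_entry((m, m)) for m in range(1000, 1200)]
        with pytest.raises(CombinatorialBoundError, match="restrict"):
            enumerate_candidates(
                hc, CONJ, big_library, CandidateConfig(max_candidates=100)
            )


class TestLabels:
    def test_label_round_trip(self):
        hc = chain("ASV", sites=3, cid="HC")
        cands = enumerate_candidates(
            hc,
            CONJ,
            [hydrolysis_entry(CONJ)],
            CandidateConfig(dar_range=(0, 1, 2, 3), glycans=("none", "G0F")),
        )
        for c in cands:
            parsed = parse_label(c.label)
            assert parsed["chain_id"] == "HC"
            assert parsed["dar"] == c.dar
            assert parsed["caps"] == c.caps
            assert parsed["glycan"] == c.glycan
            assert tuple(parsed["mods"]) == c.conjugate_mods

    def test_table_style_label(self):
        label = format_label("HC", 2, "G0F", 1, ["hydrolysis"])
        assert label == "HC + 2PL + 1Cys + 1H2O + G0F"


class TestIO:
    def test_fasta_defaults_and_overrides(self, tmp_path):
        fasta = tmp_path / "chains.fasta"
        fasta.write_text(
            ">LC\nQSVLTQPPSVK\n>HC sites=3 disulfides=4\nQVQLVQSGAEVK\n"
        )
        lc, hc = read_chains_fasta(fasta)
        assert (lc.n_intrachain_disulfides, lc.n_conjugation_sites) == (2, 1)
        assert (hc.n_intrachain_disulfides, hc.n_conjugation_sites) == (4, 3)

    def test_candidates_csv_round_trip(self, tmp_path):
        hc = chain("ASVK", sites=2, cid="HC")
        cands = enumerate_candidates(hc, CONJ, [hydrolysis_entry(CONJ)])
        path = export_candidates(cands, tmp_path / "cands.csv")
        back = read_candidates(path)
        assert [c.label for c in back] == [c.label for c in cands]
        for orig, re in zip(cands, back):
            assert re.theo_avg_mass == pytest.approx(orig.theo_avg_mass, abs=1e-6)
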