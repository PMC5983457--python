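import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepthalf import (
    ALPHABET,
    amino_acid_composition,
    atom_composition,
    binary_profile,
    dipeptide_composition,
    extreme_group_comparison,
    feature_halflife_correlations,
    peptide_molecular_formula,
    peptide_to_smiles,
    physicochemical_properties,
    smiles_element_counts,
    terminal_fragment,
)
from pepthalf.encoders import EncodingError, FeatureVector, SmilesParseError

from conftest import make_dataset

sequences = st.text(alphabet=ALPHABET, min_size=1, max_size=50)


class TestCompositions:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAAA", {"AAC_A": 100.0}),
            ("ACDE", {"AAC_A": 25.0, "AAC_C": 25.0, "AAC_D": 25.0, "AAC_E": 25.0}),
            ("AAC", {"AAC_A": pytest.approx(200 / 3), "AAC_C": pytest.approx(100 / 3)}),
        ],
    )
    def test_aac_values(self, seq, expected):
        fv = amino_acid_composition(seq)
        assert len(fv) == 20
        for name, value in expected.items():
            assert fv[name] == value

    def test_aac_rejects_nonstandard_with_position(self):
        with pytest.raises(EncodingError, match="'X'.*position 3"):
            amino_acid_composition("ACXDE")

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAAA", {"DPC_AA": 100.0}),
            ("ACAC", {"DPC_AC": pytest.approx(200 / 3), "DPC_CA": pytest.approx(100 / 3)}),
        ],
    )
    def test_dpc_values(self, seq, expected):
        fv = dipeptide_composition(seq)
        assert len(fv) == 400
        for name, value in expected.items():
            assert fv[name] == value

    def test_dpc_needs_length_2(self):
        with pytest.raises(EncodingError):
            dipeptide_composition("A")

    @settings(derandomize=True, max_examples=100)
    @given(sequences)
    def test_composition_vectors_sum_to_100(self, seq):
        assert amino_acid_composition(seq).values.sum() == pytest.approx(100, abs=1e-9)
        if len(seq) >= 2:
            assert dipeptide_composition(seq).values.sum() == pytest.approx(100, abs=1e-9)
        assert atom_composition(
            peptide_molecular_formula(seq)
        ).values.sum() == pytest.approx(100, abs=1e-9)


class TestTerminalEncodings:
    @pytest.mark.parametrize(
        "seq,end,expected",
        [("ACDEFGH", "N", "ACDEF"), ("ACDEFGH", "C", "DEFGH"),
         ("ACDEF", "N", "ACDEF"), ("ACDEF", "C", "ACDEF")],
    )
    def test_terminal_fragment(self, seq, end, expected):
        assert terminal_fragment(seq, end, 5) == expected

    def test_fragment_too_short(self):
        with pytest.raises(EncodingError):
            terminal_fragment("ACD", "N", 5)

    def test_binary_profile_layout(self):
        fv = binary_profile("AC", 2)
        assert len(fv) == 40
        assert fv["P1_A"] == 1.0 and fv["P2_C"] == 1.0
        assert fv.values.sum() == 2

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet=ALPHABET, min_size=5, max_size=5))
    def test_binary_profile_one_hot_property(self, frag):
        fv = binary_profile(frag, 5)
        assert len(fv) == 100 and fv.values.sum() == 5
        assert set(np.unique(fv.values)) <= {0.0, 1.0}

    def test_binary_profile_wrong_length(self):
        with pytest.raises(EncodingError):
            binary_profile("ACD", 5)


class TestFormulas:
    @pytest.mark.parametrize(
        "seq,formula",
        [("G", "C2H5NO2"), ("GG", "C4H8N2O3"), ("GGG", "C6H11N3O4")],
    )
    def test_peptide_formula(self, seq, formula):
        counts = peptide_molecular_formula(seq)
        import re

        expected = {m[0]: int(m[1] or 1)
                    for m in re.findall(r"([A-Z][a-z]?)(\d*)", formula)}
        assert dict(counts.counts) == expected

    def test_atom_composition_counts_and_fractions(self):
        f = peptide_molecular_formula("GG")
        counts = atom_composition(f, mode="count")
        assert [counts[n] for n in
                ("ATC_C", "ATC_H", "ATC_O", "ATC_N", "ATC_S")] == [4, 8, 3, 2, 0]
        frac = atom_composition(f, mode="fraction")
        assert frac["ATC_C"] == pytest.approx(100 * 4 / 17, abs=1e-3)
        assert frac["ATC_H"] == pytest.approx(100 * 8 / 17, abs=1e-3)

    @pytest.mark.parametrize(
        "smiles,formula",
        [
            ("C(C(=O)O)N", {"C": 2, "H": 5, "N": 1, "O": 2}),  # glycine
            ("ClCCl", {"C": 1, "H": 2, "Cl": 2}),
            ("[NH3+]CC(=O)[O-]", {"C": 2, "H": 5, "N": 1, "O": 2}),
            ("c1ccccc1", {"C": 6, "H": 6}),  # benzene, aromatic valences
            ("Cc1c[nH]cn1", {"C": 4, "H": 6, "N": 2}),  # 4-methylimidazole
        ],
    )
    def test_smiles_element_counts(self, smiles, formula):
        assert dict(smiles_element_counts(smiles).counts) == formula

    @pytest.mark.parametrize("bad", ["", "C(", "C1CC", "[Q]", "C$C"])
    def test_smiles_parse_errors(self, bad):
        with pytest.raises(SmilesParseError):
            smiles_element_counts(bad)

    @settings(derandomize=True, max_examples=60)
    @given(st.text(alphabet=ALPHABET, min_size=1, max_size=6))
    def test_formula_and_smiles_paths_agree(self, seq):
        """Residue-formula arithmetic is the oracle for the SMILES route."""
        via_formula = peptide_molecular_formula(seq)
        via_smiles = smiles_element_counts(peptide_to_smiles(seq))
        assert dict(via_formula.counts) == dict(via_smiles.counts)

    @pytest.mark.parametrize("seq", ["GW", "PPH", "MCRY", "ACDEF"])
    def test_rdkit_agrees_on_generated_smiles(self, seq):
        """Independent cross-check of the hand tokenizer against RDKit."""
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem
        from rdkit.Chem.rdMolDescriptors import CalcMolFormula
        import re

        mol = Chem.MolFromSmiles(peptide_to_smiles(seq))
        assert mol is not None
        ref = {m[0]: int(m[1] or 1)
               for m in re.findall(r"([A-Z][a-z]?)(\d*)", CalcMolFormula(mol))}
        assert dict(smiles_element_counts(peptide_to_smiles(seq)).counts) == ref


class TestPhysicochemical:
    def test_charge_and_percents(self):
        fv = physicochemical_properties("EEEEE")
        assert fv["net_charge"] == -5 and fv["negative_percent"] == 100.0
        assert physicochemical_properties("FFFFF")["aromatic_percent"] == 100.0

    def test_molecular_weight_polyglycine(self):
        fv = physicochemical_properties("GGGGG")
        assert fv["molecular_weight"] == pytest.approx(5 * 57.02146 + 18.01056, abs=1e-3)
        assert fv["net_charge"] == 0.0

    def test_histidine_partial_charge(self):
        assert physicochemical_properties("HHHHH")["net_charge"] == pytest.approx(0.5)


class TestDatasetAnalyses:
    def test_exact_linear_feature_has_r_one(self):
        # y equals Ala composition by construction
        rows = [("a", "AAAAG", 2.0 ** 8), ("b", "AAGGG", 2.0 ** 4),
                ("c", "AGGGG", 2.0 ** 2), ("d", "AAAGG", 2.0 ** 6)]
        ds = make_dataset(rows)
        table = feature_halflife_correlations(ds, "aac")
        r_ala = table.set_index("feature").loc["AAC_A", "r"]
        assert r_ala == pytest.approx(1.0)

    def test_constant_feature_flagged_undefined(self, tiny_ds):
        table = feature_halflife_correlations(tiny_ds, "aac")
        # Arg never occurs in the fixture, so its column is constant zero
        row = table.set_index("feature").loc["AAC_R"]
        assert row["undefined"] and np.isnan(row["r"])

    def test_too_few_records(self):
        ds = make_dataset([("a", "ACDEF", 100.0), ("b", "GGGGG", 200.0)])
        with pytest.raises(ValueError):
            feature_halflife_correlations(ds, "aac")

    def test_extreme_groups_k1(self):
        ds = make_dataset([("long", "AAAAA", 7200.0), ("short", "FFFFF", 30.0)])
        out = extreme_group_comparison(ds, k=1)
        assert out["long_aac"]["AAC_A"] == 100.0
        assert out["short_aac"]["AAC_F"] == 100.0
        assert out["aac_difference"]["AAC_A"] == 100.0

    def test_groups_disjoint_even_with_ties(self):
        ds = make_dataset([(f"p{i}", "ACDEF", 100.0) for i in range(6)])
        out = extreme_group_comparison(ds, k=3)
        assert out["long_aac"].sum() == pytest.approx(100)

    def test_requires_2k_records(self, tiny_ds):
        with pytest.raises(ValueError):
            extreme_group_comparison(tiny_ds, k=3)

    def test_planted_signal_recovered(self, simulated_ds):
        """Stabilizing residues correlate positively, aromatic negatively."""
        table = feature_halflife_correlations(simulated_ds, "aac").set_index("feature")
        assert table.loc["AAC_A", "r"] > 0 and table.loc["AAC_E", "r"] > 0
        assert table.loc["AAC_F", "r"] < 0 and table.loc["AAC_Y", "r"] < 0
        groups = extreme_group_comparison(simulated_ds, k=20)
        assert groups["aac_difference"]["AAC_E"] > 0
        assert groups["aac_difference"]["AAC_F"] < 0


class TestFeatureVector:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(("a", "a"), np.array([1.0, 2.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(("a",), np.array([1.0, 2.0]))
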