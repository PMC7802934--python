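"""The ten mutation features and their providers."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldstab import (
    ConservationTable,
    FEATURE_NAMES,
    PssmProfile,
    build_feature_vector,
    burial_composition,
    delta_omh,
    make_synthetic_pssm,
    make_toy_structure,
    mutate_structure_naive,
    parse_pdb,
    pssm_feature,
    read_psiblast_pssm,
    sasa_profile,
    window_counts,
)
from foldstab.datasets import MutationRecord
from foldstab.errors import (
    AminoAcidError,
    ConsistencyError,
    FormatError,
    MissingFeatureError,
    ResidueNotFoundError,
)
from foldstab.tables import AMINO_ACIDS, CHARGED, HYDROPHOBIC, MAX_ASA, OMH, PSSM_ALPHABET


class TestPssmParsing:
    def test_roundtrip_of_generated_profile(self):
        text = make_synthetic_pssm("ACDEFGH", conservation_strength=3, seed=5)
        profile = read_psiblast_pssm(text)
        assert profile.sequence == "ACDEFGH"
        assert profile.scores.shape == (7, 20)
        assert read_psiblast_pssm(text).scores.tolist() == profile.scores.tolist()

    def test_both_dialects_parse_to_identical_score_block(self):
        full = read_psiblast_pssm(make_synthetic_pssm("MKVLT", 5, seed=2, dialect="full"))
        short = read_psiblast_pssm(make_synthetic_pssm("MKVLT", 5, seed=2, dialect="short"))
        assert np.array_equal(full.scores, short.scores)
        assert full.sequence == short.sequence

    def test_empty_input_is_a_format_error(self):
        with pytest.raises(FormatError):
            read_psiblast_pssm("")

    def test_truncated_row_is_a_format_error(self):
        text = make_synthetic_pssm("MKV", 0, seed=1, dialect="short")
        lines = text.splitlines()
        lines[-1] = "    3 V    1   2   3"
        with pytest.raises(FormatError):
            read_psiblast_pssm("\n".join(lines))


def _profile(seq, scores=None):
    """Profile with explicit {(pos, aa): score} entries, zero elsewhere."""
    mat = np.zeros((len(seq), 20))
    for (pos, aa), v in (scores or {}).items():
        mat[pos - 1, PSSM_ALPHABET.index(aa)] = v
    return PssmProfile(sequence=seq, scores=mat)


class TestPssmFeature:
    def test_difference_convention_by_direct_lookup(self):
        p = _profile("LAK", {(2, "A"): 5, (2, "W"): -3})
        assert pssm_feature(p, 2, "A", "W") == -8.0

    def test_equal_scores_give_zero(self):
        p = _profile("LAK", {(2, "A"): 4, (2, "W"): 4})
        assert pssm_feature(p, 2, "A", "W") == 0.0

    def test_self_substitution_is_zero(self):
        p = _profile("LAK", {(2, "A"): 7})
        assert pssm_feature(p, 2, "A", "A") == 0.0

    def test_wild_type_mismatch_raises(self):
        p = _profile("LAK")
        with pytest.raises(ConsistencyError):
            pssm_feature(p, 2, "K", "W")

    def test_expect_override_for_reverse_direction(self):
        p = _profile("LAK", {(2, "A"): 5, (2, "W"): -3})
        # reverse record: wt=W, mut=A, profile still shows the original A
        assert pssm_feature(p, 2, "W", "A", expect="A") == 8.0

    def test_single_score_conventions(self):
        p = _profile("LAK", {(2, "A"): 5, (2, "W"): -3})
        assert pssm_feature(p, 2, "A", "W", convention="wt") == 5.0
        assert pssm_feature(p, 2, "A", "W", convention="mut") == -3.0


class TestDeltaOmh:
    def test_antisymmetric_over_all_400_ordered_pairs(self):
        for a, b in itertools.product(AMINO_ACIDS, repeat=2):
            assert delta_omh(a, b) + delta_omh(b, a) == 0.0

    def test_matches_bundled_table(self):
        assert delta_omh("A", "V") == pytest.approx(OMH["V"] - OMH["A"])
        assert delta_omh("A", "V") == pytest.approx(1.31)

    def test_unknown_residue(self):
        with pytest.raises(AminoAcidError):
            delta_omh("A", "Z")


class TestWindowCounts:
    def test_poly_alanine_has_no_hits(self):
        assert window_counts("A" * 30, 15) == (0, 0)

    def test_saturated_hydrophobic_window(self):
        assert window_counts("L" * 30, 15) == (23, 0)

    def test_truncated_window_matches_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=40))
        pos = 5
        window = seq[max(0, pos - 12): pos + 11]
        expected = (
            sum(c in HYDROPHOBIC for c in window),
            sum(c in CHARGED for c in window),
        )
        assert window_counts(seq, pos) == expected

    def test_out_of_range_position(self):
        with pytest.raises(IndexError):
            window_counts("ACD", 4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60), st.data())
    def test_counts_bounded_by_window_size(self, seq, data):
        pos = data.draw(st.integers(1, len(seq)))
        n_h, n_c = window_counts(seq, pos)
        assert 0 <= n_h + n_c <= 23  # hydrophobic and charged sets are disjoint
        assert n_h + n_c <= len(seq)


class TestBurialComposition:
    def test_counts_match_brute_force_on_toy_profile(self, helix20, helix20_sasa):
        comp = burial_composition(helix20, helix20_sasa)
        buried = {
            k for k, loc in zip(helix20_sasa.keys, helix20_sasa.locations) if loc == "COR"
        }
        residues = list(helix20.residues())
        assert comp.n_all == 20
        assert comp.n_l == sum(1 for r in residues if r.aa == "L" and r.key in buried)
        assert comp.n_fwy == sum(1 for r in residues if r.aa in "FWY" and r.key in buried)
        assert comp.n_rkde == sum(1 for r in residues if r.aa in "RKDE" and r.key in buried)
        assert comp.n_fwy + comp.n_rkde + comp.n_l <= comp.n_all

    def test_two_buried_leucines_give_p_l_one_tenth(self, helix20, helix20_sasa):
        import dataclasses

        profile = dataclasses.replace(helix20_sasa)
        leu_idx = [i for i, aa in enumerate(profile.aas) if aa == "L"][:2]
        assert len(leu_idx) == 2
        profile.locations = ["COR" if i in leu_idx else "SUR" for i in range(len(profile))]
        comp = burial_composition(helix20, profile)
        assert comp.p_l == pytest.approx(0.1)
        assert comp.n_l == 2

    def test_nothing_buried_gives_zero_fractions(self, helix20, helix20_sasa):
        import dataclasses

        profile = dataclasses.replace(helix20_sasa)
        profile.locations = ["SUR"] * len(profile)
        comp = burial_composition(helix20, profile)
        assert (comp.p_fwy, comp.p_rkde, comp.p_l) == (0.0, 0.0, 0.0)


@pytest.fixture(scope="module")
def structure():
    return parse_pdb(make_toy_structure(sequence="GKLWADEFHI", seed=2))


class TestNaiveMutator:
    def test_side_chain_truncated_beyond_cbeta(self, structure):
        mutated = mutate_structure_naive(structure, "A", 3, wt="L", mut="A")
        res = mutated.get_residue("A", 3)
        assert res.aa == "A"
        assert sorted(a.name for a in res.atoms) == ["C", "CA", "CB", "N", "O"]

    def test_glycine_target_loses_cbeta(self, structure):
        res = mutate_structure_naive(structure, "A", 4, wt="W", mut="G").get_residue("A", 4)
        assert sorted(a.name for a in res.atoms) == ["C", "CA", "N", "O"]

    def test_other_residues_untouched(self, structure):
        mutated = mutate_structure_naive(structure, "A", 3, wt="L", mut="A")
        for num in (1, 2, 4, 5):
            before = structure.get_residue("A", num)
            after = mutated.get_residue("A", num)
            assert [a.name for a in before.atoms] == [a.name for a in after.atoms]
            assert all(
                np.array_equal(x.coords, y.coords)
                for x, y in zip(before.atoms, after.atoms)
            )

    def test_self_mutation_changes_nothing(self, structure):
        same = mutate_structure_naive(structure, "A", 3, wt="L", mut="L")
        assert [a.name for a in same.get_residue("A", 3).atoms] == [
            a.name for a in structure.get_residue("A", 3).atoms
        ]

    def test_wild_type_mismatch(self, structure):
        with pytest.raises(ConsistencyError):
            mutate_structure_naive(structure, "A", 3, wt="K", mut="A")

    def test_absent_residue(self, structure):
        with pytest.raises(ResidueNotFoundError):
            mutate_structure_naive(structure, "A", 99, wt="L", mut="A")


@pytest.fixture(scope="module")
def context():
    seq = "LKVADELFWYRICHMNQSTGAVILMKRDEW"
    structure = parse_pdb(make_toy_structure(sequence=seq, seed=9), id="P1")
    sasa = sasa_profile(structure)
    pssm = read_psiblast_pssm(make_synthetic_pssm(seq, 5, seed=9))
    cons = ConservationTable()
    cons.set("P1", 5, "D", "W", -2.5)
    cons.set("P1", 5, "W", "D", 2.5)
    return structure, sasa, pssm, cons


class TestFeatureVector:
    def test_composition_equals_memberwise_operations(self, context):
        structure, sasa, pssm, cons = context
        rec = MutationRecord(protein_id="P1", chain="A", position=5, wt="D", mut="W")
        fv = build_feature_vector(rec, structure, sasa, pssm, cons)
        assert fv.pssm == pssm_feature(pssm, 5, "D", "W")
        assert fv.delta_cs == -2.5
        assert fv.delta_omh == delta_omh("D", "W")
        assert fv.sasa_pro == pytest.approx(sasa.for_residue("A", 5)[0])
        assert fv.sasa_sol == MAX_ASA["D"]
        comp = burial_composition(structure, sasa)
        assert (fv.p_fwy, fv.p_rkde, fv.p_l) == (comp.p_fwy, comp.p_rkde, comp.p_l)
        assert (fv.n_hydro, fv.n_charg) == window_counts(structure.sequence(), 5)
        assert len(fv.to_array()) == len(FEATURE_NAMES) == 10

    def test_missing_providers_are_named(self, context):
        structure, sasa, pssm, cons = context
        rec = MutationRecord(protein_id="P1", chain="A", position=6, wt="E", mut="Q")
        with pytest.raises(MissingFeatureError) as err:
            build_feature_vector(rec, structure, sasa, pssm, cons)
        assert err.value.provider == "conservation"
        with pytest.raises(MissingFeatureError) as err:
            build_feature_vector(rec, structure, sasa, None, cons)
        assert err.value.provider == "pssm"

    def test_reverse_features_mirror_forward_for_symmetric_terms(self, context):
        structure, sasa, pssm, cons = context
        fwd = MutationRecord(protein_id="P1", chain="A", position=5, wt="D", mut="W")
        fv_f = build_feature_vector(fwd, structure, sasa, pssm, cons)
        mutant = mutate_structure_naive(structure, "A", 5, wt="D", mut="W")
        rev = MutationRecord(
            protein_id="P1", chain="A", position=5, wt="W", mut="D", direction="reverse"
        )
        fv_r = build_feature_vector(rev, mutant, sasa_profile(mutant), pssm, cons)
        assert fv_r.delta_omh == -fv_f.delta_omh
        assert fv_r.pssm == -fv_f.pssm
        assert fv_r.delta_cs == -fv_f.delta_cs

    def test_structure_record_disagreement_raises(self, context):
        structure, sasa, pssm, cons = context
        rec = MutationRecord(protein_id="P1", chain="A", position=5, wt="K", mut="W")
        with pytest.raises(ConsistencyError):
            build_feature_vector(rec, structure, sasa, pssm, cons)
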