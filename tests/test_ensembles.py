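"""Ensemble I/O, selection language, subdomain map, ion arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import efsam as E
from efsam import synth
from efsam.ensembles import (
    EmptyInputError,
    IonComposition,
    SelectionError,
    TopologyMismatchError,
    load_subdomain_map,
)


class TestPDBRoundTrip:
    def test_single_model_identity(self, tmp_path):
        ens = synth.make_helix(3)
        path = tmp_path / "h.pdb"
        E.write_ensemble(ens, path)
        back = E.parse_ensemble(path)
        assert back.n_models == 1
        assert back.residue_ids().tolist() == [1, 2, 3]
        assert [a.atom_name for a in back.atoms] == [a.atom_name for a in ens.atoms]

    def test_multi_model_round_trip_to_written_precision(self, tmp_path, toy_reference):
        rng = np.random.default_rng(0)
        coords = np.round(
            toy_reference.coords[0] + rng.normal(0, 0.5, (20,) + toy_reference.coords[0].shape),
            3,
        )
        ens = E.Ensemble(toy_reference.atoms, coords)
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        E.write_ensemble(ens, p1)
        back = E.parse_ensemble(p1)
        assert back.n_models == 20
        assert np.max(np.abs(back.coords - ens.coords)) < 5e-4
        # a second trip is bit-stable
        E.write_ensemble(back, p2)
        again = E.parse_ensemble(p2)
        assert np.array_equal(again.coords, back.coords)
        assert [a.residue_number for a in again.atoms] == [
            a.residue_number for a in ens.atoms
        ]

    def test_negative_tag_numbering_preserved(self, tmp_path):
        atoms = [E.Atom("CA", "C", "GLY", r) for r in range(-5, 3)]
        ens = E.Ensemble(atoms, np.arange(24, dtype=float).reshape(1, 8, 3))
        path = tmp_path / "tag.pdb"
        E.write_ensemble(ens, path)
        assert E.parse_ensemble(path).residue_ids().tolist() == list(range(-5, 3))

    def test_mismatched_models_raise(self, tmp_path):
        text = (
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        path = tmp_path / "bad.pdb"
        path.write_text(text)
        with pytest.raises(TopologyMismatchError):
            E.parse_ensemble(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(EmptyInputError):
            E.parse_ensemble(path)

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.70  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "alt.pdb"
        path.write_text(text)
        ens = E.parse_ensemble(path)
        assert ens.n_atoms == 1
        assert ens.coords[0, 0, 0] == pytest.approx(5.0)


class TestSelection:
    def test_binding_loop_ca_count(self, toy_reference):
        idx = E.select(toy_reference, "segment binding_loop and name CA",
                       E.default_subdomain_map())
        # Leu74-Ser88 inclusive = 15 C-alpha atoms
        assert idx.size == 15
        assert sorted(set(toy_reference.residue_numbers[idx])) == list(range(74, 89))

    def test_single_atom_selection(self, toy_reference):
        idx = E.select(toy_reference, "resnum 108 and name CZ")
        assert idx.size == 1
        assert toy_reference.atoms[idx[0]].residue_name == "PHE"

    def test_unknown_segment_names_available(self, toy_reference):
        with pytest.raises(SelectionError, match="binding_loop"):
            E.select(toy_reference, "segment nonsense", E.default_subdomain_map())

    def test_or_and_parentheses(self, toy_reference):
        a = E.select(toy_reference, "(resnum 76 or resnum 87) and name CA")
        assert a.size == 2

    def test_empty_selection_allowed(self, toy_reference):
        assert E.select(toy_reference, "resnum 500").size == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        lo=st.integers(min_value=60, max_value=200),
        hi=st.integers(min_value=60, max_value=200),
    )
    def test_union_is_monotone_and_idempotent(self, lo, hi):
        ens = synth.build_toy_protein()
        lo, hi = min(lo, hi), max(lo, hi)
        a = set(E.select(ens, f"resnum {lo} to {hi}"))
        b = set(E.select(ens, "name CA"))
        union = set(E.select(ens, f"resnum {lo} to {hi} or name CA"))
        assert union == a | b
        twice = set(E.select(ens, f"resnum {lo} to {hi} or resnum {lo} to {hi}"))
        assert twice == a


class TestSubdomainMap:
    def test_construct_length_is_150(self):
        assert E.default_subdomain_map().construct_length() == 150

    def test_delta1_spans_16_residues(self):
        m = E.default_subdomain_map()
        assert m.residues("delta1").size == 16

    def test_bad_delta1_rejected(self):
        with pytest.raises(ValueError, match="delta1"):
            E.SubdomainMap(segments={"delta1": [(73, 80)]})

    def test_interval_outside_construct_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            E.SubdomainMap(segments={"x": [(250, 260)]})

    def test_yaml_override(self, tmp_path):
        cfg = tmp_path / "map.yaml"
        cfg.write_text("segments:\n  alpha3: [[99, 107]]\n")
        m = load_subdomain_map(cfg)
        assert m.segments["alpha3"] == [(99, 107)]
        assert m.segments["alpha1"] == [(64, 73)]  # defaults retained


class TestIonArithmetic:
    def test_physiological_box_gives_31_pairs(self):
        assert E.salt_pairs_for_box(0.150, 7.0) == 31

    def test_zero_concentration(self):
        assert E.salt_pairs_for_box(0.0, 7.0) == 0

    def test_half_box(self):
        # 0.150 * 42.875e-24 * 6.022e23 = 3.87 -> rounds to 4
        assert E.salt_pairs_for_box(0.150, 3.5) == 4

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError):
            E.salt_pairs_for_box(-0.1, 7.0)
        with pytest.raises(ValueError):
            E.salt_pairs_for_box(0.1, 0.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        c=st.floats(min_value=0, max_value=1),
        d=st.floats(min_value=0.01, max_value=0.5),
        e=st.floats(min_value=1, max_value=12),
        f=st.floats(min_value=0.01, max_value=5),
    )
    def test_pair_count_monotone_in_both_arguments(self, c, d, e, f):
        assert E.salt_pairs_for_box(c + d, e) >= E.salt_pairs_for_box(c, e)
        assert E.salt_pairs_for_box(c, e + f) >= E.salt_pairs_for_box(c, e)

    def test_calcium_removal_drops_two_anions(self):
        holo = IonComposition(41, 31)
        apo = E.rebalance_anions(holo, -2)
        assert (apo.n_cation, apo.n_anion) == (41, 29)

    def test_identity_change(self):
        holo = IonComposition(41, 31)
        assert E.rebalance_anions(holo, 0) == holo

    def test_positive_charge_change_adds_anion(self):
        assert E.rebalance_anions(IonComposition(41, 31), +1).n_anion == 32

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        ncat=st.integers(min_value=0, max_value=100),
        q=st.integers(min_value=-20, max_value=20),
        dq=st.integers(min_value=-5, max_value=5),
    )
    def test_rebalance_preserves_electroneutrality_exactly(self, ncat, q, dq):
        nan = ncat + q
        if nan < 0 or nan + dq < 0:
            return
        out = E.rebalance_anions(
            IonComposition(ncat, nan, solute_formal_charge=nan - ncat), dq
        )
        assert out.n_cation - out.n_anion + out.solute_formal_charge == 0

    def test_negative_anion_count_raises(self):
        with pytest.raises(ValueError):
            E.rebalance_anions(IonComposition(2, 1), -5)
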