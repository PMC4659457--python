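"""The three-point distance-criterion search for Lys/Hyl-Arg pairs."""

import numpy as np
import pytest

from conftest import brute_force_pairs
from glycolink.errors import MissingAtomError
from glycolink.sites import (
    PairDistances,
    eligible_pair,
    find_candidate_sites,
    pair_distances,
    sites_to_frame,
)
from glycolink.structure import AtomRecord, CollagenMolecule, Residue
from glycolink.synthetic import (
    HelixSpec,
    PlantDirective,
    build_helix,
    random_helix,
)


def make_residue(chain, idx, name, atoms, helical=None):
    return Residue(
        chain_label=chain,
        uniprot_index=idx,
        residue_name=name,
        atoms=[AtomRecord(n, e, p) for n, e, p in atoms],
        helical_index=helical if helical is not None else idx,
    )


class TestEligibility:
    def test_arg_lys_across_chains(self):
        arg = make_residue("A1B", 257, "ARG", [])
        lys = make_residue("A2", 183, "LYS", [])
        assert eligible_pair(arg, lys)
        assert eligible_pair(lys, arg)

    def test_two_lysines_not_eligible(self):
        a = make_residue("A1A", 10, "LYS", [])
        b = make_residue("A2", 20, "LYS", [])
        assert not eligible_pair(a, b)

    def test_same_chain_excluded(self):
        hyl = make_residue("A1A", 10, "HYL", [])
        arg = make_residue("A1A", 40, "ARG", [])
        assert not eligible_pair(hyl, arg)

    def test_hydroxylysine_is_lysine_equivalent(self):
        hyl = make_residue("A1A", 10, "HYL", [])
        arg = make_residue("A2", 40, "ARG", [])
        assert eligible_pair(hyl, arg)

    def test_telopeptide_residues_never_eligible(self):
        lys = make_residue("A1A", 10, "LYS", [])
        arg = make_residue("A2", 40, "ARG", [])
        arg.helical_index = None
        assert not eligible_pair(lys, arg)


class TestPairDistances:
    def test_coincident_atoms_give_zero(self):
        at = [0.0, 0.0, 0.0]
        lys = make_residue("A1A", 1, "LYS", [("NZ", "N", at), ("CE", "C", at), ("CD", "C", at)])
        arg = make_residue("A2", 1, "ARG", [("NH1", "N", at), ("NH2", "N", at), ("NE", "N", at), ("CD", "C", at)])
        d = pair_distances(lys, arg)
        assert (d.d_nn, d.d_ne_ce, d.d_cd_cd) == (0.0, 0.0, 0.0)

    def test_eta_minimum_governs_d_nn(self):
        lys = make_residue(
            "A1A", 1, "LYS",
            [("NZ", "N", [0, 0, 0]), ("CE", "C", [1, 0, 0]), ("CD", "C", [2, 0, 0])],
        )
        arg = make_residue(
            "A2", 1, "ARG",
            [("NH1", "N", [3, 0, 0]), ("NH2", "N", [0, 4, 0]),
             ("NE", "N", [5, 0, 0]), ("CD", "C", [6, 0, 0])],
        )
        assert pair_distances(lys, arg).d_nn == pytest.approx(3.0)

    def test_single_eta_nitrogen_accepted(self):
        lys = make_residue(
            "A1A", 1, "LYS",
            [("NZ", "N", [0, 0, 0]), ("CE", "C", [1, 0, 0]), ("CD", "C", [2, 0, 0])],
        )
        arg = make_residue(
            "A2", 1, "ARG",
            [("NH2", "N", [0, 4, 0]), ("NE", "N", [5, 0, 0]), ("CD", "C", [6, 0, 0])],
        )
        assert pair_distances(lys, arg).d_nn == pytest.approx(4.0)

    def test_missing_atom_is_named(self):
        lys = make_residue("A1A", 7, "LYS", [("NZ", "N", [0, 0, 0]), ("CD", "C", [1, 0, 0])])
        arg = make_residue(
            "A2", 1, "ARG",
            [("NH1", "N", [3, 0, 0]), ("NE", "N", [5, 0, 0]), ("CD", "C", [6, 0, 0])],
        )
        with pytest.raises(MissingAtomError, match="CE"):
            pair_distances(lys, arg)

    def test_planted_distances_recovered(self, planted_pair_molecule):
        molecule, _, _ = planted_pair_molecule
        sites = find_candidate_sites(molecule)
        assert len(sites) == 1
        d = sites[0].distances
        assert d.d_nn == pytest.approx(4.2, abs=0.1)
        assert d.d_ne_ce == pytest.approx(4.8, abs=0.1)
        assert d.d_cd_cd == pytest.approx(5.5, abs=0.1)


class TestSearch:
    def test_no_arginine_means_no_sites(self):
        molecule, _, _ = build_helix(HelixSpec(n_residues=9))
        assert find_candidate_sites(molecule) == []

    def test_single_planted_pair_found_and_accepted(self, planted_pair_molecule):
        molecule, _, _ = planted_pair_molecule
        sites = find_candidate_sites(molecule)
        assert len(sites) == 1
        site = sites[0]
        assert site.accepted
        assert site.site_id == 1
        assert (site.lys_ref.chain_label, site.lys_ref.uniprot_index) == ("A1A", 5)
        assert (site.arg_ref.chain_label, site.arg_ref.uniprot_index) == ("A2", 5)

    @pytest.mark.parametrize(
        "d_nn,expected", [(4.2, 1), (5.0, 1), (5.1, 0)],
        ids=["inside", "at-cutoff", "outside"],
    )
    def test_cutoff_is_inclusive(self, sparse_spec, d_nn, expected):
        plant = PlantDirective(
            kind="candidate_pair",
            lys_slot=("A1A", 5),
            arg_slot=("A2", 5),
            distances=PairDistances(d_nn, 8.0, 9.0),
        )
        molecule, _, _ = build_helix(sparse_spec, [plant])
        assert len(find_candidate_sites(molecule, cutoff=5.0)) == expected

    def test_chain_order_independence(self, planted_pair_molecule):
        molecule, _, _ = planted_pair_molecule
        reordered = CollagenMolecule(
            {k: molecule.chains[k] for k in ("A2", "A1B", "A1A")},
            provenance="reordered",
        )
        a = [(s.lys_ref, s.arg_ref, s.site_id) for s in find_candidate_sites(molecule)]
        b = [(s.lys_ref, s.arg_ref, s.site_id) for s in find_candidate_sites(reordered)]
        assert a == b

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(42)
        molecule, _ = random_helix(rng, n_lysine=5, n_arginine=5)

        def key_set(cutoff):
            return {
                (s.lys_ref.chain_label, s.lys_ref.uniprot_index,
                 s.arg_ref.chain_label, s.arg_ref.uniprot_index)
                for s in find_candidate_sites(molecule, cutoff=cutoff)
            }

        small, large = key_set(4.0), key_set(7.0)
        assert small <= large

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        n_structures_with_sites = 0
        for _ in range(25):
            molecule, _ = random_helix(rng, n_lysine=4, n_arginine=4)
            fast = {
                (s.lys_ref.chain_label, s.lys_ref.uniprot_index,
                 s.arg_ref.chain_label, s.arg_ref.uniprot_index)
                for s in find_candidate_sites(molecule)
            }
            assert fast == brute_force_pairs(molecule)
            n_structures_with_sites += bool(fast)
        assert n_structures_with_sites > 0

    def test_unevaluable_pair_reported(self):
        molecule, _, _ = build_helix(
            HelixSpec(
                n_residues=9,
                substitutions={("A1A", 5): "LYS", ("A2", 5): "ARG"},
            )
        )
        lys = molecule.get_residue("A1A", 5)
        lys.atoms = [a for a in lys.atoms if a.name != "CE"]
        unevaluable = []
        find_candidate_sites(molecule, unevaluable=unevaluable)
        assert len(unevaluable) == 1
        assert "CE" in unevaluable[0][2]

    def test_site_ids_follow_lysine_order(self):
        plants = [
            PlantDirective(kind="candidate_pair", lys_slot=("A1B", 8),
                           arg_slot=("A2", 7), distances=PairDistances(4.0, 9.0, 9.0)),
            PlantDirective(kind="candidate_pair", lys_slot=("A1A", 2),
                           arg_slot=("A2", 3), distances=PairDistances(4.0, 9.0, 9.0)),
        ]
        molecule, _, _ = build_helix(
            HelixSpec(n_residues=9, rise_per_residue=10.0, backbone_radius=16.0), plants
        )
        sites = find_candidate_sites(molecule)
        assert [s.site_id for s in sites] == [1, 2]
        assert sites[0].lys_ref.helical_index < sites[1].lys_ref.helical_index

    def test_frame_roundtrip(self, planted_pair_molecule):
        molecule, _, _ = planted_pair_molecule
        sites = find_candidate_sites(molecule)
        frame = sites_to_frame(sites)
        assert list(frame["site_id"]) == [1]
        assert frame.loc[0, "lys_resname"] == "LYS"
        assert frame.loc[0, "d_nn"] == pytest.approx(4.2, abs=0.1)
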