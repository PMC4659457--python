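"""Shared fixtures: reference table rows, sparse/dense synthetic helices."""

import math

import numpy as np
import pytest

from glycolink.sites import PairDistances
from glycolink.synthetic import (
    HelixSpec,
    PlantDirective,
    build_helix,
    make_table1_fixture,
)


@pytest.fixture(scope="session")
def table1_rows():
    return make_table1_fixture()


@pytest.fixture
def sparse_spec():
    """A wide, stretched helix: planted side chains end up isolated, so
    contact reports are empty unless a clash is planted explicitly."""
    return HelixSpec(n_residues=9, rise_per_residue=8.0, backbone_radius=14.0)


@pytest.fixture
def planted_pair_molecule(sparse_spec):
    plant = PlantDirective(
        kind="candidate_pair",
        lys_slot=("A1A", 5),
        arg_slot=("A2", 5),
        distances=PairDistances(4.2, 4.8, 5.5),
    )
    molecule, cell, pdb_text = build_helix(sparse_spec, [plant])
    return molecule, cell, pdb_text


def brute_force_pairs(molecule, cutoff=5.0):
    """Independent all-pairs oracle for the candidate search: nested loops,
    plain arithmetic, no shared code path with the implementation."""
    lys_names = {"LYS", "HYL", "LYZ"}
    hits = set()
    residues = list(molecule.residues())
    for ra in residues:
        for rb in residues:
            if ra.chain_label == rb.chain_label:
                continue
            if ra.helical_index is None or rb.helical_index is None:
                continue
            if ra.residue_name not in lys_names or rb.residue_name != "ARG":
                continue
            atoms_a = {a.name: a.position for a in ra.atoms}
            atoms_b = {a.name: a.position for a in rb.atoms}
            needed_a = all(n in atoms_a for n in ("NZ", "CE", "CD"))
            etas = [n for n in ("NH1", "NH2") if n in atoms_b]
            needed_b = "NE" in atoms_b and "CD" in atoms_b and etas
            if not (needed_a and needed_b):
                continue
            d1 = min(
                math.dist(atoms_a["NZ"], atoms_b[e]) for e in etas
            )
            d2 = math.dist(atoms_a["CE"], atoms_b["NE"])
            d3 = math.dist(atoms_a["CD"], atoms_b["CD"])
            if min(d1, d2, d3) <= cutoff:
                hits.add(
                    (ra.chain_label, ra.uniprot_index, rb.chain_label, rb.uniprot_index)
                )
    return hits


def brute_force_min_image(p, q, cell):
    """Exhaustive 27-shift minimum-image oracle using explicit loops."""
    mat = cell.matrix
    best = None
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                shift = mat @ np.array([i, j, k], dtype=float)
                d = math.dist(p, q + shift)
                if best is None or d < best[0]:
                    best = (d, (i, j, k))
    return best
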