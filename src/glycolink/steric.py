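"""Close-contact screening of candidate sites under triclinic periodicity.

In a fibril, collagen molecules pack densely; a cross-link that is geometric-
ally feasible inside one molecule can still be blocked by side chains of the
same molecule or of a neighbouring periodic image. This module finds every
heavy-atom close contact between a candidate site's two side chains and the
rest of the structure under the minimum-image convention in a triclinic cell,
and flags sites with severe clashes for exclusion (the call remains auditable
— severe sites are reported, not silently dropped).

The image search is restricted to lattice shifts in {−1, 0, 1}³, valid while
side chains are much smaller than the cell (a documented precondition).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .sites import CandidateSite, ResidueRef
from .structure import CollagenMolecule, TriclinicCell

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_THRESHOLD = 4.0  # Å; upper end of the reported contact range
DEFAULT_SEVERE_THRESHOLD = 2.5   # Å; a clash this deep marks the site excluded

#: All 27 lattice shifts searched by the minimum-image convention here.
SHIFTS = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=int)
_ZERO_SHIFT_INDEX = int(np.flatnonzero((SHIFTS == 0).all(axis=1))[0])


@dataclass(frozen=True)
class Contact:
    """One close heavy-atom contact; ``image_shift`` = (0,0,0) means the
    partner atom belongs to the same molecule, any other value a periodic
    neighbour image."""

    atom_a: tuple[ResidueRef, str]
    atom_b: tuple[ResidueRef, str]
    distance: float
    image_shift: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValidationError("contact distance must be >= 0")


@dataclass
class ContactReport:
    site_id: int
    contacts: list[Contact] = field(default_factory=list)
    severe: bool = False

    def __post_init__(self) -> None:
        if self.severe and not self.contacts:
            raise ValidationError("a severe report must list at least one contact")


def minimum_image_distance(
    p: np.ndarray, q: np.ndarray, cell: TriclinicCell
) -> tuple[float, tuple[int, int, int]]:
    """Smallest ``|p − (q + L·s)|`` over lattice shifts s ∈ {−1,0,1}³.

    Returns the distance and the achieving shift (applied to ``q``).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    images = q + SHIFTS @ cell.matrix.T            # (27, 3)
    d = np.linalg.norm(p - images, axis=1)
    i = int(np.argmin(d))
    return float(d[i]), tuple(int(x) for x in SHIFTS[i])


def _adjacent(ref_chain: str, ref_num: int, res_chain: str, res_num: int) -> bool:
    return ref_chain == res_chain and abs(ref_num - res_num) <= 1


def screen_site(
    site: CandidateSite,
    molecule: CollagenMolecule,
    cell: TriclinicCell | None,
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
    severe_threshold: float = DEFAULT_SEVERE_THRESHOLD,
    include_hydrogens: bool = False,
) -> ContactReport:
    """List every close contact of the site's two side chains.

    Partner atoms are heavy atoms of any other residue, in the same molecule
    (zero shift) or in any of the 26 neighbouring images. Within the same
    molecule, the site residues themselves and residues covalently adjacent
    in sequence to them are excluded; image contacts are kept regardless,
    since an image belongs to a different molecule of the fibril. Without a
    cell only intramolecular contacts can be screened (a warning is logged).

    ``severe`` is set when any listed contact is at or below
    ``severe_threshold``; the pipeline marks such sites "excluded".
    """
    if severe_threshold > contact_threshold:
        raise ValidationError("severe_threshold must not exceed contact_threshold")
    if cell is None:
        logger.warning(
            "site %d: no cell given, screening intramolecular contacts only",
            site.site_id,
        )

    site_res = [
        molecule.get_residue(site.lys_ref.chain_label, site.lys_ref.uniprot_index),
        molecule.get_residue(site.arg_ref.chain_label, site.arg_ref.uniprot_index),
    ]
    site_keys = {(r.chain_label, r.uniprot_index) for r in site_res}

    # partner atoms: every heavy atom in the structure, with ownership
    partner_pos: list[np.ndarray] = []
    partner_meta: list[tuple[ResidueRef, str]] = []
    excluded_intra: list[bool] = []
    for res in molecule.residues():
        is_site = (res.chain_label, res.uniprot_index) in site_keys
        is_adj = any(
            _adjacent(r.chain_label, r.uniprot_index, res.chain_label, res.uniprot_index)
            for r in site_res
        )
        ref = ResidueRef.of(res)
        for atom in res.atoms:
            if not include_hydrogens and atom.element.upper() == "H":
                continue
            partner_pos.append(atom.position)
            partner_meta.append((ref, atom.name))
            excluded_intra.append(is_site or is_adj)
    if not partner_pos:
        return ContactReport(site_id=site.site_id)
    pos = np.asarray(partner_pos)                    # (n, 3)
    excl = np.asarray(excluded_intra)

    if cell is not None:
        offsets = SHIFTS @ cell.matrix.T             # (27, 3)
    else:
        offsets = np.zeros((1, 3))

    contacts: list[Contact] = []
    for res in site_res:
        ref = ResidueRef.of(res)
        for atom in res.side_chain_atoms(include_hydrogens=include_hydrogens):
            # distances of this atom to all partners under all shifts
            diff = atom.position - (pos[None, :, :] + offsets[:, None, :])
            dist = np.linalg.norm(diff, axis=2)      # (n_shift, n)
            if cell is not None:
                zero = dist[_ZERO_SHIFT_INDEX].copy()
                nz = dist.copy()
                nz[_ZERO_SHIFT_INDEX] = np.inf
                nz_min = nz.min(axis=0)
                nz_arg = nz.argmin(axis=0)
                best = np.where(excl, nz_min, np.minimum(zero, nz_min))
                use_zero = (~excl) & (zero <= nz_min)
            else:
                zero = dist[0]
                best = np.where(excl, np.inf, zero)
                nz_min = np.full_like(zero, np.inf)
                nz_arg = np.zeros(len(zero), dtype=int)
                use_zero = ~excl
            for j in np.flatnonzero(best <= contact_threshold):
                if use_zero[j]:
                    shift = (0, 0, 0)
                else:
                    shift = tuple(int(x) for x in SHIFTS[nz_arg[j]])
                contacts.append(
                    Contact(
                        atom_a=(ref, atom.name),
                        atom_b=partner_meta[j],
                        distance=float(best[j]),
                        image_shift=shift,
                    )
                )
    contacts.sort(key=lambda c: c.distance)
    severe = any(c.distance <= severe_threshold for c in contacts)
    return ContactReport(site_id=site.site_id, contacts=contacts, severe=severe)


CONTACT_COLUMNS = [
    "site_id", "chain_a", "uniprot_a", "resname_a", "atom_a",
    "chain_b", "uniprot_b", "resname_b", "atom_b",
    "distance", "shift_x", "shift_y", "shift_z", "severe_contact",
]


def contacts_to_frame(
    reports: list[ContactReport],
    severe_threshold: float = DEFAULT_SEVERE_THRESHOLD,
) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for c in rep.contacts:
            (ref_a, name_a), (ref_b, name_b) = c.atom_a, c.atom_b
            rows.append(
                {
                    "site_id": rep.site_id,
                    "chain_a": ref_a.chain_label,
                    "uniprot_a": ref_a.uniprot_index,
                    "resname_a": ref_a.residue_name,
                    "atom_a": name_a,
                    "chain_b": ref_b.chain_label,
                    "uniprot_b": ref_b.uniprot_index,
                    "resname_b": ref_b.residue_name,
                    "atom_b": name_b,
                    "distance": c.distance,
                    "shift_x": c.image_shift[0],
                    "shift_y": c.image_shift[1],
                    "shift_z": c.image_shift[2],
                    "severe_contact": c.distance <= severe_threshold,
                }
            )
    return pd.DataFrame(rows, columns=CONTACT_COLUMNS)
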