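"""Collagen molecule model: chains, dual residue numbering, unit cell, charges.

A type I collagen molecule is a heterotrimer of two identical alpha-1 chains
and one alpha-2 chain. The two alpha-1 copies are distinguished by the fixed
labels ``A1A`` and ``A1B`` (the user's chain map decides which file chain is
which); the alpha-2 chain is ``A2``. Residues carry two numberings: the
precursor (UniProt) index taken verbatim from the structure file, and the
triple-helical index counted from the first residue of the helical domain.
Telopeptide residues have no helical index and are excluded from the
cross-link candidate search.

The fibrillar packing environment is represented by a triclinic unit cell;
cell algebra (orthogonalization matrix, volume) is delegated to :mod:`gemmi`.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import gemmi
import numpy as np

from .errors import (
    ChargeRuleError,
    DuplicateResidueError,
    InputError,
    MissingChainError,
    ValidationError,
)

logger = logging.getLogger(__name__)

CHAIN_LABELS = ("A1A", "A1B", "A2")

#: Hydroxylysine appears under several PDB dialect codes; all are accepted
#: and treated as lysine-equivalent wherever the free amine matters.
HYDROXYLYSINE_CODES = frozenset({"HYL", "LYZ"})
LYSINE_LIKE = frozenset({"LYS"}) | HYDROXYLYSINE_CODES

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Default side-chain formal charges at physiological pH (standard
#: protonation states). Histidine is neutral by default; override by
#: passing a custom rule mapping to :func:`charge_census`.
DEFAULT_CHARGE_RULES: dict[str, int] = {
    "ALA": 0, "ARG": +1, "ASN": 0, "ASP": -1, "CYS": 0, "GLN": 0,
    "GLU": -1, "GLY": 0, "HIS": 0, "ILE": 0, "LEU": 0, "LYS": +1,
    "MET": 0, "PHE": 0, "PRO": 0, "SER": 0, "THR": 0, "TRP": 0,
    "TYR": 0, "VAL": 0, "HYP": 0,
}
DEFAULT_CHARGE_RULES.update({code: +1 for code in HYDROXYLYSINE_CODES})


@dataclass
class AtomRecord:
    """One atom: PDB name, element symbol, Cartesian position in Å."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.name:
            raise ValidationError("atom name must be non-empty")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValidationError(
                f"atom {self.name}: position must be a finite 3-vector"
            )


@dataclass
class Residue:
    """A residue with dual numbering.

    ``helical_index`` is ``None`` for telopeptide residues, which lie outside
    the triple-helical numbering range.
    """

    chain_label: str
    uniprot_index: int
    residue_name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    helical_index: int | None = None

    def __post_init__(self) -> None:
        if self.chain_label not in CHAIN_LABELS:
            raise ValidationError(f"unknown chain label {self.chain_label!r}")
        if self.uniprot_index < 1:
            raise ValidationError("uniprot_index must be >= 1")
        if self.helical_index is not None and self.helical_index < 1:
            raise ValidationError("helical_index must be >= 1 when present")

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_lysine_like(self) -> bool:
        return self.residue_name in LYSINE_LIKE

    @property
    def is_arginine(self) -> bool:
        return self.residue_name == "ARG"

    def side_chain_atoms(self, include_hydrogens: bool = False) -> list[AtomRecord]:
        out = []
        for a in self.atoms:
            if a.name in BACKBONE_ATOMS:
                continue
            if not include_hydrogens and a.element.upper() == "H":
                continue
            out.append(a)
        return out


@dataclass
class TriclinicCell:
    """Triclinic periodic box (lengths in Å, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValidationError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValidationError("cell angles must lie strictly in (0, 180)")
        if self.volume <= 0:
            raise ValidationError("cell volume must be positive")

    def _gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def matrix(self) -> np.ndarray:
        """Orthogonalization matrix; columns are the lattice vectors a, b, c."""
        return np.array(self._gemmi().orth.mat.tolist(), dtype=float)

    @property
    def volume(self) -> float:
        return float(self._gemmi().volume)


class CollagenMolecule:
    """Three labelled chains of residues (two alpha-1 copies, one alpha-2)."""

    def __init__(
        self,
        chains: Mapping[str, list[Residue]],
        provenance: str = "",
    ) -> None:
        if set(chains) != set(CHAIN_LABELS):
            raise ValidationError(
                f"chains must carry exactly the labels {CHAIN_LABELS}, got {sorted(chains)}"
            )
        self.chains: dict[str, list[Residue]] = {k: list(chains[k]) for k in CHAIN_LABELS}
        self.provenance = provenance
        self._index: dict[tuple[str, int], Residue] = {}
        for label, residues in self.chains.items():
            for res in residues:
                if res.chain_label != label:
                    raise ValidationError(
                        f"residue {res.uniprot_index} labelled {res.chain_label} "
                        f"stored under chain {label}"
                    )
                key = (label, res.uniprot_index)
                if key in self._index:
                    raise DuplicateResidueError(
                        f"duplicate residue {label}:{res.uniprot_index}"
                    )
                self._index[key] = res

    def residues(self) -> Iterator[Residue]:
        for label in CHAIN_LABELS:
            yield from self.chains[label]

    def get_residue(self, chain_label: str, uniprot_index: int) -> Residue:
        try:
            return self._index[(chain_label, uniprot_index)]
        except KeyError:
            raise InputError(
                f"no residue {chain_label}:{uniprot_index} in molecule"
            ) from None

    @property
    def n_residues(self) -> int:
        return len(self._index)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


@dataclass
class ChargeCensus:
    """Counts of charged side-chain sites and the resulting net charge."""

    n_cationic: int
    n_anionic: int
    net_charge: int | None = None

    def __post_init__(self) -> None:
        expected = self.n_cationic - self.n_anionic
        if self.net_charge is None:
            self.net_charge = expected
        elif self.net_charge != expected:
            raise ValidationError(
                f"net_charge {self.net_charge} != n_cationic - n_anionic = {expected}"
            )


def charge_census(
    molecule: CollagenMolecule,
    rules: Mapping[str, int] | None = None,
) -> ChargeCensus:
    """Count basic (+1) and acidic (−1) side-chain sites.

    Termini are ignored; every residue name must be covered by ``rules``
    (default: standard protonation states at physiological pH, His neutral).
    """
    rules = DEFAULT_CHARGE_RULES if rules is None else rules
    unknown = sorted(
        {r.residue_name for r in molecule.residues() if r.residue_name not in rules}
    )
    if unknown:
        raise ChargeRuleError(
            f"residue names not covered by protonation rules: {', '.join(unknown)}"
        )
    n_cat = sum(1 for r in molecule.residues() if rules[r.residue_name] > 0)
    n_an = sum(1 for r in molecule.residues() if rules[r.residue_name] < 0)
    return ChargeCensus(n_cationic=n_cat, n_anionic=n_an)


_DEFAULT_GEMMI_CELL = (1.0, 1.0, 1.0, 90.0, 90.0, 90.0)


def read_structure(
    pdb_text: str,
    chain_map: Mapping[str, str],
    offsets: "object | None" = None,
    helical_max: int | None = None,
) -> tuple[CollagenMolecule, TriclinicCell | None]:
    """Parse PDB text into a :class:`CollagenMolecule` (+ cell, if CRYST1 given).

    ``chain_map`` maps file chain IDs to the canonical labels A1A/A1B/A2;
    unmapped chains are ignored (a count is logged). Residue numbers in the
    file are taken verbatim as UniProt numbering. If ``offsets`` (a
    :class:`glycolink.domains.ChainOffsets`) is given, triple-helical indices
    are assigned immediately via :func:`assign_helical_numbering`.
    """
    inverse: dict[str, str] = {}
    for file_id, label in chain_map.items():
        if label not in CHAIN_LABELS:
            raise ValidationError(f"chain_map target {label!r} not in {CHAIN_LABELS}")
        inverse[file_id] = label
    if len(set(chain_map.values())) != 3:
        raise ValidationError("chain_map must cover all three labels A1A, A1B, A2")

    st = gemmi.read_pdb_string(pdb_text)
    st.setup_entities()
    chains: dict[str, list[Residue]] = {label: [] for label in CHAIN_LABELS}
    seen: set[tuple[str, int]] = set()
    n_skipped = 0
    model = st[0]
    for chain in model:
        label = inverse.get(chain.name)
        if label is None:
            n_skipped += 1
            continue
        for gres in chain:
            num = gres.seqid.num
            key = (label, num)
            if key in seen:
                raise DuplicateResidueError(f"duplicate residue {label}:{num}")
            seen.add(key)
            atoms = [
                AtomRecord(
                    name=atom.name,
                    element=atom.element.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                )
                for atom in gres
            ]
            chains[label].append(
                Residue(
                    chain_label=label,
                    uniprot_index=num,
                    residue_name=gres.name.upper(),
                    atoms=atoms,
                )
            )
    if n_skipped:
        logger.info("ignored %d unmapped chain(s)", n_skipped)
    missing = [label for label in CHAIN_LABELS if not chains[label]]
    if missing:
        raise MissingChainError(
            f"mapped chain(s) absent from structure: {', '.join(missing)}"
        )

    cellpar = (st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
    cell: TriclinicCell | None = None
    if not np.allclose(cellpar, _DEFAULT_GEMMI_CELL):
        cell = TriclinicCell(*cellpar)

    molecule = CollagenMolecule(chains, provenance="read_structure")
    if offsets is not None:
        assign_helical_numbering(molecule, offsets, helical_max=helical_max)
    return molecule, cell


def assign_helical_numbering(
    molecule: CollagenMolecule,
    offsets,
    helical_max: int | None = None,
) -> None:
    """Set ``helical_index = uniprot_index − offset(chain)`` where valid.

    Residues mapping to an index < 1 (or > ``helical_max`` if given) are
    telopeptide: their helical index is left absent.
    """
    for res in molecule.residues():
        h = res.uniprot_index - offsets.offset_for(res.chain_label)
        if h >= 1 and (helical_max is None or h <= helical_max):
            res.helical_index = h
        else:
            res.helical_index = None


_DEFAULT_CHAIN_IDS = {"A1A": "A", "A1B": "B", "A2": "C"}


def write_pdb(
    molecule: CollagenMolecule,
    cell: TriclinicCell | None = None,
    chain_ids: Mapping[str, str] | None = None,
) -> str:
    """Serialize to PDB text (coordinates at the format's 3-decimal precision)."""
    chain_ids = dict(chain_ids or _DEFAULT_CHAIN_IDS)
    buf = io.StringIO()
    if cell is not None:
        buf.write(
            f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
            f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} P 1           1\n"
        )
    serial = 0
    for label in CHAIN_LABELS:
        cid = chain_ids[label]
        for res in molecule.chains[label]:
            for atom in res.atoms:
                serial += 1
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.position
                buf.write(
                    f"ATOM  {serial:5d} {name}{'':1s}{res.residue_name:>3s} "
                    f"{cid}{res.uniprot_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
        serial += 1
        buf.write(f"TER   {serial:5d}\n")
    buf.write("END\n")
    return buf.getvalue()
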