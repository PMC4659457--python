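"""Distance-criterion search for candidate Lys/Hyl–Arg cross-link pairs.

Glucosepane bridges a lysine (or hydroxylysine) side-chain amine and an
arginine guanidinium. Candidate sites are screened geometrically on a single
low-energy conformation: the distance between the side chains is measured at
three points —

1. lysine Nζ to arginine Nη (minimum over the two η nitrogens NH1/NH2),
2. lysine Cε to arginine Nε,
3. lysine Cδ to arginine Cδ

— and a pair is a candidate when at least one of the three distances falls
within the cutoff (default 5 Å, inclusive). Only pairs on *separate* chains
of the triple helix are eligible, and only residues inside the triple-helical
domain (telopeptides carry no helical index and are skipped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingAtomError, ValidationError
from .structure import CollagenMolecule, Residue

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 5.0  # Å

#: tie guard for the inclusive cutoff: a pair constructed to sit exactly at
#: the cutoff must not be dropped by the last float ulp of the distance
_CUTOFF_ATOL = 1e-9


@dataclass(frozen=True)
class PairDistances:
    """The three criterion distances (Å) for one Lys/Hyl–Arg pair."""

    d_nn: float        # Lys NZ – Arg NH1/NH2 (min)
    d_ne_ce: float     # Arg NE – Lys CE
    d_cd_cd: float     # Arg CD – Lys CD

    def __post_init__(self) -> None:
        for v in (self.d_nn, self.d_ne_ce, self.d_cd_cd):
            if not np.isfinite(v) or v < 0:
                raise ValidationError("criterion distances must be finite and >= 0")

    @property
    def minimum(self) -> float:
        return min(self.d_nn, self.d_ne_ce, self.d_cd_cd)


@dataclass(frozen=True)
class ResidueRef:
    """Lightweight reference to a residue: chain, dual numbering, name."""

    chain_label: str
    uniprot_index: int
    helical_index: int | None
    residue_name: str

    @classmethod
    def of(cls, res: Residue) -> "ResidueRef":
        return cls(res.chain_label, res.uniprot_index, res.helical_index, res.residue_name)


@dataclass(frozen=True)
class CandidateSite:
    """One candidate cross-link pair, numbered N→C along the lysine partner."""

    site_id: int
    lys_ref: ResidueRef
    arg_ref: ResidueRef
    distances: PairDistances
    accepted: bool

    def __post_init__(self) -> None:
        if self.lys_ref.chain_label == self.arg_ref.chain_label:
            raise ValidationError("cross-link partners must lie on separate chains")


def eligible_pair(res_a: Residue, res_b: Residue) -> bool:
    """True iff exactly one residue is Arg, the other Lys/Hyl, on different chains.

    Both residues must be inside the triple-helical domain (helical index
    present); telopeptide residues never form eligible pairs.
    """
    if res_a.helical_index is None or res_b.helical_index is None:
        return False
    if res_a.chain_label == res_b.chain_label:
        return False
    return (res_a.is_lysine_like and res_b.is_arginine) or (
        res_a.is_arginine and res_b.is_lysine_like
    )


def _require_atom(res: Residue, name: str) -> np.ndarray:
    atom = res.atom(name)
    if atom is None:
        raise MissingAtomError(
            f"{res.residue_name} {res.chain_label}:{res.uniprot_index} "
            f"is missing atom {name}"
        )
    return atom.position


def pair_distances(lys: Residue, arg: Residue) -> PairDistances:
    """Euclidean criterion distances; raises :class:`MissingAtomError` if a
    required side-chain atom is absent (the site is unevaluable, not skipped)."""
    nz = _require_atom(lys, "NZ")
    ce = _require_atom(lys, "CE")
    cd_l = _require_atom(lys, "CD")
    ne = _require_atom(arg, "NE")
    cd_a = _require_atom(arg, "CD")
    etas = [arg.atom(n) for n in ("NH1", "NH2")]
    etas = [a for a in etas if a is not None]
    if not etas:
        raise MissingAtomError(
            f"ARG {arg.chain_label}:{arg.uniprot_index} is missing atoms NH1/NH2"
        )
    d_nn = min(float(np.linalg.norm(nz - a.position)) for a in etas)
    return PairDistances(
        d_nn=d_nn,
        d_ne_ce=float(np.linalg.norm(ne - ce)),
        d_cd_cd=float(np.linalg.norm(cd_a - cd_l)),
    )


def find_candidate_sites(
    molecule: CollagenMolecule,
    cutoff: float = DEFAULT_CUTOFF,
    unevaluable: list | None = None,
) -> list[CandidateSite]:
    """All eligible inter-chain Lys/Hyl–Arg pairs whose minimum criterion
    distance is within ``cutoff`` (inclusive).

    The result is deduplicated (one entry per residue pair regardless of scan
    order), sorted by the lysine's helical index then the arginine's, and
    numbered consecutively from 1. Pairs with missing criterion atoms are
    appended to ``unevaluable`` (if given) as ``(lys_ref, arg_ref, message)``
    and logged — never silently dropped.
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    lys_res = [
        r for r in molecule.residues()
        if r.is_lysine_like and r.helical_index is not None
    ]
    arg_res = [
        r for r in molecule.residues()
        if r.is_arginine and r.helical_index is not None
    ]
    found: list[tuple] = []
    for lys in lys_res:
        for arg in arg_res:
            if lys.chain_label == arg.chain_label:
                continue
            try:
                d = pair_distances(lys, arg)
            except MissingAtomError as exc:
                logger.warning("unevaluable pair: %s", exc)
                if unevaluable is not None:
                    unevaluable.append((ResidueRef.of(lys), ResidueRef.of(arg), str(exc)))
                continue
            if d.minimum <= cutoff + _CUTOFF_ATOL:
                found.append((lys, arg, d))
    found.sort(
        key=lambda t: (
            t[0].helical_index, t[1].helical_index,
            t[0].chain_label, t[1].chain_label,
        )
    )
    return [
        CandidateSite(
            site_id=i,
            lys_ref=ResidueRef.of(lys),
            arg_ref=ResidueRef.of(arg),
            distances=d,
            accepted=True,
        )
        for i, (lys, arg, d) in enumerate(found, start=1)
    ]


SITE_COLUMNS = [
    "site_id", "lys_chain", "lys_uniprot", "lys_helical", "lys_resname",
    "arg_chain", "arg_uniprot", "arg_helical", "arg_resname",
    "d_nn", "d_ne_ce", "d_cd_cd", "accepted",
]


def sites_to_frame(sites: list[CandidateSite]) -> pd.DataFrame:
    rows = [
        {
            "site_id": s.site_id,
            "lys_chain": s.lys_ref.chain_label,
            "lys_uniprot": s.lys_ref.uniprot_index,
            "lys_helical": s.lys_ref.helical_index,
            "lys_resname": s.lys_ref.residue_name,
            "arg_chain": s.arg_ref.chain_label,
            "arg_uniprot": s.arg_ref.uniprot_index,
            "arg_helical": s.arg_ref.helical_index,
            "arg_resname": s.arg_ref.residue_name,
            "d_nn": s.distances.d_nn,
            "d_ne_ce": s.distances.d_ne_ce,
            "d_cd_cd": s.distances.d_cd_cd,
            "accepted": s.accepted,
        }
        for s in sites
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def sites_from_frame(frame: pd.DataFrame) -> list[CandidateSite]:
    sites = []
    for row in frame.itertuples(index=False):
        sites.append(
            CandidateSite(
                site_id=int(row.site_id),
                lys_ref=ResidueRef(
                    row.lys_chain, int(row.lys_uniprot),
                    None if pd.isna(row.lys_helical) else int(row.lys_helical),
                    row.lys_resname,
                ),
                arg_ref=ResidueRef(
                    row.arg_chain, int(row.arg_uniprot),
                    None if pd.isna(row.arg_helical) else int(row.arg_helical),
                    row.arg_resname,
                ),
                distances=PairDistances(
                    float(row.d_nn), float(row.d_ne_ce), float(row.d_cd_cd)
                ),
                accepted=bool(row.accepted),
            )
        )
    return sites
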