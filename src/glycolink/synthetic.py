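"""Synthetic inputs: idealized triple helices, planted geometry, energy series.

Building a realistic collagen model from sequence is out of scope here; what
the pipeline needs for testing is geometric plausibility. The generator
produces an idealized triple helix — three chains on a common axis with the
standard collagen approximation of 10/3 helical symmetry (2.86 Å axial rise
and −103.9° twist per residue), a 2.6 Å backbone radius and a one-residue
axial stagger between chains — carrying a repeating Gly-Pro-Hyp sequence
with Lys/Hyl/Arg substitutions where directed.

Substituted residues get *minimal* side chains carrying exactly the atoms
the distance criterion needs (Lys: CD, CE, NZ; Arg: CD, NE, NH1, NH2).
Plant directives place those atoms in closed form so that either a candidate
pair hits prescribed criterion distances (to well under 0.1 Å) or a steric
clash appears at a prescribed distance in a prescribed neighbour image.

Energy series are stationary AR(1) processes around a planted mean: the
planted mean offset between a cross-linked and a native series is the ground
-truth ΔH that the analysis must recover. Defaults mirror the study
conditions the analysis targets: a 60 ns production trace sampled every
0.01 ns whose last-25-ns naive SEM is ≈ 0.7 kcal/mol (frame sd 35, since
35/√2500 = 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .energetics import EnergySeries
from .errors import SyntheticSpecError
from .sites import PairDistances
from .structure import (
    AtomRecord,
    CHAIN_LABELS,
    CollagenMolecule,
    Residue,
    TriclinicCell,
    write_pdb,
)

DEFAULT_RISE = 2.86          # Å per residue along the axis
DEFAULT_TWIST = -103.9       # degrees per residue (10/3 symmetry)
DEFAULT_RADIUS = 2.6         # Å, backbone circle
DEFAULT_STAGGER = 1          # residues of axial stagger between chains
DEFAULT_PATTERN = ("GLY", "PRO", "HYP")
AXIAL_CLEARANCE = 10.0       # Å of empty cell beyond the helix along c
LATERAL_CELL = 30.0          # Å cell edge perpendicular to the axis

# study-condition defaults for energy series
DEFAULT_N_FRAMES = 6000      # 60 ns production
DEFAULT_DT = 0.01            # ns between frames
DEFAULT_SD = 35.0            # kcal/mol per frame -> last-25-ns SEM ~ 0.7


@dataclass
class HelixSpec:
    """Geometry and sequence of an idealized triple helix."""

    n_residues: int = 30
    rise_per_residue: float = DEFAULT_RISE
    twist_per_residue: float = DEFAULT_TWIST
    backbone_radius: float = DEFAULT_RADIUS
    chain_stagger: int = DEFAULT_STAGGER
    sequence_pattern: tuple[str, ...] = DEFAULT_PATTERN
    substitutions: dict[tuple[str, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise SyntheticSpecError("n_residues must be >= 3")
        if self.rise_per_residue <= 0 or self.backbone_radius <= 0:
            raise SyntheticSpecError("rise and radius must be positive")
        for (chain, idx), name in self.substitutions.items():
            if chain not in CHAIN_LABELS or not 1 <= idx <= self.n_residues:
                raise SyntheticSpecError(
                    f"substitution slot ({chain}, {idx}) out of range"
                )

    @classmethod
    def from_dict(cls, d: Mapping) -> "HelixSpec":
        subs = {
            (str(s["chain"]), int(s["index"])): str(s["resname"]).upper()
            for s in d.get("substitutions", [])
        }
        return cls(
            n_residues=int(d.get("n_residues", 30)),
            rise_per_residue=float(d.get("rise_per_residue", DEFAULT_RISE)),
            twist_per_residue=float(d.get("twist_per_residue", DEFAULT_TWIST)),
            backbone_radius=float(d.get("backbone_radius", DEFAULT_RADIUS)),
            chain_stagger=int(d.get("chain_stagger", DEFAULT_STAGGER)),
            sequence_pattern=tuple(d.get("sequence_pattern", DEFAULT_PATTERN)),
            substitutions=subs,
        )


@dataclass
class PlantDirective:
    """Ground truth planted into a synthetic structure.

    ``candidate_pair``: ``lys_slot``/``arg_slot`` name (chain, residue index)
    positions on different chains; ``distances`` are the target criterion
    distances. ``clash``: an extra residue is appended (outside the helical
    numbering) whose NZ sits ``clash_distance`` Å from the NZ/NE of
    ``lys_slot`` *in the periodic image* reached by ``image_shift``.
    """

    kind: str
    lys_slot: tuple[str, int] | None = None
    arg_slot: tuple[str, int] | None = None
    distances: PairDistances | None = None
    clash_distance: float | None = None
    image_shift: tuple[int, int, int] = (1, 0, 0)

    def __post_init__(self) -> None:
        if self.kind == "candidate_pair":
            if self.lys_slot is None or self.arg_slot is None or self.distances is None:
                raise SyntheticSpecError(
                    "candidate_pair directive needs lys_slot, arg_slot and distances"
                )
            if self.lys_slot[0] == self.arg_slot[0]:
                raise SyntheticSpecError(
                    f"candidate_pair directive {self.lys_slot}/{self.arg_slot}: "
                    "partners must lie on different chains"
                )
        elif self.kind == "clash":
            if self.lys_slot is None or self.clash_distance is None:
                raise SyntheticSpecError("clash directive needs lys_slot and clash_distance")
            if self.clash_distance <= 0:
                raise SyntheticSpecError("clash_distance must be positive")
            if self.image_shift == (0, 0, 0):
                raise SyntheticSpecError("clash image_shift must be non-zero")
        else:
            raise SyntheticSpecError(f"unknown directive kind {self.kind!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlantDirective":
        kind = str(d["kind"])
        dist = d.get("distances")
        return cls(
            kind=kind,
            lys_slot=tuple(d["lys_slot"]) if "lys_slot" in d else None,
            arg_slot=tuple(d["arg_slot"]) if "arg_slot" in d else None,
            distances=None if dist is None else PairDistances(*[float(x) for x in dist]),
            clash_distance=d.get("clash_distance"),
            image_shift=tuple(d.get("image_shift", (1, 0, 0))),
        )


def _perp(u: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to u."""
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, u)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    v = trial - np.dot(trial, u) * u
    return v / np.linalg.norm(v)


def _ca_position(spec: HelixSpec, chain_idx: int, res_idx: int) -> np.ndarray:
    """Idealized CA placement: chain phase 120° apart, shared axis along z."""
    t = (res_idx - 1) + spec.chain_stagger * chain_idx
    theta = np.deg2rad(120.0 * chain_idx + spec.twist_per_residue * t)
    r = spec.backbone_radius
    return np.array([r * np.cos(theta), r * np.sin(theta), spec.rise_per_residue * t])


_LYS_SIDE = ("CD", "CE", "NZ")
_ARG_SIDE = ("CD", "NE", "NH1", "NH2")


def _default_side_chain(
    res: Residue,
    ca: np.ndarray,
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
    direction: np.ndarray | None = None,
) -> None:
    """Extend a minimal side chain outward from the axis (or along
    ``direction``), with optional positional jitter."""
    if direction is None:
        radial = np.array([ca[0], ca[1], 0.0])
        nrm = np.linalg.norm(radial)
        direction = radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
    if rng is not None and jitter > 0:
        direction = direction + rng.normal(0.0, jitter, 3)
        direction = direction / np.linalg.norm(direction)
    perp = _perp(direction)

    def jit() -> np.ndarray:
        if rng is None or jitter <= 0:
            return np.zeros(3)
        return rng.normal(0.0, jitter, 3)

    if res.is_lysine_like:
        spots = {"CD": 1.5, "CE": 2.9, "NZ": 4.2}
        for name, dist in spots.items():
            res.atoms.append(
                AtomRecord(name, "N" if name == "NZ" else "C",
                           ca + dist * direction + jit())
            )
    elif res.is_arginine:
        res.atoms.append(AtomRecord("CD", "C", ca + 1.5 * direction + jit()))
        res.atoms.append(AtomRecord("NE", "N", ca + 2.7 * direction + jit()))
        res.atoms.append(AtomRecord("NH1", "N", ca + 3.9 * direction + 1.0 * perp + jit()))
        res.atoms.append(AtomRecord("NH2", "N", ca + 3.9 * direction - 1.0 * perp + jit()))


def _plant_pair(
    lys: Residue, arg: Residue, targets: PairDistances
) -> None:
    """Closed-form atom placement hitting the three criterion distances
    exactly: each criterion pair straddles the midpoint of the two CAs along
    a shared contact axis, on its own perpendicular rail."""
    ca_l = lys.atom("CA").position
    ca_a = arg.atom("CA").position
    mid = 0.5 * (ca_l + ca_a)
    u = ca_a - ca_l
    nrm = np.linalg.norm(u)
    if nrm < 1e-9:
        raise SyntheticSpecError("planted pair CAs coincide; directive unsatisfiable")
    u = u / nrm
    # push the contact centre radially outward so the planted side chains sit
    # outside the backbone circle instead of threading through the helix core
    radial = np.array([mid[0], mid[1], 0.0])
    rnrm = np.linalg.norm(radial)
    radial = radial / rnrm if rnrm > 1e-9 else np.array([1.0, 0.0, 0.0])
    r_backbone = max(np.linalg.norm(ca_l[:2]), np.linalg.norm(ca_a[:2]))
    mid = mid + (r_backbone + 4.0 - rnrm) * radial
    v = _perp(u)

    lys.atoms = [a for a in lys.atoms if a.name not in _LYS_SIDE]
    arg.atoms = [a for a in arg.atoms if a.name not in _ARG_SIDE]
    # criterion 1: Lys NZ -- Arg NH1 at d_nn (NH2 strictly farther)
    lys.atoms.append(AtomRecord("NZ", "N", mid - 0.5 * targets.d_nn * u))
    arg.atoms.append(AtomRecord("NH1", "N", mid + 0.5 * targets.d_nn * u))
    arg.atoms.append(AtomRecord("NH2", "N", mid + (0.5 * targets.d_nn + 1.1) * u))
    # criterion 2: Lys CE -- Arg NE at d_ne_ce, offset to its own rail
    lys.atoms.append(AtomRecord("CE", "C", mid + 0.8 * v - 0.5 * targets.d_ne_ce * u))
    arg.atoms.append(AtomRecord("NE", "N", mid + 0.8 * v + 0.5 * targets.d_ne_ce * u))
    # criterion 3: Lys CD -- Arg CD at d_cd_cd
    lys.atoms.append(AtomRecord("CD", "C", mid + 1.6 * v - 0.5 * targets.d_cd_cd * u))
    arg.atoms.append(AtomRecord("CD", "C", mid + 1.6 * v + 0.5 * targets.d_cd_cd * u))


def build_helix(
    spec: HelixSpec,
    plants: Sequence[PlantDirective] = (),
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
) -> tuple[CollagenMolecule, TriclinicCell, str]:
    """Build the idealized helix, apply plant directives, and return
    (molecule, periodic cell, PDB text).

    The cell is sized so that atoms of *unplanted* residues stay more than
    8 Å from every neighbour image; planted clashes are introduced
    explicitly via their directives.
    """
    chains: dict[str, list[Residue]] = {}
    for chain_idx, label in enumerate(CHAIN_LABELS):
        residues = []
        for j in range(1, spec.n_residues + 1):
            name = spec.substitutions.get(
                (label, j), spec.sequence_pattern[(j - 1) % len(spec.sequence_pattern)]
            )
            ca = _ca_position(spec, chain_idx, j)
            res = Residue(
                chain_label=label,
                uniprot_index=j,
                residue_name=name,
                atoms=[AtomRecord("CA", "C", ca)],
                helical_index=j,
            )
            residues.append(res)
        chains[label] = residues

    molecule = CollagenMolecule(chains, provenance="synthetic idealized helix")

    # force plant slots to the right residue types
    for p in plants:
        if p.kind == "candidate_pair":
            lys = molecule.get_residue(*p.lys_slot)
            arg = molecule.get_residue(*p.arg_slot)
            if not lys.is_lysine_like:
                lys.residue_name = "LYS"
            arg.residue_name = "ARG"
        elif p.kind == "clash":
            anchor = molecule.get_residue(*p.lys_slot)
            if not (anchor.is_lysine_like or anchor.is_arginine):
                anchor.residue_name = "LYS"

    # default side chains for every Lys/Hyl/Arg not re-placed by a pair plant
    planted_slots = {
        slot
        for p in plants
        if p.kind == "candidate_pair"
        for slot in (p.lys_slot, p.arg_slot)
    }
    for res in molecule.residues():
        if (res.is_lysine_like or res.is_arginine) and (
            (res.chain_label, res.uniprot_index) not in planted_slots
        ):
            _default_side_chain(res, res.atom("CA").position, rng=rng, jitter=jitter)

    for p in plants:
        if p.kind == "candidate_pair":
            _plant_pair(
                molecule.get_residue(*p.lys_slot),
                molecule.get_residue(*p.arg_slot),
                p.distances,
            )

    # size the cell from the realized coordinates so that neighbour images of
    # unplanted atoms stay at least AXIAL_CLEARANCE apart in every direction
    coords = np.array([a.position for r in molecule.residues() for a in r.atoms])
    r_max = float(np.sqrt((coords[:, 0] ** 2 + coords[:, 1] ** 2).max()))
    z_extent = float(coords[:, 2].max() - coords[:, 2].min())
    lateral = max(LATERAL_CELL, 2.0 * r_max + AXIAL_CLEARANCE)
    cell = TriclinicCell(a=lateral, b=lateral, c=z_extent + AXIAL_CLEARANCE)

    # clash plants go in last: they need the cell to aim at a specific image
    n_extra = 0
    for p in plants:
        if p.kind != "clash":
            continue
        anchor = molecule.get_residue(*p.lys_slot)
        target_atom = anchor.atom("NZ") or anchor.atom("NE") or anchor.atom("CA")
        direction = _perp(np.array([0.0, 0.0, 1.0]))
        shift_vec = cell.matrix @ np.asarray(p.image_shift, dtype=float)
        q = target_atom.position + p.clash_distance * direction - shift_vec
        n_extra += 1
        extra = Residue(
            chain_label="A2",
            uniprot_index=spec.n_residues + spec.chain_stagger * 2 + n_extra,
            residue_name="LYS",
            atoms=[
                AtomRecord("NZ", "N", q),
                AtomRecord("CA", "C", q + 2.5 * direction),
            ],
            helical_index=None,   # outside the helical domain: never a candidate
        )
        molecule.chains["A2"].append(extra)
        molecule._index[(extra.chain_label, extra.uniprot_index)] = extra

    pdb_text = write_pdb(molecule, cell)
    return molecule, cell, pdb_text


def random_helix(
    rng: np.random.Generator,
    n_residues: int = 30,
    n_lysine: int = 3,
    n_arginine: int = 3,
    jitter: float = 0.6,
    hydroxylysine_fraction: float = 0.25,
) -> tuple[CollagenMolecule, TriclinicCell]:
    """A randomized helix for property tests: Lys/Hyl and Arg scattered over
    random chain/slot positions with jittered side-chain directions, so that
    some inter-chain pairs land inside and some outside the 5 Å cutoff."""
    slots = [
        (label, idx) for label in CHAIN_LABELS for idx in range(1, n_residues + 1)
    ]
    picks = rng.choice(len(slots), size=n_lysine + n_arginine, replace=False)
    subs: dict[tuple[str, int], str] = {}
    for k, p in enumerate(picks):
        if k < n_lysine:
            name = "HYL" if rng.random() < hydroxylysine_fraction else "LYS"
        else:
            name = "ARG"
        subs[slots[p]] = name
    spec = HelixSpec(n_residues=n_residues, substitutions=subs)
    molecule, cell, _ = build_helix(spec, rng=rng, jitter=jitter)
    return molecule, cell


@dataclass
class SeriesSpec:
    """Specification of one synthetic energy trace (stationary AR(1))."""

    n_frames: int = DEFAULT_N_FRAMES
    dt: float = DEFAULT_DT
    mean: float = 0.0
    sd: float = DEFAULT_SD
    ar1_phi: float = 0.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise SyntheticSpecError("n_frames must be >= 2")
        if self.sd < 0:
            raise SyntheticSpecError("sd must be >= 0")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise SyntheticSpecError("ar1_phi must lie in [0, 1)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SeriesSpec":
        return cls(
            n_frames=int(d.get("n_frames", DEFAULT_N_FRAMES)),
            dt=float(d.get("dt", DEFAULT_DT)),
            mean=float(d.get("mean", 0.0)),
            sd=float(d.get("sd", DEFAULT_SD)),
            ar1_phi=float(d.get("ar1_phi", 0.0)),
            seed=int(d.get("seed", 0)),
            label=str(d.get("label", "")),
        )


def generate_energy_series(spec: SeriesSpec) -> EnergySeries:
    """e_t = mean + x_t with x_t = φ·x_{t−1} + ε_t, ε_t ~ N(0, sd·√(1−φ²)),
    started from the stationary distribution x_0 ~ N(0, sd). Bit-reproducible
    for a given seed."""
    rng = np.random.default_rng(spec.seed)
    times = np.arange(spec.n_frames) * spec.dt
    if spec.sd == 0:
        x = np.zeros(spec.n_frames)
    else:
        x0 = rng.normal(0.0, spec.sd)
        eps = rng.normal(
            0.0, spec.sd * np.sqrt(1.0 - spec.ar1_phi**2), spec.n_frames - 1
        )
        tail, _ = lfilter(
            [1.0], [1.0, -spec.ar1_phi], eps, zi=np.array([spec.ar1_phi * x0])
        )
        x = np.concatenate([[x0], tail])
    return EnergySeries(label=spec.label, times=times, energies=spec.mean + x)


@dataclass(frozen=True)
class Table1Row:
    """One row of the packaged 24-site reference table (dual numbering and
    the reported enthalpy change; sterically excluded rows carry no value)."""

    site_id: int
    lys_chain: str
    lys_uniprot: int
    lys_helical: int
    arg_chain: str
    arg_uniprot: int
    arg_helical: int
    delta_h: float | None
    excluded: bool


def make_table1_fixture() -> list[Table1Row]:
    """The 24 reference cross-link sites, verbatim from the packaged CSV."""
    with resources.files("glycolink").joinpath("data/table1.csv").open() as fh:
        frame = pd.read_csv(fh)
    rows = []
    for r in frame.itertuples(index=False):
        rows.append(
            Table1Row(
                site_id=int(r.site_id),
                lys_chain=str(r.lys_chain),
                lys_uniprot=int(r.lys_uniprot),
                lys_helical=int(r.lys_helical),
                arg_chain=str(r.arg_chain),
                arg_uniprot=int(r.arg_uniprot),
                arg_helical=int(r.arg_helical),
                delta_h=None if pd.isna(r.delta_h) else float(r.delta_h),
                excluded=bool(r.excluded),
            )
        )
    return rows
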