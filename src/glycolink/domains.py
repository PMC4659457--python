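"""Residue-numbering conversion and ECM binding-domain annotation.

Collagen residues are bookkept in two coordinate systems: the UniProt
precursor numbering used by structure files, and the triple-helical
numbering counted from the first helical residue. The two differ by a fixed
per-chain-type offset (one offset for the two alpha-1 copies, one for
alpha-2), which can be derived from any table of dual-numbered residues.

ECM interaction domains (heparin, decorin, integrins, MMP1, interleukin-2,
...) are named inclusive intervals in triple-helical coordinates. A
cross-link site is annotated as *overlapping* a domain when either of its
residues lies inside the interval, and *proximal* when it lies within a
small residue window of the interval without overlapping — the situation of
a cross-link "a couple of residues down" from a protease binding site.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .errors import OffsetConflictError, TelopeptideError, ValidationError
from .sites import CandidateSite

DEFAULT_PROXIMITY_WINDOW = 5  # residues

_CHAIN_TYPE = {"A1A": "A1", "A1B": "A1", "A2": "A2"}


@dataclass(frozen=True)
class ChainOffsets:
    """UniProt-minus-helical offsets; one per chain type (A1 covers both
    alpha-1 copies)."""

    offset_a1: int
    offset_a2: int

    def offset_for(self, chain_label: str) -> int:
        try:
            kind = _CHAIN_TYPE[chain_label]
        except KeyError:
            raise ValidationError(f"unknown chain label {chain_label!r}") from None
        return self.offset_a1 if kind == "A1" else self.offset_a2


def derive_offsets(table: Iterable[tuple[str, int, int]]) -> ChainOffsets:
    """Derive the per-chain-type offsets from (chain_type, uniprot, helical)
    triples; every triple of one chain type must agree."""
    offsets: dict[str, set[int]] = {"A1": set(), "A2": set()}
    rows: dict[str, list[tuple[int, int]]] = {"A1": [], "A2": []}
    for chain_type, uniprot, helical in table:
        kind = _CHAIN_TYPE.get(chain_type, chain_type)
        if kind not in offsets:
            raise ValidationError(f"unknown chain type {chain_type!r}")
        offsets[kind].add(uniprot - helical)
        rows[kind].append((uniprot, helical))
    for kind, vals in offsets.items():
        if len(vals) > 1:
            conflicts = ", ".join(f"{u}->{h}" for u, h in rows[kind])
            raise OffsetConflictError(
                f"chain type {kind} implies offsets {sorted(vals)}; rows: {conflicts}"
            )
    if not offsets["A1"] or not offsets["A2"]:
        missing = [k for k, v in offsets.items() if not v]
        raise ValidationError(f"no dual-numbered rows for chain type(s) {missing}")
    return ChainOffsets(
        offset_a1=offsets["A1"].pop(), offset_a2=offsets["A2"].pop()
    )


def helical_from_uniprot(
    chain_label: str, uniprot_index: int, offsets: ChainOffsets
) -> int:
    """Triple-helical index of a residue; residues before the helical domain
    raise :class:`TelopeptideError`."""
    h = uniprot_index - offsets.offset_for(chain_label)
    if h < 1:
        raise TelopeptideError(
            f"{chain_label}:{uniprot_index} lies outside the triple helix "
            f"(helical index {h})"
        )
    return h


@dataclass(frozen=True)
class BindingSiteInterval:
    """A named ECM interaction domain, inclusive in helical coordinates."""

    name: str
    chain_scope: str            # "A1", "A2" or "any"
    helical_start: int
    helical_end: int
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.helical_start <= self.helical_end:
            raise ValidationError(
                f"interval {self.name!r}: need 1 <= start <= end"
            )
        if self.chain_scope not in ("A1", "A2", "any"):
            raise ValidationError(
                f"interval {self.name!r}: chain_scope must be A1, A2 or any"
            )

    def applies_to(self, chain_label: str) -> bool:
        return self.chain_scope == "any" or self.chain_scope == _CHAIN_TYPE[chain_label]

    def contains(self, helical_index: int) -> bool:
        return self.helical_start <= helical_index <= self.helical_end

    def distance_to(self, helical_index: int) -> int:
        """0 inside the interval, else residue distance to its nearer edge."""
        if self.contains(helical_index):
            return 0
        return min(
            abs(helical_index - self.helical_start),
            abs(helical_index - self.helical_end),
        )


@dataclass(frozen=True)
class SiteAnnotation:
    site_id: int
    overlapping: tuple[str, ...]
    proximal: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.overlapping) & set(self.proximal):
            raise ValidationError("overlapping and proximal must be disjoint")


def annotate_site(
    site: CandidateSite,
    domain_map: Sequence[BindingSiteInterval],
    proximity_window: int = DEFAULT_PROXIMITY_WINDOW,
) -> SiteAnnotation:
    """Names of domains containing either cross-linked residue, and of
    domains within ``proximity_window`` residues without containing one."""
    refs = [site.lys_ref, site.arg_ref]
    for ref in refs:
        if ref.helical_index is None:
            raise ValidationError(
                f"site {site.site_id}: residue {ref.chain_label}:{ref.uniprot_index} "
                "has no helical index"
            )
    overlapping: list[str] = []
    proximal: list[str] = []
    for iv in domain_map:
        dists = [
            iv.distance_to(ref.helical_index)
            for ref in refs
            if iv.applies_to(ref.chain_label)
        ]
        if not dists:
            continue
        d = min(dists)
        if d == 0:
            if iv.name not in overlapping:
                overlapping.append(iv.name)
        elif d <= proximity_window:
            if iv.name not in proximal:
                proximal.append(iv.name)
    proximal = [n for n in proximal if n not in overlapping]
    return SiteAnnotation(
        site_id=site.site_id,
        overlapping=tuple(overlapping),
        proximal=tuple(proximal),
    )


DOMAIN_COLUMNS = ["name", "chain_scope", "helical_start", "helical_end", "source_tag"]


def read_domain_map(path_or_buffer) -> list[BindingSiteInterval]:
    """Read a tab-separated interval map (columns: name, chain_scope,
    helical_start, helical_end, source_tag; '#' comments)."""
    frame = pd.read_csv(
        path_or_buffer, sep="\t", comment="#", header=None, names=DOMAIN_COLUMNS,
        skip_blank_lines=True,
    )
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            BindingSiteInterval(
                name=str(row.name).strip(),
                chain_scope=str(row.chain_scope).strip(),
                helical_start=int(row.helical_start),
                helical_end=int(row.helical_end),
                source_tag="" if pd.isna(row.source_tag) else str(row.source_tag),
            )
        )
    return out


def packaged_domain_map() -> list[BindingSiteInterval]:
    """The packaged *synthetic* ECM domain fixture map.

    The published interaction-domain map is not reproduced here; this fixture
    encodes only qualitative containment — each named biomolecule gets an
    interval covering the favourable cross-link site(s) it is reported to
    overlap, and the MMP1 interval starts two residues past site 17's lysine
    so that it annotates as proximal rather than overlapping. Users with the
    real map should supply it in the same TSV format.
    """
    with resources.files("glycolink").joinpath("data/ecm_domains_synthetic.tsv").open() as fh:
        return read_domain_map(fh)


def annotations_to_frame(annotations: Sequence[SiteAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "site_id": a.site_id,
            "overlapping": "; ".join(a.overlapping),
            "proximal": "; ".join(a.proximal),
        }
        for a in annotations
    ]
    return pd.DataFrame(rows, columns=["site_id", "overlapping", "proximal"])
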