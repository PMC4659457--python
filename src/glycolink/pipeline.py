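"""End-to-end pipeline: search → steric screen → enthalpy → domain annotation.

The driver ties the stages together for a structure plus per-site energy
tables, and writes the full report bundle:

* ``sites.csv`` — candidate pairs with their criterion distances,
* ``contacts.csv`` — close contacts found by the periodic steric screen,
* ``enthalpy.csv`` — ΔH ± SEM and classification per site,
* ``annotated.csv`` — joined per-site report with ECM domain overlaps,
* ``distribution.tsv`` — helical position vs classification track (a
  site-distribution profile along the molecule),
* ``summary.json`` — classification counts and ΔH extremes.

Every candidate site lands in exactly one of {favourable, unfavourable,
excluded, no-data}: sterically severe sites are excluded (their energy files
are not read), sites without energy data are reported as "no-data" and the
pipeline continues.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import domains, energetics, sites, steric, structure
from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    structure_path: str
    chain_map: dict[str, str] = field(
        default_factory=lambda: {"A": "A1A", "B": "A1B", "C": "A2"}
    )
    cutoff: float = sites.DEFAULT_CUTOFF
    contact_threshold: float = steric.DEFAULT_CONTACT_THRESHOLD
    severe_threshold: float = steric.DEFAULT_SEVERE_THRESHOLD
    native_energy: str | None = None
    site_energies: dict[int, str] = field(default_factory=dict)
    window_last_ns: float = energetics.DEFAULT_WINDOW_LAST_NS
    sem_method: str = "naive"
    domain_map_path: str | None = None
    proximity_window: int = domains.DEFAULT_PROXIMITY_WINDOW
    offset_a1: int = 0
    offset_a2: int = 0
    helical_max: int | None = None
    out_dir: str = "glycolink_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("cutoff", "contact_threshold", "severe_threshold", "window_last_ns"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.proximity_window < 0:
            raise ValidationError("proximity_window must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        try:
            struct = raw["structure"]
        except KeyError:
            raise InputError("config needs a 'structure' path") from None
        energy = raw.get("energy", {})
        site_energies = {
            int(k): str(v) for k, v in (energy.get("sites") or {}).items()
        }
        steric_cfg = raw.get("steric", {})
        dom = raw.get("domains", {})
        offsets = raw.get("offsets", {})
        return cls(
            structure_path=str(struct),
            chain_map=dict(raw.get("chain_map", {"A": "A1A", "B": "A1B", "C": "A2"})),
            cutoff=float(raw.get("cutoff", sites.DEFAULT_CUTOFF)),
            contact_threshold=float(
                steric_cfg.get("contact_threshold", steric.DEFAULT_CONTACT_THRESHOLD)
            ),
            severe_threshold=float(
                steric_cfg.get("severe_threshold", steric.DEFAULT_SEVERE_THRESHOLD)
            ),
            native_energy=energy.get("native"),
            site_energies=site_energies,
            window_last_ns=float(
                energy.get("window_last_ns", energetics.DEFAULT_WINDOW_LAST_NS)
            ),
            sem_method=str(energy.get("sem_method", "naive")),
            domain_map_path=dom.get("map"),
            proximity_window=int(dom.get("proximity_window", domains.DEFAULT_PROXIMITY_WINDOW)),
            offset_a1=int(offsets.get("a1", 0)),
            offset_a2=int(offsets.get("a2", 0)),
            helical_max=raw.get("helical_max"),
            out_dir=str(raw.get("out_dir", "glycolink_out")),
            log_level=str(raw.get("log_level", "INFO")),
        )


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline computed."""

    molecule: structure.CollagenMolecule
    cell: structure.TriclinicCell | None
    candidate_sites: list[sites.CandidateSite]
    contact_reports: list[steric.ContactReport]
    enthalpies: list[energetics.EnthalpyResult]
    annotations: list[domains.SiteAnnotation]
    summary: energetics.EnthalpySummary


def classify_sites_from_energy(
    candidate_sites: list[sites.CandidateSite],
    severe_ids: set[int],
    native: energetics.EnergySeries | None,
    site_series: dict[int, energetics.EnergySeries],
    window_last_ns: float,
    sem_method: str = "naive",
) -> list[energetics.EnthalpyResult]:
    """Per-site enthalpy results: severe sites are excluded without touching
    their energy data; sites without a series are reported "no-data"."""
    results = []
    for site in candidate_sites:
        if site.site_id in severe_ids:
            results.append(energetics.excluded_result(site.site_id))
            continue
        series = site_series.get(site.site_id)
        if series is None or native is None:
            logger.warning("site %d: no energy data; reported as no-data", site.site_id)
            results.append(energetics.no_data_result(site.site_id))
            continue
        window = energetics.AnalysisWindow.last(series, window_last_ns)
        results.append(
            energetics.binding_enthalpy(
                series, native, window, site_id=site.site_id, sem_method=sem_method
            )
        )
    return results


def distribution_track(
    candidate_sites: list[sites.CandidateSite],
    enthalpies: list[energetics.EnthalpyResult],
):
    """Site-distribution profile along the molecule: one row per site with
    the helical positions of its two residues and the classification."""
    import pandas as pd

    cls = {r.site_id: r.classification for r in enthalpies}
    rows = [
        {
            "site_id": s.site_id,
            "lys_helical": s.lys_ref.helical_index,
            "arg_helical": s.arg_ref.helical_index,
            "classification": cls.get(s.site_id, energetics.NO_DATA),
        }
        for s in candidate_sites
    ]
    return pd.DataFrame(
        rows, columns=["site_id", "lys_helical", "arg_helical", "classification"]
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pdb_text = Path(config.structure_path).read_text()
    offsets = domains.ChainOffsets(config.offset_a1, config.offset_a2)
    molecule, cell = structure.read_structure(
        pdb_text, config.chain_map, offsets=offsets, helical_max=config.helical_max
    )
    logger.info("structure: %d residues, %d atoms, cell=%s",
                molecule.n_residues, molecule.n_atoms, cell)

    candidate_sites = sites.find_candidate_sites(molecule, cutoff=config.cutoff)
    logger.info("distance criterion: %d candidate site(s) at %.1f A",
                len(candidate_sites), config.cutoff)
    sites.sites_to_frame(candidate_sites).to_csv(out / "sites.csv", index=False)

    reports = [
        steric.screen_site(
            s, molecule, cell,
            contact_threshold=config.contact_threshold,
            severe_threshold=config.severe_threshold,
        )
        for s in candidate_sites
    ]
    severe_ids = {r.site_id for r in reports if r.severe}
    logger.info("steric screen: %d severe site(s) excluded", len(severe_ids))
    steric.contacts_to_frame(reports, config.severe_threshold).to_csv(
        out / "contacts.csv", index=False
    )

    native = None
    if config.native_energy:
        native = energetics.EnergySeries.from_table(config.native_energy, label="native")
    site_series = {
        sid: energetics.EnergySeries.from_table(path, label=f"site{sid:02d}")
        for sid, path in config.site_energies.items()
    }
    enthalpies = classify_sites_from_energy(
        candidate_sites, severe_ids, native, site_series,
        config.window_last_ns, config.sem_method,
    )
    energetics.results_to_frame(enthalpies).to_csv(out / "enthalpy.csv", index=False)

    if config.domain_map_path:
        domain_map = domains.read_domain_map(config.domain_map_path)
    else:
        domain_map = domains.packaged_domain_map()
    annotations = [
        domains.annotate_site(s, domain_map, config.proximity_window)
        for s in candidate_sites
    ]
    ann_frame = domains.annotations_to_frame(annotations)
    joined = sites.sites_to_frame(candidate_sites).merge(
        energetics.results_to_frame(enthalpies), on="site_id"
    ).merge(ann_frame, on="site_id")
    joined.to_csv(out / "annotated.csv", index=False)

    distribution_track(candidate_sites, enthalpies).to_csv(
        out / "distribution.tsv", sep="\t", index=False
    )

    summary = energetics.summarize(enthalpies)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
        fh.write("\n")
    logger.info(
        "summary: %d sites (%d favourable, %d unfavourable, %d excluded, %d no-data)",
        summary.n_sites, summary.n_favourable, summary.n_unfavourable,
        summary.n_excluded, summary.n_no_data,
    )
    return PipelineResult(
        molecule=molecule, cell=cell, candidate_sites=candidate_sites,
        contact_reports=reports, enthalpies=enthalpies,
        annotations=annotations, summary=summary,
    )


def plot_distribution(track, path) -> None:
    """Optional graphical rendering of the site-distribution track."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        energetics.FAVOURABLE: "tab:green",
        energetics.UNFAVOURABLE: "tab:red",
        energetics.EXCLUDED: "tab:gray",
        energetics.NO_DATA: "tab:blue",
    }
    fig, ax = plt.subplots(figsize=(8, 1.8))
    for row in track.itertuples(index=False):
        ax.axvline(row.lys_helical, color=colors.get(row.classification, "k"), lw=2)
    ax.set_xlabel("triple-helical position of lysine partner")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
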