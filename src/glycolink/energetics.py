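"""Binding-enthalpy analysis of cross-linked vs native energy time series.

A candidate site is evaluated thermodynamically by simulating the molecule
with the cross-link in place and comparing its mean total energy against a
matched native reference (unbound glucose, minus the four waters released by
the condensation). The binding enthalpy is

    ΔH = ⟨E_crosslinked⟩_w − ⟨E_native⟩_w

averaged over an analysis window w (default: the last 25 ns of a 60 ns
production run). A negative (exothermic) ΔH marks the site favourable;
ΔH ≥ 0 is unfavourable; sites rejected by the steric screen are "excluded"
and carry no ΔH.

Uncertainty is reported as a standard error of the mean. The naive SEM
(sd/√n over window frames) matches the headline statistic; block averaging
(sd of k block means /√k) is available for autocorrelated series, where the
naive estimate is known to be optimistic. The SEM of ΔH combines the two
series' SEMs in quadrature.

"Total energy" is whatever the input column contains — the analysis is
agnostic to whether the user logged potential or potential+kinetic energy,
as long as both series report the same quantity.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyWindowError, SeriesMismatchError, ValidationError

FAVOURABLE = "favourable"
UNFAVOURABLE = "unfavourable"
EXCLUDED = "excluded"
NO_DATA = "no-data"

DEFAULT_WINDOW_LAST_NS = 25.0
DEFAULT_BLOCKS = 5

_SPACING_RTOL = 1e-9


@dataclass
class EnergySeries:
    """A uniformly sampled total-energy trace (times in ns, energy kcal/mol)."""

    label: str
    times: np.ndarray
    energies: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.energies.shape:
            raise ValidationError("times and energies must be 1-D and equal length")
        if len(self.times) < 2:
            raise ValidationError("an energy series needs at least 2 frames")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=_SPACING_RTOL, atol=0.0):
            raise ValidationError("frame spacing must be uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    @classmethod
    def from_table(cls, text_or_path, label: str = "") -> "EnergySeries":
        """Read the canonical plain two-column table (time_ns, energy_kcal_mol;
        '#' comments)."""
        data = np.loadtxt(text_or_path, comments="#", ndmin=2)
        if data.shape[1] < 2:
            raise ValidationError("energy table needs two columns: time, energy")
        return cls(label=label, times=data[:, 0], energies=data[:, 1])

    def to_table(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.energies]),
            header="time_ns  energy_kcal_mol",
            fmt="%.6f %.6f",
        )


_MDOUT_TIME = re.compile(r"TIME\(PS\)\s*=\s*([-\d.]+)")
_MDOUT_ETOT = re.compile(r"Etot\s*=\s*([-\d.eE+]+)")


def read_amber_mdout(text_or_path, label: str = "") -> EnergySeries:
    """Optional importer for AMBER-style mdout energy records.

    Pairs each ``TIME(PS)`` with the following ``Etot`` value; times are
    converted from ps to ns. The plain two-column table remains canonical.
    """
    if hasattr(text_or_path, "read"):
        text = text_or_path.read()
    else:
        try:
            with open(text_or_path) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = str(text_or_path)
    times, energies = [], []
    pending_time = None
    for line in text.splitlines():
        m = _MDOUT_TIME.search(line)
        if m:
            pending_time = float(m.group(1)) / 1000.0
            continue
        m = _MDOUT_ETOT.search(line)
        if m and pending_time is not None:
            times.append(pending_time)
            energies.append(float(m.group(1)))
            pending_time = None
    if len(times) < 2:
        raise ValidationError("mdout text yielded fewer than 2 energy records")
    return EnergySeries(label=label, times=np.array(times), energies=np.array(energies))


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time window [t_start, t_end) in ns."""

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValidationError("window requires t_start < t_end")

    @classmethod
    def last(cls, series: EnergySeries, duration_ns: float = DEFAULT_WINDOW_LAST_NS) -> "AnalysisWindow":
        """The final ``duration_ns`` of a series (half-open, so the last frame
        is included by extending the end one spacing past it)."""
        end = series.t_end + series.dt
        return cls(t_start=end - duration_ns, t_end=end)

    def mask(self, series: EnergySeries) -> np.ndarray:
        return (series.times >= self.t_start) & (series.times < self.t_end)


@dataclass
class EnthalpyResult:
    """ΔH ± SEM for one site, with the window used and its classification."""

    site_id: int
    delta_h: float | None
    sem: float | None
    window: AnalysisWindow | None
    n_frames_used: int
    classification: str

    def __post_init__(self) -> None:
        if self.sem is not None and self.sem < 0:
            raise ValidationError("sem must be >= 0")
        if self.classification not in (FAVOURABLE, UNFAVOURABLE, EXCLUDED, NO_DATA):
            raise ValidationError(f"unknown classification {self.classification!r}")
        if self.classification != EXCLUDED and self.delta_h is not None:
            if (self.delta_h < 0) != (self.classification == FAVOURABLE):
                raise ValidationError("classification inconsistent with delta_h sign")


def _window_values(series: EnergySeries, window: AnalysisWindow) -> np.ndarray:
    vals = series.energies[window.mask(series)]
    if len(vals) < 2:
        raise EmptyWindowError(
            f"window [{window.t_start}, {window.t_end}) holds {len(vals)} frame(s) "
            f"of series {series.label!r}; need at least 2"
        )
    return vals


def window_mean(series: EnergySeries, window: AnalysisWindow) -> float:
    """Arithmetic mean of the energies with times in the half-open window."""
    return float(np.mean(_window_values(series, window)))


def sem_estimate(
    series: EnergySeries,
    window: AnalysisWindow,
    method: str = "naive",
    n_blocks: int = DEFAULT_BLOCKS,
) -> float:
    """Standard error of the window mean.

    ``naive``: sd/√n over the window frames (unbiased for iid noise, an
    underestimate when frames are autocorrelated). ``block``: the frames are
    cut into ``n_blocks`` contiguous equal blocks (trailing remainder
    dropped) and the SEM is the sd of the block means over √k.
    """
    vals = _window_values(series, window)
    if method == "naive":
        return float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
    if method == "block":
        if n_blocks < 2:
            raise ValidationError("block SEM needs at least 2 blocks")
        m = len(vals) // n_blocks
        if m < 1:
            raise EmptyWindowError(
                f"{len(vals)} frames cannot fill {n_blocks} blocks"
            )
        means = vals[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
        return float(np.std(means, ddof=1) / np.sqrt(n_blocks))
    raise ValidationError(f"unknown SEM method {method!r}")


def classify(delta_h: float | None, excluded: bool = False) -> str:
    """Excluded sites stay excluded; otherwise exothermic (ΔH < 0) is
    favourable and ΔH ≥ 0 (including exactly zero) unfavourable."""
    if excluded:
        return EXCLUDED
    if delta_h is None:
        return NO_DATA
    return FAVOURABLE if delta_h < 0 else UNFAVOURABLE


def binding_enthalpy(
    crosslinked: EnergySeries,
    native: EnergySeries,
    window: AnalysisWindow,
    site_id: int = 0,
    sem_method: str = "naive",
    n_blocks: int = DEFAULT_BLOCKS,
) -> EnthalpyResult:
    """ΔH = mean(crosslinked) − mean(native) over the window, with SEM
    combined in quadrature from the two series."""
    if not np.isclose(crosslinked.dt, native.dt, rtol=_SPACING_RTOL):
        raise SeriesMismatchError(
            f"frame spacing differs: {crosslinked.dt} vs {native.dt} ns"
        )
    mean_x = window_mean(crosslinked, window)
    mean_0 = window_mean(native, window)
    sem_x = sem_estimate(crosslinked, window, method=sem_method, n_blocks=n_blocks)
    sem_0 = sem_estimate(native, window, method=sem_method, n_blocks=n_blocks)
    delta = mean_x - mean_0
    return EnthalpyResult(
        site_id=site_id,
        delta_h=delta,
        sem=float(np.hypot(sem_x, sem_0)),
        window=window,
        n_frames_used=int(window.mask(crosslinked).sum()),
        classification=classify(delta),
    )


def excluded_result(site_id: int) -> EnthalpyResult:
    """Placeholder result for a site rejected by the steric screen."""
    return EnthalpyResult(
        site_id=site_id, delta_h=None, sem=None, window=None,
        n_frames_used=0, classification=EXCLUDED,
    )


def no_data_result(site_id: int) -> EnthalpyResult:
    """Placeholder for a site with no energy series supplied."""
    return EnthalpyResult(
        site_id=site_id, delta_h=None, sem=None, window=None,
        n_frames_used=0, classification=NO_DATA,
    )


def convergence_time(
    series: EnergySeries,
    slope_tol: float,
    window_len: float,
) -> float | None:
    """Earliest time t with |least-squares slope| ≤ ``slope_tol`` over
    [t, t + window_len]; ``None`` if the series never settles.

    Scans every frame as a window start, using closed-form rolling sums.
    """
    if slope_tol < 0 or window_len <= 0:
        raise ValidationError("slope_tol must be >= 0 and window_len > 0")
    m = int(round(window_len / series.dt)) + 1
    n = len(series.times)
    if m < 2 or m > n:
        raise ValidationError("window_len must fit inside the series")
    t, e = series.times, series.energies
    # rolling sums via cumulative sums
    def roll(x: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0.0], np.cumsum(x)])
        return c[m:] - c[:-m]

    st, se = roll(t), roll(e)
    stt, ste = roll(t * t), roll(t * e)
    denom = m * stt - st * st
    slope = (m * ste - st * se) / denom
    ok = np.abs(slope) <= slope_tol
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        return None
    return float(t[idx[0]])


@dataclass
class EnthalpySummary:
    """Classification counts and ΔH extremes over a set of site results."""

    n_sites: int
    n_favourable: int
    n_unfavourable: int
    n_excluded: int
    n_no_data: int
    min_delta_h: float | None
    min_site_id: int | None
    max_delta_h: float | None
    max_site_id: int | None

    @property
    def n_not_favourable(self) -> int:
        """Unfavourable plus excluded — the complement of the favourable
        count among evaluated sites (the convention used when the sterically
        excluded sites are counted with the endothermic ones)."""
        return self.n_unfavourable + self.n_excluded

    def to_dict(self) -> dict:
        d = {
            "n_sites": self.n_sites,
            "n_favourable": self.n_favourable,
            "n_unfavourable": self.n_unfavourable,
            "n_excluded": self.n_excluded,
            "n_no_data": self.n_no_data,
            "n_not_favourable": self.n_not_favourable,
            "min_delta_h": self.min_delta_h,
            "min_site_id": self.min_site_id,
            "max_delta_h": self.max_delta_h,
            "max_site_id": self.max_site_id,
        }
        return d


def summarize(results: Sequence[EnthalpyResult]) -> EnthalpySummary:
    """Counts by classification and the extreme ΔH values with their sites."""
    valued = [r for r in results if r.delta_h is not None]
    min_r = min(valued, key=lambda r: r.delta_h, default=None)
    max_r = max(valued, key=lambda r: r.delta_h, default=None)
    return EnthalpySummary(
        n_sites=len(results),
        n_favourable=sum(r.classification == FAVOURABLE for r in results),
        n_unfavourable=sum(r.classification == UNFAVOURABLE for r in results),
        n_excluded=sum(r.classification == EXCLUDED for r in results),
        n_no_data=sum(r.classification == NO_DATA for r in results),
        min_delta_h=None if min_r is None else float(min_r.delta_h),
        min_site_id=None if min_r is None else min_r.site_id,
        max_delta_h=None if max_r is None else float(max_r.delta_h),
        max_site_id=None if max_r is None else max_r.site_id,
    )


def results_to_frame(results: Sequence[EnthalpyResult]) -> pd.DataFrame:
    rows = [
        {
            "site_id": r.site_id,
            "delta_h": np.nan if r.delta_h is None else round(r.delta_h, 3),
            "sem": np.nan if r.sem is None else round(r.sem, 3),
            "n_frames": r.n_frames_used,
            "classification": r.classification,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["site_id", "delta_h", "sem", "n_frames", "classification"]
    )


def format_table(results: Sequence[EnthalpyResult]) -> str:
    """Plain-text report in the style of a per-site enthalpy table
    (ΔH to 3 decimals; excluded sites dashed)."""
    buf = io.StringIO()
    buf.write(f"{'site':>4s}  {'dH (kcal/mol)':>14s}  {'SEM':>6s}  classification\n")
    for r in results:
        dh = "-" if r.delta_h is None else f"{r.delta_h:+.3f}"
        sem = "-" if r.sem is None else f"{r.sem:.3f}"
        buf.write(f"{r.site_id:>4d}  {dh:>14s}  {sem:>6s}  {r.classification}\n")
    return buf.getvalue()
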