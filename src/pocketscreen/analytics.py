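"""Colony-formation screening statistics and dose-response fitting.

Implements the wet-lab side of the screening pipeline:

* percent-of-control colony formation for a treated condition,
* the efficacy ratio — (percent of remaining cancer-cell colonies) /
  (percent of remaining bone-marrow colonies) at a fixed concentration,
  with values below 0.5 classed as active and at least partially selective,
* per-compound relative activity (% of tested cell lines active) and
  per-protein-site summaries (percent of active compounds, pooled
  mean +/- SEM of the sub-cutoff ratios, activity range),
* bone-marrow toxicity flags (compounds inhibiting stem-cell colony
  formation by more than 10% / 30%),
* four-parameter logistic (4PL) dose-response fitting for IC50s.

Table conventions: efficacy ratios print to 2 decimals and percentages to
integers with half-up rounding, but activity classification always uses
the unrounded values.  Missing table entries ("-" cells) are first-class:
they are excluded from numerators and denominators, never treated as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitConvergenceError, ValidationError

__all__ = [
    "ColonyAssayRecord",
    "EfficacyTable",
    "DoseResponseFit",
    "SiteSummary",
    "percent_of_control",
    "efficacy_ratio",
    "classify_active",
    "relative_activity",
    "site_summary",
    "marrow_toxicity_flags",
    "fit_4pl",
    "site_of_compound",
    "efficacy_table_from_assays",
    "round_half_up",
]

ACTIVITY_CUTOFF = 0.5


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with halves away from zero (0.5 -> 1), as printed tables do."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def site_of_compound(compound_id: str) -> str:
    """Protein-site prefix of a compound id (``Dxr2-017`` -> ``Dxr2``)."""
    return compound_id.split("-", 1)[0]


@dataclass(frozen=True)
class ColonyAssayRecord:
    """Replicate colony counts for one (cell line, compound, dose, day)."""

    cell_line: str
    compound: str
    concentration: float  # uM; 0 = vehicle control
    replicate_counts: tuple[int, ...]
    day: int = 8

    def __post_init__(self) -> None:
        if not self.replicate_counts:
            raise ValidationError("at least one replicate count is required")
        if any(c < 0 for c in self.replicate_counts):
            raise ValidationError("colony counts must be non-negative")
        if self.concentration < 0:
            raise ValidationError("concentration must be >= 0")

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.replicate_counts))


@dataclass
class EfficacyTable:
    """Compound x cell-line efficacy ratios at one concentration.

    ``ratios`` is a DataFrame (rows = cell lines, columns = compounds) with
    NaN for entries that were not tested.  ``site_of`` maps every *tested*
    compound (including ones with no active line, which may be absent from
    ``ratios``) to its protein site, so site denominators are complete.
    """

    concentration: float
    ratios: pd.DataFrame
    site_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.ratios.fillna(0.0).to_numpy()).all():
            raise ValidationError("efficacy ratios must be finite or missing")
        if (self.ratios.fillna(0.0).to_numpy() < 0).any():
            raise ValidationError("efficacy ratios must be non-negative")
        for compound in self.ratios.columns:
            if compound not in self.site_of:
                self.site_of[compound] = site_of_compound(compound)

    @property
    def compounds(self) -> list[str]:
        return list(self.ratios.columns)

    def tested_pairs(self) -> list[tuple[str, str]]:
        out = []
        for compound in self.ratios.columns:
            for cell_line in self.ratios.index:
                if not pd.isna(self.ratios.at[cell_line, compound]):
                    out.append((compound, cell_line))
        return out


@dataclass
class SiteSummary:
    site: str
    n_compounds_tested: int
    n_compounds_active: int
    pct_active_compounds: float
    pooled_mean: float | None
    pooled_sem: float | None
    pooled_n: int
    activity_range: tuple[int, int] | None


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    log_ic50: float
    hill: float
    ic50: float
    residual_norm: float
    n_points: int
    covariance: np.ndarray | None = None


def percent_of_control(
    treated: ColonyAssayRecord, control: ColonyAssayRecord
) -> float:
    """Mean treated colonies as a percentage of mean control colonies."""
    if treated.cell_line != control.cell_line or treated.day != control.day:
        raise ValidationError(
            "treated and control records must share cell line and day"
        )
    if control.mean_count <= 0:
        raise ValidationError(
            f"control mean for {control.cell_line} day {control.day} is zero"
        )
    return 100.0 * treated.mean_count / control.mean_count


def efficacy_ratio(cancer_pct: float, marrow_pct: float) -> float:
    """(percent remaining cancer colonies) / (percent remaining marrow colonies)."""
    if marrow_pct <= 0:
        raise ValidationError("efficacy ratio undefined: marrow percent is zero")
    if cancer_pct < 0:
        raise ValidationError("cancer percent must be >= 0")
    return cancer_pct / marrow_pct


def classify_active(
    table: EfficacyTable, cutoff: float = ACTIVITY_CUTOFF
) -> dict[tuple[str, str], bool]:
    """(compound, cell_line) -> ratio < cutoff; missing entries excluded."""
    out: dict[tuple[str, str], bool] = {}
    for compound, cell_line in table.tested_pairs():
        out[(compound, cell_line)] = bool(
            table.ratios.at[cell_line, compound] < cutoff
        )
    return out


def relative_activity(
    table: EfficacyTable, compound: str, cutoff: float = ACTIVITY_CUTOFF
) -> int:
    """Percent of tested cell lines with ratio < cutoff (half-up integer)."""
    if compound not in table.ratios.columns:
        raise ValidationError(f"compound {compound!r} not in table")
    col = table.ratios[compound].dropna()
    if col.empty:
        raise ValidationError(f"compound {compound!r} has no tested cell lines")
    active = int((col < cutoff).sum())
    return int(round_half_up(100.0 * active / len(col)))


def _sub_cutoff_ratios(
    table: EfficacyTable, compound: str, cutoff: float
) -> np.ndarray:
    col = table.ratios[compound].dropna()
    return col[col < cutoff].to_numpy()


def site_summary(
    table: EfficacyTable, cutoff: float = ACTIVITY_CUTOFF
) -> dict[str, SiteSummary]:
    """Per-site roll-up of compound activity.

    A compound is active if it has at least one sub-cutoff cell line.  The
    pooled mean/SEM run over *all* sub-cutoff ratios of a site's active
    compounds (sample SEM, n-1 denominator; a single pooled value reports
    SEM 0.0).  ``activity_range`` is the min-max of relative activity over
    the active compounds.  Sites whose compounds are all inactive report
    empty summary fields.
    """
    by_site: dict[str, list[str]] = {}
    for compound, site in table.site_of.items():
        by_site.setdefault(site, []).append(compound)

    out: dict[str, SiteSummary] = {}
    for site in sorted(by_site):
        compounds = sorted(by_site[site])
        if not compounds:
            continue
        active_compounds = []
        pooled: list[float] = []
        activities: list[int] = []
        for compound in compounds:
            if compound not in table.ratios.columns:
                continue  # tested, but no line reached the table: inactive
            sub = _sub_cutoff_ratios(table, compound, cutoff)
            if sub.size:
                active_compounds.append(compound)
                pooled.extend(sub.tolist())
                activities.append(relative_activity(table, compound, cutoff))
        n_tested = len(compounds)
        n_active = len(active_compounds)
        pct_active = round_half_up(100.0 * n_active / n_tested)
        if pooled:
            arr = np.asarray(pooled)
            mean = float(arr.mean())
            sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
            arange = (min(activities), max(activities))
        else:
            mean = sem = None
            arange = None
        out[site] = SiteSummary(
            site=site,
            n_compounds_tested=n_tested,
            n_compounds_active=n_active,
            pct_active_compounds=pct_active,
            pooled_mean=mean,
            pooled_sem=sem,
            pooled_n=len(pooled),
            activity_range=arange,
        )
    return out


def pooled_compound_stats(
    table: EfficacyTable, compound: str, cutoff: float = ACTIVITY_CUTOFF
) -> tuple[float, float, int]:
    """(mean, SEM, n) of one compound's sub-cutoff ratios."""
    sub = _sub_cutoff_ratios(table, compound, cutoff)
    if sub.size == 0:
        raise ValidationError(f"{compound!r} has no sub-cutoff cell lines")
    sem = float(sub.std(ddof=1) / np.sqrt(sub.size)) if sub.size > 1 else 0.0
    return float(sub.mean()), sem, int(sub.size)


def marrow_toxicity_flags(
    day8_pct: Mapping[str, float],
    thresholds: tuple[float, float] = (10.0, 30.0),
) -> tuple[int, int, list[str]]:
    """Count compounds inhibiting marrow colony formation beyond thresholds.

    ``day8_pct`` maps compound -> percent-of-control at 8 days; inhibition
    is 100 - percent, compared strictly against each threshold.  Returns
    (count over low, count over high, sorted ids over the low threshold).
    """
    if not day8_pct:
        raise ValidationError("no compounds supplied")
    low, high = thresholds
    flagged = sorted(c for c, pct in day8_pct.items() if 100.0 - pct > low)
    over_high = sum(1 for pct in day8_pct.values() if 100.0 - pct > high)
    return len(flagged), over_high, flagged


def _four_pl(log_x: np.ndarray, bottom: float, top: float, log_ic50: float, hill: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - log_x) * hill))


def fit_4pl(
    doses: Sequence[float],
    responses: Sequence[float],
    *,
    max_iterations: int = 10000,
) -> DoseResponseFit:
    """Least-squares four-parameter logistic fit of percent-of-control data.

    Model: y = bottom + (top - bottom) / (1 + 10^((log10 IC50 - log10 x) * hill)).
    Doses are log-transformed; zero-dose controls are the normalization
    denominator upstream and are excluded here (log 0 undefined).
    Initialization comes from the data quartiles.  Non-convergence raises
    :class:`FitConvergenceError` with diagnostics — never a silent failure.
    """
    doses = np.asarray(doses, float)
    responses = np.asarray(responses, float)
    if doses.shape != responses.shape:
        raise ValidationError("doses and responses must have equal length")
    if not np.all(np.isfinite(responses)):
        raise ValidationError("responses must be finite")
    mask = doses > 0
    x = doses[mask]
    y = responses[mask]
    if len(np.unique(x)) < 4:
        raise ValidationError(
            f"need >= 4 distinct positive dose levels, got {len(np.unique(x))}"
        )
    if np.ptp(y) < 1e-6:
        raise FitConvergenceError(
            "responses are flat; no dose-response to fit",
            details={"response_range": float(np.ptp(y))},
        )
    log_x = np.log10(x)
    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    # initial log-IC50: dose whose response is nearest the half-way point
    half = 0.5 * (y_lo + y_hi)
    log_ic50_0 = float(log_x[np.argmin(np.abs(y - half))])
    # hill sign from the overall trend of response vs log dose
    trend = np.polyfit(log_x, y, 1)[0]
    hill_0 = -1.0 if trend < 0 else 1.0
    p0 = (y_lo, y_hi, log_ic50_0, hill_0)
    try:
        popt, pcov = curve_fit(
            _four_pl, log_x, y, p0=p0, maxfev=max_iterations, method="lm"
        )
    except RuntimeError as exc:
        residuals = y - _four_pl(log_x, *p0)
        raise FitConvergenceError(
            f"4PL fit did not converge: {exc}",
            details={"p0": p0, "residuals": residuals.tolist()},
        ) from exc
    bottom, top, log_ic50, hill = (float(v) for v in popt)
    if bottom > top:
        # the two asymptotes are exchangeable with a sign flip of hill
        bottom, top, hill = top, bottom, -hill
    residual = float(np.linalg.norm(y - _four_pl(log_x, *popt)))
    return DoseResponseFit(
        bottom=bottom,
        top=top,
        log_ic50=log_ic50,
        hill=hill,
        ic50=10.0**log_ic50,
        residual_norm=residual,
        n_points=int(mask.sum()),
        covariance=pcov,
    )


def efficacy_table_from_assays(
    records: Iterable[ColonyAssayRecord],
    marrow_line: str,
    concentration: float,
    day: int = 8,
) -> EfficacyTable:
    """Build an efficacy table from raw colony assay records.

    For every compound, percent-of-control is computed per cell line at the
    requested concentration and day, then divided by the marrow line's
    percent-of-control for the same compound.
    """
    records = list(records)
    controls: dict[tuple[str, int], ColonyAssayRecord] = {}
    for r in records:
        if r.concentration == 0:
            controls[(r.cell_line, r.day)] = r
    pct: dict[tuple[str, str], float] = {}
    compounds: set[str] = set()
    for r in records:
        if r.concentration != concentration or r.day != day:
            continue
        control = controls.get((r.cell_line, r.day))
        if control is None:
            raise ValidationError(
                f"no vehicle control for ({r.cell_line}, day {r.day})"
            )
        pct[(r.compound, r.cell_line)] = percent_of_control(r, control)
        compounds.add(r.compound)

    cell_lines = sorted({cl for (_, cl) in pct} - {marrow_line})
    data: dict[str, list[float]] = {}
    for compound in sorted(compounds):
        marrow = pct.get((compound, marrow_line))
        if marrow is None:
            raise ValidationError(
                f"compound {compound!r} lacks a {marrow_line} measurement"
            )
        col = []
        for cl in cell_lines:
            cancer = pct.get((compound, cl))
            col.append(
                np.nan if cancer is None else efficacy_ratio(cancer, marrow)
            )
        data[compound] = col
    ratios = pd.DataFrame(data, index=cell_lines)
    return EfficacyTable(concentration=concentration, ratios=ratios)
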