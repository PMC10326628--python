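"""Internal-standard relative quantification of amino acids.

Seven amino acids are quantified from each preprocessed spectrum by the
intensity of their characteristic Raman peak relative to the
phenylalanine ring-breathing internal standard at 1003 cm^-1:

    quantitative ratio = log10(I_target / I_standard)

Ratioing against an in-spectrum standard cancels acquisition-scale
effects (laser power, focus, normalization), so the ratio is invariant
under any positive rescaling of the spectrum.  Group differences
(pregnancy vs non-pregnancy) are assessed per analyte with a two-sided
Mann-Whitney U test by default (Welch's t-test optionally), tiered
``**`` (p<0.01), ``*`` (p<0.05) or ``ns``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ramanomics.spectra_io import Spectrum

logger = logging.getLogger(__name__)


class AssignmentError(ValueError):
    """Peak window does not intersect the spectrum axis."""


class UndefinedRatioError(ValueError):
    """Ratio requested for a non-positive peak intensity."""


class InsufficientDataError(ValueError):
    """Too few observations in a group for a comparison."""


@dataclass(frozen=True)
class PeakAssignment:
    """Maps a Raman shift position to an analyte and vibration mode."""

    position: float  # cm^-1
    analyte: str
    vibration_mode: str
    window_halfwidth: float = 5.0

    def __post_init__(self):
        if self.window_halfwidth <= 0:
            raise ValueError("window_halfwidth must be positive")
        if not (600.0 <= self.position <= 1800.0):
            raise ValueError(
                f"peak position {self.position} outside fingerprint band [600, 1800]")


#: Characteristic peaks used for quantification: seven amino acids plus
#: the phenylalanine internal standard.
QUANT_CATALOG: tuple[PeakAssignment, ...] = (
    PeakAssignment(941.0, "aspartic_acid", "C-H bending"),
    PeakAssignment(900.0, "glycine", "COOH scissoring / C-C stretch"),
    PeakAssignment(758.0, "tryptophan", "aromatic C-H / C-C-C bending"),
    PeakAssignment(853.0, "tyrosine", "aromatic C-H / C-C-C bending"),
    PeakAssignment(1032.0, "taurine", "S=O stretching"),
    PeakAssignment(1326.0, "serine", "C-N stretching"),
    PeakAssignment(828.0, "proline", "aromatic C-H / C-C-C bending"),
)

#: Phenylalanine ring symmetric breathing mode — the internal standard.
INTERNAL_STANDARD = PeakAssignment(1003.0, "phenylalanine", "ring symmetric breathing")

QUANT_ANALYTES: tuple[str, ...] = tuple(a.analyte for a in QUANT_CATALOG)


@dataclass(frozen=True)
class PeakMeasurement:
    """Paired target / internal-standard peak intensities for one spectrum."""

    I_target: float
    I_standard: float
    analyte: str
    spectrum_id: str


@dataclass(frozen=True)
class QuantRatio:
    analyte: str
    spectrum_id: str
    ratio: float


@dataclass(frozen=True)
class GroupComparison:
    analyte: str
    median_pregnancy: float
    median_non_pregnancy: float
    mean_pregnancy: float
    mean_non_pregnancy: float
    statistic: float
    p_value: float
    tier: str          # "ns", "*", "**"
    direction: int     # sign of (non_pregnancy - pregnancy) median difference


def peak_intensity(spectrum: Spectrum, assignment: PeakAssignment) -> float:
    """Maximum intensity within ``position +/- window_halfwidth``.

    A non-positive result is returned as-is; callers flag such spectra
    for exclusion from ratio formation.
    """
    lo = assignment.position - assignment.window_halfwidth
    hi = assignment.position + assignment.window_halfwidth
    mask = (spectrum.shifts >= lo) & (spectrum.shifts <= hi)
    if not mask.any():
        raise AssignmentError(
            f"window [{lo:g}, {hi:g}] for {assignment.analyte} does not "
            f"intersect axis [{spectrum.shifts[0]:g}, {spectrum.shifts[-1]:g}]")
    return float(spectrum.intensities[mask].max())


def quant_ratio(measurement: PeakMeasurement, log_base: float = 10.0) -> QuantRatio:
    """Eq.-style internal-standard ratio: log(I_target / I_standard).

    Base 10 by default, so one unit of ratio is a decade of relative
    intensity.
    """
    if measurement.I_target <= 0 or measurement.I_standard <= 0:
        raise UndefinedRatioError(
            f"non-positive intensity for {measurement.analyte} in "
            f"{measurement.spectrum_id}: I_target={measurement.I_target}, "
            f"I_standard={measurement.I_standard}")
    value = math.log(measurement.I_target / measurement.I_standard, log_base)
    return QuantRatio(measurement.analyte, measurement.spectrum_id, value)


def quant_table(spectra: list[Spectrum],
                catalog: tuple[PeakAssignment, ...] = QUANT_CATALOG,
                standard: PeakAssignment = INTERNAL_STANDARD,
                log_base: float = 10.0) -> pd.DataFrame:
    """Quantify every catalog analyte in every spectrum.

    Returns a long-format table with one row per (spectrum, analyte):
    columns ``spectrum_id, sample_id, label, analyte, I_target,
    I_standard, ratio``.  Spectra whose target or standard intensity is
    non-positive are omitted from the table and logged.
    """
    rows = []
    for s in spectra:
        i_std = peak_intensity(s, standard)
        if i_std <= 0:
            logger.warning("spectrum %s: non-positive internal-standard intensity; skipped",
                           s.spectrum_id)
            continue
        for assignment in catalog:
            i_t = peak_intensity(s, assignment)
            if i_t <= 0:
                logger.warning("spectrum %s: non-positive %s intensity; skipped",
                               s.spectrum_id, assignment.analyte)
                continue
            r = quant_ratio(PeakMeasurement(i_t, i_std, assignment.analyte, s.spectrum_id),
                            log_base=log_base)
            rows.append({
                "spectrum_id": s.spectrum_id,
                "sample_id": s.sample_id,
                "label": s.label,
                "analyte": r.analyte,
                "I_target": i_t,
                "I_standard": i_std,
                "ratio": r.ratio,
            })
    return pd.DataFrame(rows, columns=["spectrum_id", "sample_id", "label",
                                       "analyte", "I_target", "I_standard", "ratio"])


def _tier(p: float, alpha_levels: tuple[float, float]) -> str:
    weak, strong = max(alpha_levels), min(alpha_levels)
    if p < strong:
        return "**"
    if p < weak:
        return "*"
    return "ns"


def compare_groups(table: pd.DataFrame,
                   manifest: pd.DataFrame | None = None,
                   alpha_levels: tuple[float, float] = (0.05, 0.01),
                   test: str = "mannwhitney",
                   per_sample: bool = False) -> list[GroupComparison]:
    """Per-analyte two-group comparison of quantitative ratios.

    Parameters
    ----------
    table : DataFrame
        Output of :func:`quant_table`.  If its ``label`` column is empty,
        labels are joined from ``manifest`` on ``sample_id``.
    alpha_levels : (float, float)
        Significance thresholds for the ``*`` and ``**`` tiers.
    test : {"mannwhitney", "welch"}
        Rank test by default; Welch's unequal-variance t-test optionally.
    per_sample : bool
        When True, replicate spectra of a sample are first collapsed to
        the sample median, so observations are independent samples
        rather than (correlated) individual spectra.
    """
    df = table.copy()
    if df["label"].isna().all():
        if manifest is None:
            raise ValueError("table has no labels and no manifest given")
        labels = manifest.drop_duplicates("sample_id").set_index("sample_id")["label"]
        df["label"] = df["sample_id"].map(labels)
    df = df.dropna(subset=["label"])
    if per_sample:
        df = (df.groupby(["sample_id", "label", "analyte"], as_index=False)["ratio"]
                .median())
    results = []
    for analyte, sub in df.groupby("analyte", sort=False):
        preg = sub.loc[sub["label"] == "pregnancy", "ratio"].to_numpy()
        nonpreg = sub.loc[sub["label"] == "non_pregnancy", "ratio"].to_numpy()
        if len(preg) < 3 or len(nonpreg) < 3:
            raise InsufficientDataError(
                f"{analyte}: need >=3 observations per group "
                f"(got {len(preg)} pregnancy, {len(nonpreg)} non-pregnancy)")
        if np.array_equal(np.sort(preg), np.sort(nonpreg)):
            stat, p = 0.0, 1.0  # identical groups: no evidence by construction
        elif test == "mannwhitney":
            stat, p = stats.mannwhitneyu(nonpreg, preg, alternative="two-sided")
        elif test == "welch":
            stat, p = stats.ttest_ind(nonpreg, preg, equal_var=False)
        else:
            raise ValueError(f"unknown test {test!r}")
        diff = float(np.median(nonpreg) - np.median(preg))
        results.append(GroupComparison(
            analyte=analyte,
            median_pregnancy=float(np.median(preg)),
            median_non_pregnancy=float(np.median(nonpreg)),
            mean_pregnancy=float(np.mean(preg)),
            mean_non_pregnancy=float(np.mean(nonpreg)),
            statistic=float(stat),
            p_value=float(p),
            tier=_tier(float(p), alpha_levels),
            direction=int(np.sign(diff)),
        ))
    return results


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Tabulate GroupComparison results for reporting."""
    return pd.DataFrame([vars(c) for c in comparisons])
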