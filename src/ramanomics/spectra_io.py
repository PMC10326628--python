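"""Spectrum and cohort-manifest containers with plain-text I/O.

A :class:`Spectrum` is one Raman acquisition: a strictly increasing shift
axis (cm^-1) with intensities, plus acquisition metadata.  Spectra are
persisted as two-column CSV files (``shift_cm1,intensity``); cohort
manifests, which bind replicate spectra to sample-level outcome labels,
as TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABELS = ("pregnancy", "non_pregnancy")
PLATFORMS = ("p532", "p785")

MANIFEST_COLUMNS = ["spectrum_file", "sample_id", "replicate", "platform", "label"]

# The container itself only needs a well-formed axis; stages with real
# length requirements (smoothing window, outlier PCA) enforce their own.
MIN_CHANNELS = 2


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file or array pair is malformed."""


class ManifestError(ValueError):
    """Raised when a cohort manifest violates its invariants."""


@dataclass
class Spectrum:
    """One Raman acquisition.

    Attributes
    ----------
    shifts : ndarray
        Raman shift axis in cm^-1, strictly increasing.
    intensities : ndarray
        Detector counts (float; averaged exposures need not be integral).
    spectrum_id, sample_id : str
        Unique acquisition id and the biological sample it belongs to.
    replicate : int
        Replicate index within the sample (1-based).
    platform : str
        Acquisition platform tag, one of ``p532`` / ``p785``.
    label : str or None
        Clinical outcome of the sample, ``pregnancy`` / ``non_pregnancy``.
    """

    shifts: np.ndarray
    intensities: np.ndarray
    spectrum_id: str = ""
    sample_id: str = ""
    replicate: int = 1
    platform: str = "p532"
    label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        validate_axes(self.shifts, self.intensities)

    def __len__(self) -> int:
        return self.shifts.size

    def with_intensities(self, intensities: np.ndarray, **meta_updates) -> "Spectrum":
        """Copy of this spectrum with new intensities (same axis)."""
        s = replace(self, intensities=np.asarray(intensities, dtype=float))
        s.meta = {**self.meta, **meta_updates}
        return s

    def with_axis(self, shifts: np.ndarray, intensities: np.ndarray) -> "Spectrum":
        """Copy with a new (shift, intensity) pair, e.g. after band clipping."""
        s = replace(self, shifts=np.asarray(shifts, dtype=float),
                    intensities=np.asarray(intensities, dtype=float))
        s.meta = dict(self.meta)
        return s


def validate_axes(shifts: np.ndarray, intensities: np.ndarray) -> None:
    if shifts.ndim != 1 or intensities.ndim != 1:
        raise SpectrumFormatError("shifts and intensities must be 1-D")
    if shifts.size != intensities.size:
        raise SpectrumFormatError(
            f"length mismatch: {shifts.size} shifts vs {intensities.size} intensities")
    if shifts.size < MIN_CHANNELS:
        raise SpectrumFormatError(
            f"spectrum has {shifts.size} channels; at least {MIN_CHANNELS} required")
    if np.isnan(shifts).any() or np.isnan(intensities).any():
        raise SpectrumFormatError("NaN values in spectrum")
    d = np.diff(shifts)
    if (d == 0).any():
        dup = shifts[:-1][d == 0][0]
        raise SpectrumFormatError(f"duplicate shift value {dup:g}")
    if (d < 0).any():
        raise SpectrumFormatError("shift axis not strictly increasing")


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a spectrum as a two-column CSV with header ``shift_cm1,intensity``."""
    path = Path(path)
    arr = np.column_stack([spectrum.shifts, spectrum.intensities])
    header = "shift_cm1,intensity"
    np.savetxt(path, arr, delimiter=",", header=header, comments="", fmt="%.10g")
    return path


def read_spectrum(path: str | Path, id_fields: dict | None = None) -> Spectrum:
    """Read a two-column (shift, intensity) text file into a Spectrum.

    Accepts comma- or whitespace-delimited files with an optional header
    line.  A descending axis is re-sorted ascending with a warning.

    Parameters
    ----------
    path : path-like
    id_fields : dict, optional
        Metadata fields (``spectrum_id``, ``sample_id``, ``replicate``,
        ``platform``, ``label``) attached to the returned spectrum.
    """
    path = Path(path)
    shifts: list[float] = []
    intens: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if lineno == 1 and any(not _is_number(p) for p in parts):
                continue  # header line
            if len(parts) != 2 or not all(_is_number(p) for p in parts):
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected two numeric columns, got {line!r}")
            shifts.append(float(parts[0]))
            intens.append(float(parts[1]))
    x = np.asarray(shifts)
    y = np.asarray(intens)
    if x.size > 1 and np.all(np.diff(x) < 0):
        logger.warning("%s: descending shift axis; re-sorting ascending", path)
        x, y = x[::-1], y[::-1]
    fields = dict(id_fields or {})
    fields.setdefault("spectrum_id", path.stem)
    try:
        return Spectrum(shifts=x, intensities=y, **fields)
    except SpectrumFormatError as exc:
        raise SpectrumFormatError(f"{path}: {exc}") from exc


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort manifest against its invariants.

    Requires the standard columns, uniqueness of (sample_id, replicate),
    a single label per sample, and labels from the two-class set.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ManifestError(f"manifest missing columns: {missing}")
    if len(manifest) == 0:
        raise ManifestError("empty manifest")
    dup = manifest.duplicated(subset=["sample_id", "replicate"])
    if dup.any():
        pair = manifest.loc[dup, ["sample_id", "replicate"]].iloc[0]
        raise ManifestError(
            f"duplicate (sample_id, replicate): ({pair.sample_id}, {pair.replicate})")
    labelled = manifest.dropna(subset=["label"])
    bad = set(labelled["label"].unique()) - set(LABELS)
    if bad:
        raise ManifestError(f"unknown labels {sorted(bad)}; expected {LABELS}")
    per_sample = labelled.groupby("sample_id")["label"].nunique()
    conflicted = per_sample[per_sample > 1]
    if len(conflicted):
        raise ManifestError(
            f"sample(s) with conflicting labels: {list(conflicted.index)}")
    return manifest


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_manifest(manifest)
    manifest.to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path: str | Path, check_files: bool = False) -> pd.DataFrame:
    """Read and validate a TSV cohort manifest.

    With ``check_files=True`` every referenced spectrum file must exist
    (paths resolved relative to the manifest's directory).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ManifestError(f"{path}: empty manifest file") from exc
    validate_manifest(df)
    if check_files:
        base = path.parent
        for f in df["spectrum_file"]:
            p = Path(f)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise ManifestError(f"referenced spectrum file not found: {p}")
    return df


def load_cohort(manifest_path: str | Path, spectra_dir: str | Path | None = None) -> tuple[list[Spectrum], pd.DataFrame]:
    """Load every spectrum referenced by a manifest, with metadata attached."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = Path(spectra_dir) if spectra_dir is not None else manifest_path.parent
    spectra = []
    for row in df.itertuples(index=False):
        p = Path(row.spectrum_file)
        if not p.is_absolute():
            p = base / p
        spectra.append(read_spectrum(p, id_fields={
            "spectrum_id": Path(row.spectrum_file).stem,
            "sample_id": str(row.sample_id),
            "replicate": int(row.replicate),
            "platform": str(row.platform),
            "label": None if pd.isna(row.label) else str(row.label),
        }))
    return spectra, df
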