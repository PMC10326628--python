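"""Spectral preprocessing chain for raw Raman acquisitions.

The chain applied to every spectrum, in order:

1. cosmic-ray despiking — narrow (<= ``spike_max_width`` channels),
   high-amplitude channels are detected on a rolling-median residual by
   a modified z-score (MAD-based) threshold and replaced by linear
   interpolation of their flanking channels;
2. fingerprint-band clipping to [600, 1800] cm^-1;
3. Savitzky-Golay least-squares polynomial smoothing;
4. SNIP (statistics-sensitive non-linear iterative peak clipping)
   baseline estimation in LLS-transformed space with a decreasing
   clipping window, subtracted from the signal;
5. per-spectrum min-max normalization to [0, 1].

Outlier acquisitions are screened after preprocessing by Mahalanobis
distance in the leading principal-component scores against a chi-square
quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal, stats
from sklearn.decomposition import PCA

from ramanomics.spectra_io import Spectrum

logger = logging.getLogger(__name__)


class BandError(ValueError):
    """Requested band does not overlap the spectrum axis."""


class ParameterError(ValueError):
    """A preprocessing parameter is incompatible with the spectrum."""


class DegenerateInputError(ValueError):
    """Operation undefined on this input (e.g. constant spectrum)."""


@dataclass
class PreprocessConfig:
    band_low: float = 600.0
    band_high: float = 1800.0
    sg_window: int = 11
    sg_order: int = 3
    snip_iterations: int = 60
    spike_mad_k: float = 8.0
    spike_max_width: int = 4
    spike_min_prominence: float = 0.5
    outlier_pc_count: int = 3
    outlier_mahal_quantile: float = 0.999

    def __post_init__(self):
        if not self.band_low < self.band_high:
            raise ParameterError("band_low must be < band_high")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ParameterError("sg_window must be odd and greater than sg_order")
        if self.snip_iterations < 1:
            raise ParameterError("snip_iterations must be >= 1")
        if not 0.0 < self.outlier_mahal_quantile < 1.0:
            raise ParameterError("outlier_mahal_quantile must be in (0, 1)")


def remove_cosmic_spikes(spectrum: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Replace narrow cosmic-ray spikes by linear interpolation.

    Channels whose residual against a rolling median exceeds
    ``spike_mad_k`` in modified z-score are flagged; contiguous flagged
    runs no wider than ``spike_max_width`` channels are interpolated
    from the nearest clean flanking channels.  Wider runs are genuine
    bands and left untouched, as is every unflagged channel.

    Cosmic-ray events are strictly positive and large compared to the
    signal they sit on, so only positive residuals are eligible and the
    residual must also exceed ``spike_min_prominence`` times the local
    rolling-median level.  The prominence guard keeps the apex of a
    genuine sharp band (whose curvature leaves a small positive
    residual that can clear a MAD threshold at high signal-to-noise)
    from being flattened.

    Detection is repeated (up to three passes) because clustered spikes
    can occupy enough of the rolling-median window to hide each other;
    removing the detectable ones first exposes the rest.
    """
    cfg = cfg or PreprocessConfig()
    out_spectrum = spectrum
    for _ in range(3):
        corrected = _despike_once(out_spectrum, cfg)
        if corrected is out_spectrum:
            break
        out_spectrum = corrected
    return out_spectrum


def _despike_once(spectrum: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    y = spectrum.intensities
    window = 2 * cfg.spike_max_width + 1
    med = ndimage.median_filter(y, size=window, mode="nearest")
    resid = y - med
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad <= 0:
        mad = np.mean(np.abs(resid)) or 1e-12
    z = 0.6745 * resid / mad
    flagged = (z > cfg.spike_mad_k) & (resid > cfg.spike_min_prominence * np.abs(med))
    if not flagged.any():
        return spectrum

    out = y.copy()
    idx = np.flatnonzero(flagged)
    runs = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
    touched = []
    for run in runs:
        if run.size > cfg.spike_max_width:
            continue  # too wide for a cosmic spike
        lo, hi = run[0] - 1, run[-1] + 1
        xl = spectrum.shifts[lo] if lo >= 0 else spectrum.shifts[hi]
        xr = spectrum.shifts[hi] if hi < y.size else spectrum.shifts[lo]
        yl = y[lo] if lo >= 0 else y[hi]
        yr = y[hi] if hi < y.size else y[lo]
        if xl == xr:
            out[run] = yl
        else:
            out[run] = yl + (yr - yl) * (spectrum.shifts[run] - xl) / (xr - xl)
        touched.extend(run.tolist())
    if not touched:
        return spectrum
    logger.debug("spectrum %s: despiked %d channel(s)", spectrum.spectrum_id, len(touched))
    all_touched = sorted(set(spectrum.meta.get("despiked_channels", [])) | set(touched))
    return spectrum.with_intensities(out, despiked_channels=all_touched)


def clip_band(spectrum: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Restrict the spectrum to ``band_low <= shift <= band_high``."""
    cfg = cfg or PreprocessConfig()
    mask = (spectrum.shifts >= cfg.band_low) & (spectrum.shifts <= cfg.band_high)
    if not mask.any():
        raise BandError(
            f"band [{cfg.band_low:g}, {cfg.band_high:g}] does not overlap axis "
            f"[{spectrum.shifts[0]:g}, {spectrum.shifts[-1]:g}]")
    return spectrum.with_axis(spectrum.shifts[mask], spectrum.intensities[mask])


def smooth_sg(spectrum: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Savitzky-Golay smoothing (window ``sg_window``, order ``sg_order``).

    Edge channels are handled by a polynomial fit over the truncated
    window, so a polynomial of degree <= ``sg_order`` passes through
    unchanged everywhere.
    """
    cfg = cfg or PreprocessConfig()
    if len(spectrum) < cfg.sg_window:
        raise ParameterError(
            f"spectrum of {len(spectrum)} channels shorter than sg_window={cfg.sg_window}")
    smoothed = signal.savgol_filter(spectrum.intensities, cfg.sg_window, cfg.sg_order,
                                    mode="interp")
    return spectrum.with_intensities(smoothed)


def _lls(y: np.ndarray) -> np.ndarray:
    return np.log(np.log(np.sqrt(y + 1.0) + 1.0) + 1.0)


def _lls_inv(v: np.ndarray) -> np.ndarray:
    return (np.exp(np.exp(v) - 1.0) - 1.0) ** 2 - 1.0


def snip_baseline(spectrum: Spectrum, cfg: PreprocessConfig | None = None) -> tuple[Spectrum, Spectrum]:
    """SNIP baseline estimate and baseline-corrected spectrum.

    The intensities are compressed by the log-log-square-root (LLS)
    transform, then iteratively clipped with a symmetric window
    decreasing from ``snip_iterations`` channels down to 1 (the
    decreasing-window variant limits peak erosion), and decompressed.
    The baseline never exceeds the signal, and corrected + baseline
    reconstructs the input exactly.
    """
    cfg = cfg or PreprocessConfig()
    y = spectrum.intensities
    n = y.size
    offset = y.min()
    v = _lls(y - offset)
    m_max = min(cfg.snip_iterations, (n - 1) // 2)
    for m in range(m_max, 0, -1):
        clipped = v.copy()
        avg = 0.5 * (v[: n - 2 * m] + v[2 * m:])
        clipped[m: n - m] = np.minimum(v[m: n - m], avg)
        v = clipped
    baseline = _lls_inv(v) + offset
    baseline = np.minimum(baseline, y)  # guard fp round-trip of the LLS transform
    corrected = y - baseline
    return (spectrum.with_intensities(baseline),
            spectrum.with_intensities(corrected))


def normalize_minmax(spectrum: Spectrum) -> Spectrum:
    """Scale intensities affinely onto [0, 1]."""
    y = spectrum.intensities
    lo, hi = y.min(), y.max()
    if hi <= lo:
        raise DegenerateInputError(
            f"constant spectrum {spectrum.spectrum_id!r}: min-max normalization undefined")
    return spectrum.with_intensities((y - lo) / (hi - lo))


def preprocess_pipeline(spectrum: Spectrum, cfg: PreprocessConfig | None = None,
                        keep_intermediates: bool = False):
    """Full chain: despike -> clip -> smooth -> SNIP -> normalize.

    Returns the final spectrum, or ``(final, intermediates)`` with a
    dict of per-stage outputs when ``keep_intermediates`` is set.
    """
    cfg = cfg or PreprocessConfig()
    stages: dict[str, Spectrum] = {}
    s = remove_cosmic_spikes(spectrum, cfg)
    stages["despiked"] = s
    s = clip_band(s, cfg)
    stages["clipped"] = s
    s = smooth_sg(s, cfg)
    stages["smoothed"] = s
    baseline, s = snip_baseline(s, cfg)
    stages["baseline"] = baseline
    stages["corrected"] = s
    s = normalize_minmax(s)
    stages["normalized"] = s
    if keep_intermediates:
        return s, stages
    return s


def preprocess_batch(spectra: list[Spectrum], cfg: PreprocessConfig | None = None) -> list[Spectrum]:
    """Preprocess a batch, preserving order."""
    cfg = cfg or PreprocessConfig()
    return [preprocess_pipeline(s, cfg) for s in spectra]


@dataclass
class OutlierReport:
    kept: list[Spectrum]
    rejected: list[Spectrum]
    distances: dict[str, float]          # squared Mahalanobis distance per spectrum
    threshold: float
    dropped_samples: list[str] = field(default_factory=list)

    def __iter__(self):  # allows `kept, rejected = detect_outlier_spectra(...)`
        return iter((self.kept, self.rejected))


def detect_outlier_spectra(spectra: list[Spectrum], cfg: PreprocessConfig | None = None) -> OutlierReport:
    """Flag abnormal acquisitions by PCA-score Mahalanobis distance.

    The batch is projected onto its first ``outlier_pc_count`` principal
    components; a spectrum is rejected when its squared Mahalanobis
    distance in score space exceeds the ``outlier_mahal_quantile``
    chi-square quantile.  A sample is reported as dropped only when all
    its replicates are rejected.
    """
    cfg = cfg or PreprocessConfig()
    if len(spectra) < 10:
        raise ParameterError("outlier detection needs at least 10 spectra")
    X = np.vstack([s.intensities for s in spectra])
    k = min(cfg.outlier_pc_count, len(spectra) - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    var = pca.explained_variance_
    usable = var > max(var.max(), 1.0) * 1e-12 if var.size else np.zeros(0, bool)
    if not usable.any():
        # identical spectra: no variance structure, nothing can be abnormal
        return OutlierReport(list(spectra), [], {s.spectrum_id: 0.0 for s in spectra},
                             threshold=float("inf"))
    scores = scores[:, usable]
    var = var[usable]
    d2 = np.sum(scores ** 2 / var, axis=1)
    threshold = stats.chi2.ppf(cfg.outlier_mahal_quantile, df=scores.shape[1])
    reject = d2 > threshold
    kept = [s for s, r in zip(spectra, reject) if not r]
    rejected = [s for s, r in zip(spectra, reject) if r]
    per_sample: dict[str, list[bool]] = {}
    for s, r in zip(spectra, reject):
        per_sample.setdefault(s.sample_id, []).append(bool(r))
    dropped = [sid for sid, flags in per_sample.items() if all(flags)]
    if rejected:
        logger.info("outlier screen: rejected %d of %d spectra (threshold %.2f)",
                    len(rejected), len(spectra), threshold)
    return OutlierReport(kept, rejected,
                         {s.spectrum_id: float(d) for s, d in zip(spectra, d2)},
                         float(threshold), dropped)
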