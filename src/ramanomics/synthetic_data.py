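"""Synthetic Raman cohorts of spent embryo culture medium.

Real spectra for this assay are not publicly deposited, so every
downstream stage is exercised against simulated cohorts with known
ground truth.  Each spectrum is built as

    sum of Gaussian vibration bands  (amino acids + background bands)
  + phenylalanine internal-standard band at 1003 cm^-1
  + smooth fluorescence baseline    (4th-order polynomial + broad
                                     exponential hump, dominating the
                                     raw signal as in real acquisitions)
  + white Gaussian detector noise
  + occasional 1-3 channel cosmic-ray spikes (5-20x the local signal)

Band amplitudes are drawn per biological sample (between-sample
biological variability), then jittered multiplicatively per replicate
acquisition.  Group effects are planted as standardized mean shifts of
sample-level amplitudes: a positive effect size for an analyte raises
its mean amplitude in the non-pregnancy group by that many
between-sample standard deviations, emulating the elevated tyrosine /
tryptophan / serine metabolite levels seen in media of embryos that
fail to implant.

Two acquisition platform presets are provided: ``p532`` (crystallized
droplet on an Al@SiO2 substrate, higher signal-to-noise) and ``p785``
(liquid sample, lower concentration: weaker peaks, more noise, and
group effects attenuated by half).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ramanomics.spectra_io import Spectrum, LABELS, PLATFORMS, write_spectrum, write_manifest

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Band catalog: position (cm^-1) -> (name, base amplitude, FWHM cm^-1).
#: Quantified amino acids carry their analyte name; the remaining
#: fingerprint-region bands (nucleic acids, lipids, amide modes, ...)
#: are background for quantification purposes.
BAND_CATALOG: dict[float, tuple[str, float, float]] = {
    621.0: ("bg_621", 0.12, 11.0),
    644.0: ("bg_644", 0.10, 11.0),
    666.0: ("bg_666", 0.10, 12.0),
    758.0: ("tryptophan", 0.22, 11.0),
    828.0: ("proline", 0.20, 12.0),
    853.0: ("tyrosine", 0.45, 12.0),
    900.0: ("glycine", 0.28, 13.0),
    941.0: ("aspartic_acid", 0.30, 13.0),
    1003.0: ("phenylalanine", 1.00, 10.0),
    1032.0: ("taurine", 0.25, 11.0),
    1071.0: ("bg_1071", 0.40, 14.0),
    1127.0: ("bg_1127", 0.18, 13.0),
    1157.0: ("bg_1157", 0.15, 13.0),
    1174.0: ("bg_1174", 0.18, 12.0),
    1208.0: ("bg_1208", 0.16, 13.0),
    1243.0: ("bg_1243", 0.28, 15.0),
    1273.0: ("bg_1273", 0.18, 14.0),
    1326.0: ("serine", 0.30, 13.0),
    1339.0: ("bg_1339", 0.42, 10.0),
    1447.0: ("bg_1447", 0.50, 14.0),
    1556.0: ("bg_1556", 0.22, 14.0),
    1584.0: ("bg_1584", 0.28, 13.0),
    1606.0: ("bg_1606", 0.24, 13.0),
    1657.0: ("bg_1657", 0.45, 16.0),
}

#: Between-sample coefficient of variation of band amplitudes.
BETWEEN_SAMPLE_CV = 0.15
#: Replicate-to-replicate multiplicative log-normal jitter (sigma of log).
REPLICATE_JITTER_SIGMA = 0.05

#: Platform presets: overall amplitude scale, noise sd (intensity units on
#: the phenylalanine-amplitude scale), baseline magnitude, and the factor
#: applied to configured effect sizes.
PLATFORM_PRESETS = {
    "p532": {"amplitude_scale": 1.0, "noise_sd": 0.02,
             "baseline_magnitude": 5.0, "effect_scale": 1.0},
    "p785": {"amplitude_scale": 0.6, "noise_sd": 0.05,
             "baseline_magnitude": 6.0, "effect_scale": 0.5},
}


class ConfigurationError(ValueError):
    """A GeneratorConfig field violates its invariants."""


@dataclass
class GeneratorConfig:
    """Parameters of one simulated cohort.

    ``noise_sd``, ``baseline_magnitude`` and ``spike_rate`` default to
    the platform preset when left as None; explicit values always win.
    ``effect_sizes`` maps analyte name to the standardized mean
    difference (non-pregnancy minus pregnancy) of its sample-level
    amplitude; the ``p785`` preset halves them.
    """

    n_samples: int = 107
    replicates_per_sample: int = 5
    axis_start: float = 50.0
    axis_end: float = 2000.0
    axis_step: float = 1.0
    platform: str = "p532"
    class_balance: float = 0.5
    effect_sizes: dict[str, float] = field(default_factory=dict)
    noise_sd: float | None = None
    baseline_magnitude: float | None = None
    spike_rate: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.replicates_per_sample < 1:
            raise ConfigurationError("replicates_per_sample must be >= 1")
        if not self.axis_start < self.axis_end:
            raise ConfigurationError("axis_start must be < axis_end")
        if self.axis_step <= 0:
            raise ConfigurationError("axis_step must be > 0")
        if self.platform not in PLATFORMS:
            raise ConfigurationError(f"platform must be one of {PLATFORMS}")
        if not 0.0 < self.class_balance < 1.0:
            raise ConfigurationError("class_balance must be in (0, 1)")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.spike_rate is not None and self.spike_rate < 0:
            raise ConfigurationError("spike_rate must be >= 0")
        known = {name for name, _, _ in BAND_CATALOG.values()}
        unknown = set(self.effect_sizes) - known
        if unknown:
            raise ConfigurationError(f"effect_sizes for unknown analytes: {sorted(unknown)}")

    def resolved(self) -> dict:
        """Platform-resolved generation parameters."""
        preset = PLATFORM_PRESETS[self.platform]
        return {
            "amplitude_scale": preset["amplitude_scale"],
            "noise_sd": preset["noise_sd"] if self.noise_sd is None else self.noise_sd,
            "baseline_magnitude": (preset["baseline_magnitude"]
                                   if self.baseline_magnitude is None
                                   else self.baseline_magnitude),
            "spike_rate": 0.3 if self.spike_rate is None else self.spike_rate,
            "effect_scale": preset["effect_scale"],
        }


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover.

    ``sample_labels``:   sample_id -> outcome label.
    ``sample_amplitudes``: sample_id -> {band name -> sample-level amplitude}.
    ``spectrum_bands``:  spectrum_id -> (position, amplitude, sigma) rows
                         after replicate jitter — the exact band
                         parameters summed into that spectrum.
    ``spike_channels``:  spectrum_id -> channel indices that received a
                         cosmic-ray spike.
    ``baselines``:       spectrum_id -> injected baseline curve.
    """

    sample_labels: dict[str, str]
    sample_amplitudes: dict[str, dict[str, float]]
    spectrum_bands: dict[str, np.ndarray]
    spike_channels: dict[str, list[int]]
    baselines: dict[str, np.ndarray]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "sample_labels": self.sample_labels,
            "sample_amplitudes": self.sample_amplitudes,
            "spectrum_bands": {k: v.tolist() for k, v in self.spectrum_bands.items()},
            "spike_channels": self.spike_channels,
            "baselines": {k: np.round(v, 6).tolist() for k, v in self.baselines.items()},
        }
        path.write_text(json.dumps(payload))
        return path


def gaussian_band(x: np.ndarray, position: float, amplitude: float, sigma: float) -> np.ndarray:
    """Gaussian vibration band evaluated on the shift axis."""
    return amplitude * np.exp(-0.5 * ((x - position) / sigma) ** 2)


def evaluate_bands(x: np.ndarray, bands: np.ndarray) -> np.ndarray:
    """Sum of Gaussian bands given rows of (position, amplitude, sigma)."""
    y = np.zeros_like(x)
    for position, amplitude, sigma in bands:
        y += gaussian_band(x, position, amplitude, sigma)
    return y


def _baseline_curve(x: np.ndarray, magnitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth fluorescence-like background, strictly positive.

    Broad exponential hump decaying from the low-wavenumber end plus a
    gentle 4th-order polynomial, with small per-spectrum coefficient
    perturbations so no two acquisitions share an identical background.
    """
    t = (x - x[0]) / (x[-1] - x[0])
    coeffs = np.array([0.35, 0.25, -0.15, 0.10, -0.05]) + rng.normal(0.0, 0.02, size=5)
    poly = np.polyval(coeffs[::-1], t)
    tau = 700.0 * (1.0 + rng.normal(0.0, 0.05))
    hump = np.exp(-(x - x[0]) / tau)
    curve = magnitude * (0.6 * hump + 0.4 * poly)
    return np.clip(curve, 0.0, None)


def _draw_labels(n_samples: int, class_balance: float, rng: np.random.Generator) -> np.ndarray:
    n_nonpreg = int(round(class_balance * n_samples))
    n_nonpreg = min(max(n_nonpreg, 1), n_samples - 1) if n_samples > 1 else n_nonpreg
    labels = np.array(["non_pregnancy"] * n_nonpreg
                      + ["pregnancy"] * (n_samples - n_nonpreg), dtype=object)
    rng.shuffle(labels)
    return labels


def generate_cohort(config: GeneratorConfig) -> tuple[list[Spectrum], pd.DataFrame, GroundTruth]:
    """Simulate a labeled cohort of replicate Raman spectra.

    Returns ``(spectra, manifest, ground_truth)`` with exactly
    ``n_samples * replicates_per_sample`` spectra.  Identical configs
    (including seed) reproduce identical output bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    params = config.resolved()
    x = np.arange(config.axis_start, config.axis_end + 0.5 * config.axis_step,
                  config.axis_step)

    labels = _draw_labels(config.n_samples, config.class_balance, rng)

    positions = np.array(sorted(BAND_CATALOG))
    names = [BAND_CATALOG[p][0] for p in positions]
    base_amps = np.array([BAND_CATALOG[p][1] for p in positions]) * params["amplitude_scale"]
    sigmas = np.array([BAND_CATALOG[p][2] for p in positions]) * FWHM_TO_SIGMA
    effect = np.array([config.effect_sizes.get(n, 0.0) for n in names]) * params["effect_scale"]

    spectra: list[Spectrum] = []
    manifest_rows = []
    gt = GroundTruth({}, {}, {}, {}, {})

    digits = max(3, len(str(config.n_samples)))
    for i in range(config.n_samples):
        sample_id = f"S{i + 1:0{digits}d}"
        label = str(labels[i])
        between_sd = BETWEEN_SAMPLE_CV * base_amps
        mean = base_amps + (between_sd * effect if label == "non_pregnancy" else 0.0)
        sample_amps = rng.normal(mean, between_sd)
        sample_amps = np.clip(sample_amps, 0.05 * base_amps, None)
        gt.sample_labels[sample_id] = label
        gt.sample_amplitudes[sample_id] = dict(zip(names, sample_amps.tolist()))

        for r in range(1, config.replicates_per_sample + 1):
            spectrum_id = f"{sample_id}_r{r}"
            jitter = np.exp(rng.normal(0.0, REPLICATE_JITTER_SIGMA, size=len(names)))
            amps = sample_amps * jitter
            bands = np.column_stack([positions, amps, sigmas])
            signal = evaluate_bands(x, bands)
            baseline = _baseline_curve(x, params["baseline_magnitude"], rng)
            y = signal + baseline
            if params["noise_sd"] > 0:
                y = y + rng.normal(0.0, params["noise_sd"], size=x.size)

            spike_channels: list[int] = []
            n_spikes = rng.poisson(params["spike_rate"])
            for _ in range(n_spikes):
                pos = int(rng.integers(2, x.size - 2))
                width = int(rng.integers(1, 4))
                factor = rng.uniform(5.0, 20.0)
                height = factor * max(abs(y[pos]), 1.0)
                for k in range(width):
                    ch = pos + k
                    if ch < x.size:
                        y[ch] += height * (1.0 - 0.3 * k)
                        spike_channels.append(ch)

            gt.spectrum_bands[spectrum_id] = bands
            gt.spike_channels[spectrum_id] = spike_channels
            gt.baselines[spectrum_id] = baseline
            spectra.append(Spectrum(
                shifts=x.copy(), intensities=y,
                spectrum_id=spectrum_id, sample_id=sample_id, replicate=r,
                platform=config.platform, label=label))
            manifest_rows.append({
                "spectrum_file": f"{spectrum_id}.csv",
                "sample_id": sample_id,
                "replicate": r,
                "platform": config.platform,
                "label": label,
            })

    manifest = pd.DataFrame(manifest_rows)
    return spectra, manifest, gt


def planted_effect_cohort(config: GeneratorConfig) -> tuple[list[Spectrum], pd.DataFrame, GroundTruth]:
    """Cohort with explicit group effects; requires a nonzero effect size."""
    if not any(v != 0.0 for v in config.effect_sizes.values()):
        raise ConfigurationError(
            "planted_effect_cohort requires a nonzero entry in effect_sizes")
    return generate_cohort(config)


def write_cohort(spectra: list[Spectrum], manifest: pd.DataFrame, ground_truth: GroundTruth,
                 outdir: str | Path) -> Path:
    """Persist a cohort: one CSV per spectrum, TSV manifest, JSON truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in spectra:
        write_spectrum(s, outdir / f"{s.spectrum_id}.csv")
    write_manifest(manifest, outdir / "manifest.tsv")
    ground_truth.to_json(outdir / "ground_truth.json")
    return outdir


def config_to_dict(config: GeneratorConfig) -> dict:
    return asdict(config)
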