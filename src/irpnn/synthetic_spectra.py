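"""Synthetic ATR-FT-IR spectrum generator for the three tissue classes.

Real mid-infrared spectra of pancreatic tissue show a small set of
assignable absorption bands whose intensities shift with carcinogenesis:
the broad O-H/N-H stretch near 3327 cm^-1 is class-invariant; the
saturated C-H stretches at 2956/2924/2852 cm^-1 and the amide I/II bands
at 1650/1555 cm^-1 weaken as the tissue progresses from normal through
early to advanced carcinoma; the ester carbonyl at 1743 cm^-1 weakens in
early carcinoma and vanishes entirely in advanced carcinoma; the nucleic
acid phosphodiester bands at 1242/1084 cm^-1 stay put.

The generator renders each sample as a sum of Gaussian (optionally
Lorentzian) band profiles with per-sample multiplicative amplitude jitter,
a random linear baseline, and additive white noise, on the instrument grid
4000-650 cm^-1 at 2 cm^-1 spacing.  The default cohort is 220 normal, 120
early and 100 advanced samples.  With all three random terms set to zero
the output is a deterministic function of the band table, which is what
the peak-position checks in the test-suite rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .spectra_io import Spectrum
from .tissue import CLASS_ORDER, TissueClass

__all__ = [
    "BandSpec",
    "SyntheticConfig",
    "default_band_table",
    "simulate_spectrum",
    "simulate_cohort",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class BandSpec:
    """One absorption band: position, width, and per-class peak amplitude.

    ``amplitude_by_class`` maps each :class:`TissueClass` to a nonnegative
    peak absorbance; the *ordering* of those amplitudes across classes is
    what encodes the biochemistry of canceration, the absolute values are
    model choices.
    """

    center: float  # cm^-1
    fwhm: float  # cm^-1, full width at half maximum
    amplitude_by_class: dict[TissueClass, float]

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"band at {self.center} cm^-1: fwhm must be > 0")
        for tc in CLASS_ORDER:
            if tc not in self.amplitude_by_class:
                raise ValueError(f"band at {self.center} cm^-1: missing amplitude for {tc.label}")
            if self.amplitude_by_class[tc] < 0:
                raise ValueError(f"band at {self.center} cm^-1: negative amplitude")

    def profile(self, grid: np.ndarray, amplitude: float, shape: str = "gaussian") -> np.ndarray:
        """Band line shape evaluated on ``grid`` with the given peak height."""
        x = grid - self.center
        if shape == "gaussian":
            return amplitude * np.exp(-4.0 * _LN2 * x**2 / self.fwhm**2)
        if shape == "lorentzian":
            hwhm = self.fwhm / 2.0
            return amplitude * hwhm**2 / (x**2 + hwhm**2)
        raise ValueError(f"unknown band shape {shape!r}")


def _band(center: float, fwhm: float, normal: float, early: float, advanced: float) -> BandSpec:
    return BandSpec(
        center,
        fwhm,
        {
            TissueClass.NORMAL: normal,
            TissueClass.EARLY: early,
            TissueClass.ADVANCED: advanced,
        },
    )


def default_band_table() -> list[BandSpec]:
    """The nine-band default table (amplitudes are normal/early/advanced).

    Weakening C-H and amide bands fall 1.0 -> 0.6 -> 0.3 with progression;
    the 1743 cm^-1 ester carbonyl falls 1.0 -> 0.5 -> 0 (absent in advanced
    carcinoma); the hydroxyl band at 3327 cm^-1 and the phosphodiester
    bands at 1242/1084 cm^-1 are class-invariant.  The broad hydroxyl band
    gets fwhm 200 cm^-1, all sharp bands fwhm 20 cm^-1.
    """
    return [
        _band(3327.0, 200.0, 1.0, 1.0, 1.0),  # O-H / N-H stretch envelope
        _band(2956.0, 20.0, 1.0, 0.6, 0.3),  # CH3 asym stretch
        _band(2924.0, 20.0, 1.0, 0.6, 0.3),  # CH2 asym stretch
        _band(2852.0, 20.0, 1.0, 0.6, 0.3),  # CH2 sym stretch
        _band(1743.0, 20.0, 1.0, 0.5, 0.0),  # ester C=O, gone in advanced
        _band(1650.0, 20.0, 1.0, 0.6, 0.3),  # amide I
        _band(1555.0, 20.0, 1.0, 0.6, 0.3),  # amide II
        _band(1242.0, 20.0, 1.0, 1.0, 1.0),  # PO2- asym stretch
        _band(1084.0, 20.0, 1.0, 1.0, 1.0),  # PO2- sym stretch
    ]


@dataclass
class SyntheticConfig:
    """Generator settings: grid, band table, noise model, cohort sizes.

    ``amplitude_jitter`` is the relative half-width of a per-sample,
    per-band uniform multiplicative perturbation (0.10 means each band
    amplitude is scaled by U[0.9, 1.1]).  ``baseline_slope_sd`` is the
    standard deviation of the random linear baseline slope, in absorbance
    per 1000 cm^-1.  ``noise_sd`` is additive white noise on absorbance.
    """

    grid_max: float = 4000.0
    grid_min: float = 650.0
    spacing: float = 2.0
    bands: list[BandSpec] = field(default_factory=default_band_table)
    band_shape: str = "gaussian"
    noise_sd: float = 0.01
    amplitude_jitter: float = 0.10
    baseline_slope_sd: float = 0.005
    class_sizes: dict[TissueClass, int] = field(
        default_factory=lambda: {
            TissueClass.NORMAL: 220,
            TissueClass.EARLY: 120,
            TissueClass.ADVANCED: 100,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grid_min < self.grid_max:
            raise ValueError("grid_min must be < grid_max")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.noise_sd < 0 or self.amplitude_jitter < 0 or self.baseline_slope_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        for tc in CLASS_ORDER:
            if self.class_sizes.get(tc, 0) < 0:
                raise ValueError("class sizes must be >= 0")
        for b in self.bands:
            if not (self.grid_min <= b.center <= self.grid_max):
                raise ValueError(
                    f"band center {b.center} cm^-1 outside grid "
                    f"[{self.grid_min}, {self.grid_max}]"
                )

    def grid(self) -> np.ndarray:
        """Descending wavenumber grid (FT-IR plotting convention)."""
        n = int(round((self.grid_max - self.grid_min) / self.spacing)) + 1
        return self.grid_max - self.spacing * np.arange(n)


def simulate_spectrum(
    tissue_class: TissueClass,
    config: SyntheticConfig,
    rng: np.random.Generator,
    sample_id: str = "",
) -> Spectrum:
    """Render one labeled synthetic spectrum.

    The signal is the sum over bands of the configured line shape with the
    class amplitude jittered multiplicatively per sample, plus a random
    linear baseline (slope drawn per sample, anchored at the grid centre)
    and i.i.d. Gaussian noise.  With ``noise_sd = amplitude_jitter =
    baseline_slope_sd = 0`` the result is deterministic.
    """
    if not isinstance(tissue_class, TissueClass):
        try:
            tissue_class = TissueClass.from_label(tissue_class)
        except ValueError:
            raise ValueError(f"invalid tissue class {tissue_class!r}") from None
    grid = config.grid()
    signal = np.zeros_like(grid)
    for band in config.bands:
        amplitude = band.amplitude_by_class[tissue_class]
        if config.amplitude_jitter > 0:
            amplitude *= rng.uniform(1 - config.amplitude_jitter, 1 + config.amplitude_jitter)
        if amplitude > 0:
            signal += band.profile(grid, amplitude, config.band_shape)
    if config.baseline_slope_sd > 0:
        slope = rng.normal(0.0, config.baseline_slope_sd)  # per 1000 cm^-1
        signal += slope * (grid - grid.mean()) / 1000.0
    if config.noise_sd > 0:
        signal += rng.normal(0.0, config.noise_sd, size=grid.size)
    return Spectrum(grid, signal, sample_id=sample_id, label=tissue_class)


def simulate_cohort(config: SyntheticConfig) -> list[Spectrum]:
    """Generate the full labeled cohort (default 220/120/100 = 440 samples).

    A single seeded random stream drives all samples, so the cohort is a
    deterministic function of ``(config, config.seed)``.  Samples are
    ordered by class (normal, early, advanced) and numbered within class.
    """
    rng = np.random.default_rng(config.seed)
    cohort: list[Spectrum] = []
    for tc in CLASS_ORDER:
        for i in range(config.class_sizes.get(tc, 0)):
            cohort.append(
                simulate_spectrum(tc, config, rng, sample_id=f"{tc.label}-{i + 1:04d}")
            )
    return cohort
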