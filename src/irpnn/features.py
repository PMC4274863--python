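"""Region-energy features from wavelet detail coefficients.

A spectrum restricted to the fingerprint region is decomposed to five
dyadic levels; the detail sequences at levels 3 and 4 — coarse enough to
suppress noise, fine enough to keep band structure — are each split into
two contiguous regions, and the energy (sum of squared coefficients) of
each region becomes one feature.  The resulting default 4-vector is
normalized to unit Euclidean length, which removes the overall intensity
scale of the spectrum: two spectra that differ by a uniform multiplicative
factor map to the same feature vector.

The level/region counts are configurable (e.g. three levels x three
regions gives a 9-feature variant); energies are the only statistic
computed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dwt import WaveletFilterBank, detail, dwt_decompose, parse_wavelet_name
from .spectra_io import Spectrum
from .tissue import TissueClass

__all__ = [
    "FeatureVector",
    "FeatureConfig",
    "partition_regions",
    "region_energy",
    "extract_features",
    "features_to_table",
    "table_to_features",
]


@dataclass
class FeatureVector:
    """Ordered region energies with their (level, region) provenance."""

    values: np.ndarray
    level_region_index: list[tuple[int, int]]
    label: TissueClass | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("feature values must be 1-D")
        if len(self.level_region_index) != self.values.size:
            raise ValueError("one (level, region) index is required per value")


@dataclass(frozen=True)
class FeatureConfig:
    """Wavelet and region settings for feature extraction."""

    wavelet: str = "db4"
    levels: int = 5
    detail_levels: tuple[int, ...] = (3, 4)
    regions_per_level: int = 2
    mode: str = "symmetric"
    normalization: str = "l2"  # or "minmax"

    def __post_init__(self) -> None:
        if self.levels < 1 or self.regions_per_level < 1:
            raise ValueError("levels and regions_per_level must be >= 1")
        if any(not 1 <= lv <= self.levels for lv in self.detail_levels):
            raise ValueError(f"detail_levels {self.detail_levels} outside 1..{self.levels}")
        if self.normalization not in ("l2", "minmax", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def partition_regions(coeffs: np.ndarray, n_regions: int) -> list[range]:
    """Split index space into contiguous near-equal regions.

    Regions are disjoint and exhaustive; lengths differ by at most one,
    with earlier regions taking the extra element.
    """
    n = len(coeffs)
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if n < n_regions:
        raise ValueError(f"cannot split {n} coefficients into {n_regions} regions")
    base, extra = divmod(n, n_regions)
    ranges: list[range] = []
    start = 0
    for r in range(n_regions):
        size = base + (1 if r < extra else 0)
        ranges.append(range(start, start + size))
        start += size
    return ranges


def region_energy(coeffs: np.ndarray, index_range: range) -> float:
    """Sum of squared coefficients over one region."""
    if len(index_range) == 0:
        raise ValueError("empty region")
    if index_range.start < 0 or index_range.stop > len(coeffs):
        raise ValueError(f"region {index_range} out of bounds for {len(coeffs)} coefficients")
    seg = np.asarray(coeffs, dtype=float)[index_range.start : index_range.stop]
    return float(np.sum(seg**2))


def extract_features(
    spectrum: Spectrum,
    config: FeatureConfig = FeatureConfig(),
    filter_bank: WaveletFilterBank | None = None,
) -> FeatureVector:
    """Decompose a spectrum and return its normalized region-energy vector.

    The spectrum is expected to be already restricted to the analysis
    region (2000-650 cm^-1 in the default pipeline).  Energies are laid
    out level-then-region, so the default is
    ``(d3 r1, d3 r2, d4 r1, d4 r2)``.
    """
    fb = filter_bank if filter_bank is not None else parse_wavelet_name(config.wavelet)
    decomposition = dwt_decompose(spectrum.absorbance, fb, config.levels, config.mode)
    values: list[float] = []
    index: list[tuple[int, int]] = []
    for level in config.detail_levels:
        coeffs = detail(decomposition, level)
        for r, rng in enumerate(partition_regions(coeffs, config.regions_per_level), start=1):
            values.append(region_energy(coeffs, rng))
            index.append((level, r))
    raw = np.array(values)
    if config.normalization == "l2":
        norm = float(np.linalg.norm(raw))
        if norm == 0.0:
            raise ValueError("all-zero feature vector cannot be normalized")
        raw = raw / norm
    elif config.normalization == "minmax":
        lo, hi = raw.min(), raw.max()
        if hi == lo:
            raise ValueError("constant feature vector cannot be min-max scaled")
        raw = (raw - lo) / (hi - lo)
    return FeatureVector(raw, index, label=spectrum.label, sample_id=spectrum.sample_id)


_TABLE_HEADER = ("sample_id", "label", "level", "region", "energy")


def features_to_table(features: list[FeatureVector], path: str | Path) -> None:
    """Write feature vectors as a long-form CSV (one row per energy)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TABLE_HEADER)
        for fv in features:
            lab = fv.label.label if fv.label is not None else ""
            for (level, region), value in zip(fv.level_region_index, fv.values):
                writer.writerow([fv.sample_id, lab, level, region, repr(float(value))])


def table_to_features(path: str | Path) -> list[FeatureVector]:
    """Read a long-form feature CSV back into feature vectors.

    Rows are grouped by ``sample_id`` in file order; write-then-read is
    the identity.
    """
    path = Path(path)
    groups: dict[str, dict] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if tuple(header) != _TABLE_HEADER:
            raise ValueError(f"{path}: expected header {_TABLE_HEADER}, got {tuple(header)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_TABLE_HEADER):
                raise ValueError(
                    f"{path}, line {lineno}: expected {len(_TABLE_HEADER)} columns, "
                    f"got {len(row)}"
                )
            sample_id, lab, level, region, energy = row
            try:
                entry = (int(level), int(region)), float(energy)
            except ValueError:
                raise ValueError(f"{path}, line {lineno}: non-numeric value in {row!r}") from None
            g = groups.setdefault(sample_id, {"label": lab, "rows": []})
            g["rows"].append(entry)
    out: list[FeatureVector] = []
    for sample_id, g in groups.items():
        label = TissueClass.from_label(g["label"]) if g["label"] else None
        index = [idx for idx, _ in g["rows"]]
        values = np.array([v for _, v in g["rows"]])
        out.append(FeatureVector(values, index, label=label, sample_id=sample_id))
    return out


def feature_matrix(features: list[FeatureVector]) -> tuple[np.ndarray, list[TissueClass | None]]:
    """Stack feature vectors into an (n_samples, n_features) design matrix."""
    if not features:
        return np.empty((0, 0)), []
    dim = features[0].values.size
    for fv in features:
        if fv.values.size != dim:
            raise ValueError("inconsistent feature dimensions")
    return np.vstack([fv.values for fv in features]), [fv.label for fv in features]
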