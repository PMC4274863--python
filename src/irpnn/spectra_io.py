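"""Spectrum container and I/O: CSV, simple JCAMP-DX, averaging, region cuts.

Spectra live on a uniform wavenumber grid stored in descending order
(4000 -> 650 cm^-1), the plotting convention of infrared spectroscopy.
Readers normalize ascending input to descending; every constructor path
validates the grid, so downstream stages can assume a clean uniform axis.

No baseline correction, smoothing or atmospheric compensation is applied
anywhere in this module; replicate averaging is the only preprocessing.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .tissue import TissueClass

__all__ = [
    "Spectrum",
    "SpectrumError",
    "ParseError",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_jcampdx",
    "average_replicates",
    "restrict_region",
    "resample",
]

CSV_HEADER = ("wavenumber_cm-1", "absorbance")

#: relative tolerance on grid-spacing uniformity
_GRID_RTOL = 1e-6


class SpectrumError(ValueError):
    """A spectrum violates its structural invariants."""


class ParseError(SpectrumError):
    """A spectrum file could not be decoded."""


@dataclass
class Spectrum:
    """One sample's absorbance values on a uniform wavenumber grid.

    Parameters
    ----------
    wavenumbers : array of float
        Uniform grid in cm^-1.  Either orientation is accepted; the stored
        grid is always descending.
    absorbance : array of float
        One absorbance value per grid point.
    sample_id : str
        Free-text identifier.
    label : TissueClass, optional
        Histological class, when known.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    label: TissueClass | None = field(default=None)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or ab.ndim != 1:
            raise SpectrumError("wavenumbers and absorbance must be 1-D")
        if wn.size != ab.size:
            raise SpectrumError(
                f"length mismatch: {wn.size} wavenumbers vs {ab.size} absorbances"
            )
        if wn.size < 2:
            raise SpectrumError("a spectrum needs at least 2 grid points")
        if not (np.all(np.isfinite(wn)) and np.all(np.isfinite(ab))):
            raise SpectrumError("non-finite values in spectrum")
        d = np.diff(wn)
        if np.all(d > 0):  # ascending input -> normalize to descending
            wn, ab, d = wn[::-1], ab[::-1], -d[::-1]
        elif not np.all(d < 0):
            raise SpectrumError("wavenumber grid is not strictly monotonic")
        step = d.mean()
        if np.max(np.abs(d - step)) > _GRID_RTOL * abs(step):
            raise SpectrumError("wavenumber grid spacing is not uniform")
        self.wavenumbers = np.ascontiguousarray(wn)
        self.absorbance = np.ascontiguousarray(ab)
        if self.label is not None and not isinstance(self.label, TissueClass):
            self.label = TissueClass(self.label)

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def spacing(self) -> float:
        """Grid step in cm^-1 (positive)."""
        return float(self.wavenumbers[0] - self.wavenumbers[1])

    def same_grid(self, other: "Spectrum") -> bool:
        return self.wavenumbers.shape == other.wavenumbers.shape and np.allclose(
            self.wavenumbers, other.wavenumbers, rtol=_GRID_RTOL, atol=0.0
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.label == other.label
            and np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.absorbance, other.absorbance)
        )


def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Read a two-column ``wavenumber_cm-1,absorbance`` CSV.

    Rows may be in ascending or descending wavenumber order; the result is
    normalized to descending.  Malformed rows raise :class:`ParseError`
    naming the offending line.
    """
    path = Path(path)
    wn: list[float] = []
    ab: list[float] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) != 2:
            raise ParseError(f"{path}, line 1: expected 2 header columns, got {len(header)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise ParseError(f"{path}, line {lineno}: expected 2 columns, got {len(row)}")
            try:
                wn.append(float(row[0]))
                ab.append(float(row[1]))
            except ValueError:
                raise ParseError(f"{path}, line {lineno}: non-numeric value in {row!r}") from None
    try:
        return Spectrum(np.array(wn), np.array(ab), sample_id=path.stem)
    except SpectrumError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as a two-column CSV (descending wavenumbers).

    Values are written with ``repr`` so a write-then-read round trip is
    exact.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for w, a in zip(spectrum.wavenumbers, spectrum.absorbance):
            writer.writerow([repr(float(w)), repr(float(a))])


def _jcamp_fields(path: Path) -> tuple[dict[str, str], list[str]]:
    """Split a JCAMP-DX file into labelled-data-records and XYDATA lines."""
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in path.read_text().splitlines():
        line = raw.split("$$")[0].rstrip()  # strip comments
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                in_data = True
                fields[key] = value
            elif key == "END":
                in_data = False
            else:
                if in_data:
                    in_data = False
                fields[key] = value
        elif in_data:
            data_lines.append(line)
    return fields, data_lines


_AFFN_ALLOWED = set("0123456789+-.eE \t,")


def read_jcampdx(path: str | Path) -> Spectrum:
    """Read a JCAMP-DX spectrum in the uncompressed ``(X++(Y..Y))`` form.

    Supports AFFN (plain numeric) tables with XFACTOR/YFACTOR scaling and
    FIRSTX/LASTX/NPOINTS grid definition.  TRANSMITTANCE data are converted
    to absorbance via ``A = -log10(T)``.  Compressed dialects (SQZ, DIF,
    DUP, PAC packing with letter digits) are rejected explicitly rather
    than silently misparsed.
    """
    path = Path(path)
    fields, data_lines = _jcamp_fields(path)
    if "XYDATA" not in fields:
        raise ParseError(f"{path}: no ##XYDATA record")
    form = fields["XYDATA"].replace(" ", "")
    if form != "(X++(Y..Y))":
        raise ParseError(f"{path}: dialect unsupported: ##XYDATA={fields['XYDATA']!r}")
    try:
        npoints = int(float(fields["NPOINTS"]))
        firstx = float(fields["FIRSTX"])
        lastx = float(fields["LASTX"])
    except KeyError as exc:
        raise ParseError(f"{path}: missing required record ##{exc.args[0]}") from None
    xfactor = float(fields.get("XFACTOR", "1"))
    yfactor = float(fields.get("YFACTOR", "1"))

    ys: list[float] = []
    for line in data_lines:
        if not set(line) <= _AFFN_ALLOWED:
            bad = sorted(set(line) - _AFFN_ALLOWED)
            raise ParseError(
                f"{path}: dialect unsupported: non-AFFN characters {bad!r} "
                "(SQZ/DIF/DUP compression is not handled)"
            )
        tokens = line.replace(",", " ").split()
        if not tokens:
            continue
        # first token is the line's starting X; the rest are Y values
        ys.extend(float(t) for t in tokens[1:])
    if len(ys) != npoints:
        raise ParseError(
            f"{path}: ##NPOINTS={npoints} but decoded {len(ys)} ordinate values"
        )
    x = np.linspace(firstx, lastx, npoints) * xfactor
    y = np.array(ys) * yfactor
    yunits = fields.get("YUNITS", "ABSORBANCE").upper()
    if yunits.startswith("TRANSMIT"):
        if np.any(y <= 0):
            raise ParseError(f"{path}: non-positive transmittance cannot be converted")
        y = -np.log10(y)
    elif not yunits.startswith("ABSORB"):
        raise ParseError(f"{path}: unsupported ##YUNITS={fields.get('YUNITS')!r}")
    try:
        return Spectrum(x, y, sample_id=fields.get("TITLE", path.stem))
    except SpectrumError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def average_replicates(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate measurements on an identical grid.

    The label is kept only if all replicates agree on it; sample ids are
    joined with '+'.  Mismatched grids are an error — resampling must be
    requested explicitly via :func:`resample`.
    """
    if not spectra:
        raise SpectrumError("cannot average an empty replicate list")
    first = spectra[0]
    for s in spectra[1:]:
        if not first.same_grid(s):
            raise SpectrumError(
                "replicates are on different grids; resample explicitly first"
            )
    mean = np.mean([s.absorbance for s in spectra], axis=0)
    labels = {s.label for s in spectra}
    label = labels.pop() if len(labels) == 1 else None
    sample_id = "+".join(s.sample_id for s in spectra if s.sample_id)
    return Spectrum(first.wavenumbers.copy(), mean, sample_id=sample_id, label=label)


def restrict_region(spectrum: Spectrum, high: float, low: float) -> Spectrum:
    """Keep grid points with ``low <= wavenumber <= high`` (closed interval).

    The default analysis window of the pipeline is the fingerprint region
    2000-650 cm^-1.
    """
    if not low < high:
        raise SpectrumError(f"empty window: low={low} must be < high={high}")
    mask = (spectrum.wavenumbers >= low) & (spectrum.wavenumbers <= high)
    if mask.sum() < 2:
        raise SpectrumError(
            f"window [{low}, {high}] cm^-1 covers {int(mask.sum())} grid points; need >= 2"
        )
    return replace(
        spectrum,
        wavenumbers=spectrum.wavenumbers[mask],
        absorbance=spectrum.absorbance[mask],
    )


def resample(spectrum: Spectrum, high: float, low: float, spacing: float) -> Spectrum:
    """Linearly interpolate onto the uniform grid ``high..low`` step ``spacing``.

    Deliberately a separate operation: readers never resample silently.
    Points outside the source grid are an error, not an extrapolation.
    """
    if spacing <= 0:
        raise SpectrumError("spacing must be positive")
    n = int(round((high - low) / spacing)) + 1
    if n < 2 or not math.isclose(low + (n - 1) * spacing, high, rel_tol=1e-9):
        raise SpectrumError(f"({high}, {low}) is not an integer number of {spacing} steps")
    grid = high - spacing * np.arange(n)
    src_hi, src_lo = spectrum.wavenumbers[0], spectrum.wavenumbers[-1]
    if high > src_hi or low < src_lo:
        raise SpectrumError(
            f"target grid [{low}, {high}] exceeds source range [{src_lo}, {src_hi}]"
        )
    # np.interp wants ascending abscissae
    values = np.interp(grid[::-1], spectrum.wavenumbers[::-1], spectrum.absorbance[::-1])[::-1]
    return replace(spectrum, wavenumbers=grid, absorbance=values)
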