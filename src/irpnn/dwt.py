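"""Multilevel 1-D discrete wavelet transform with Daubechies filter banks.

The dyadic DWT is computed with the Mallat pyramid: at each level the
current approximation is convolved with the analysis low-pass/high-pass
pair and downsampled by two, yielding the next approximation and one
detail sequence.  Two boundary treatments are provided:

``"symmetric"``
    Half-point symmetric extension (…b a | a b c … | c b…).  The natural
    choice for absorption spectra, which are not periodic.  Level-j output
    length is ``floor((n + L - 1) / 2)`` for filter length ``L``.
``"periodic"``
    Periodized transform.  Orthogonal for even lengths (exact energy
    conservation), output length ``ceil(n / 2)`` per level; odd lengths
    are extended by repeating the last sample.

Both modes reconstruct the input exactly (to rounding) via
:func:`idwt_reconstruct`.

Filter conventions: the analysis high-pass is the quadrature mirror
``hi_d[k] = (-1)^k * lo_d[L-1-k]`` of the low-pass.  This fixes the sign
of the detail coefficients; some other implementations use the opposite
sign, which flips details globally but changes no energy and no
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._daubechies import DB_LO_D

__all__ = [
    "WaveletFilterBank",
    "DWTDecomposition",
    "daubechies_filters",
    "parse_wavelet_name",
    "dwt_decompose",
    "idwt_reconstruct",
    "detail",
]

MODES = ("symmetric", "periodic")


@dataclass(frozen=True)
class WaveletFilterBank:
    """Orthogonal two-channel filter bank (analysis + synthesis filters)."""

    family: str
    order: int
    lo_d: np.ndarray
    hi_d: np.ndarray
    lo_r: np.ndarray
    hi_r: np.ndarray

    def __post_init__(self) -> None:
        L = len(self.lo_d)
        if L != 2 * self.order:
            raise ValueError(f"filter length {L} != 2 * order {self.order}")
        if abs(self.lo_d.sum() - np.sqrt(2.0)) > 1e-10:
            raise ValueError("low-pass filter does not sum to sqrt(2)")
        qmf = (-1.0) ** np.arange(L) * self.lo_d[::-1]
        if np.max(np.abs(qmf - self.hi_d)) > 1e-12:
            raise ValueError("hi_d is not the quadrature mirror of lo_d")
        # orthonormality of the low-pass to its even shifts
        for shift in range(2, L, 2):
            if abs(np.dot(self.lo_d[:-shift], self.lo_d[shift:])) > 1e-10:
                raise ValueError("lo_d is not orthogonal to its even shifts")

    def __len__(self) -> int:
        return len(self.lo_d)


def daubechies_filters(order: int) -> WaveletFilterBank:
    """Daubechies filter bank of the given order (db1=Haar … db10).

    Coefficients come from the frozen table in :mod:`irpnn._daubechies`;
    reconstruction filters are the time-reversed analysis filters, as for
    any orthogonal wavelet.
    """
    if order not in DB_LO_D:
        supported = f"1..{max(DB_LO_D)}"
        raise ValueError(f"unsupported Daubechies order {order}; supported: {supported}")
    lo_d = np.array(DB_LO_D[order])
    hi_d = (-1.0) ** np.arange(len(lo_d)) * lo_d[::-1]
    return WaveletFilterBank(
        family="daubechies",
        order=order,
        lo_d=lo_d,
        hi_d=hi_d,
        lo_r=lo_d[::-1].copy(),
        hi_r=hi_d[::-1].copy(),
    )


def parse_wavelet_name(name: str) -> WaveletFilterBank:
    """Resolve a name like ``"db4"`` or ``"haar"`` to a filter bank."""
    key = name.strip().lower()
    if key == "haar":
        return daubechies_filters(1)
    if key.startswith("db"):
        try:
            return daubechies_filters(int(key[2:]))
        except ValueError:
            raise ValueError(f"unknown wavelet {name!r}") from None
    raise ValueError(f"unknown wavelet {name!r}; supported: haar, db1..db10")


@dataclass
class DWTDecomposition:
    """Result of a multilevel decomposition.

    ``details`` is ordered fine to coarse (d1 … dL).  ``original_length``
    and the per-level input lengths are kept so reconstruction can trim
    the boundary-extension surplus exactly.
    """

    approximation: np.ndarray
    details: list[np.ndarray]
    levels: int
    mode: str
    filter_bank: WaveletFilterBank
    original_length: int
    _input_lengths: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len(self.details) != self.levels:
            raise ValueError(f"expected {self.levels} detail sequences, got {len(self.details)}")
        if not self._input_lengths:
            # lengths of the approximation fed into each analysis step
            lengths = [self.original_length]
            for d in self.details[:-1]:
                lengths.append(len(d))
            self._input_lengths = lengths

    def coefficient_arrays(self) -> list[np.ndarray]:
        """All coefficient sequences, coarse first: [aL, dL, …, d1]."""
        return [self.approximation, *self.details[::-1]]

    def total_energy(self) -> float:
        return float(sum(np.sum(c**2) for c in self.coefficient_arrays()))


def _dwt_step(x: np.ndarray, fb: WaveletFilterBank, mode: str) -> tuple[np.ndarray, np.ndarray]:
    L = len(fb)
    if mode == "periodic":
        if x.size % 2:
            x = np.concatenate([x, x[-1:]])
        n = x.size
        ks = np.arange(n // 2)
        ca = np.zeros(n // 2)
        cd = np.zeros(n // 2)
        for j in range(L):
            seg = x[(2 * ks - j + L // 2) % n]
            ca += fb.lo_d[j] * seg
            cd += fb.hi_d[j] * seg
        return ca, cd
    if mode == "symmetric":
        ext = np.pad(x, L - 1, mode="symmetric")
        return (
            np.convolve(ext, fb.lo_d, "valid")[1::2],
            np.convolve(ext, fb.hi_d, "valid")[1::2],
        )
    raise ValueError(f"unknown boundary mode {mode!r}; supported: {MODES}")


def _idwt_step(
    ca: np.ndarray, cd: np.ndarray, fb: WaveletFilterBank, mode: str, n_out: int
) -> np.ndarray:
    if len(ca) != len(cd):
        raise ValueError(f"coefficient length mismatch: {len(ca)} vs {len(cd)}")
    L = len(fb)
    if mode == "periodic":
        n = 2 * len(ca)
        ks = np.arange(len(ca))
        x = np.zeros(n)
        for j in range(L):  # transpose of the analysis operator
            idx = (2 * ks - j + L // 2) % n
            np.add.at(x, idx, fb.lo_d[j] * ca + fb.hi_d[j] * cd)
        return x[:n_out]
    if mode == "symmetric":
        up_a = np.zeros(2 * len(ca))
        up_a[::2] = ca
        up_d = np.zeros(2 * len(cd))
        up_d[::2] = cd
        y = np.convolve(up_a, fb.lo_r, "full") + np.convolve(up_d, fb.hi_r, "full")
        start = L - 2 if L > 2 else 0
        return y[start : start + n_out]
    raise ValueError(f"unknown boundary mode {mode!r}; supported: {MODES}")


def dwt_decompose(
    signal: np.ndarray,
    fb: WaveletFilterBank,
    levels: int,
    mode: str = "symmetric",
) -> DWTDecomposition:
    """Multilevel Mallat decomposition of a 1-D signal.

    Requires the running approximation to stay at least as long as the
    filter at every level; a too-deep request reports the maximum feasible
    depth for this signal/filter combination.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if mode not in MODES:
        raise ValueError(f"unknown boundary mode {mode!r}; supported: {MODES}")
    L = len(fb)

    # maximum depth check: simulate the length cascade
    n, feasible = x.size, 0
    while n >= L and feasible < levels:
        n = (n + 1) // 2 if mode == "periodic" else (n + L - 1) // 2
        feasible += 1
    if feasible < levels:
        raise ValueError(
            f"signal of length {x.size} supports at most {feasible} level(s) "
            f"with a length-{L} filter in {mode} mode; {levels} requested"
        )

    details: list[np.ndarray] = []
    input_lengths: list[int] = []
    approx = x
    for _ in range(levels):
        input_lengths.append(approx.size)
        approx, d = _dwt_step(approx, fb, mode)
        details.append(d)
    return DWTDecomposition(
        approximation=approx,
        details=details,
        levels=levels,
        mode=mode,
        filter_bank=fb,
        original_length=x.size,
        _input_lengths=input_lengths,
    )


def idwt_reconstruct(decomposition: DWTDecomposition) -> np.ndarray:
    """Invert a multilevel decomposition; exact up to rounding in both modes."""
    approx = decomposition.approximation
    for level in range(decomposition.levels, 0, -1):
        d = decomposition.details[level - 1]
        n_out = decomposition._input_lengths[level - 1]
        approx = _idwt_step(approx, d, decomposition.filter_bank, decomposition.mode, n_out)
    return approx


def detail(decomposition: DWTDecomposition, level: int) -> np.ndarray:
    """Detail coefficients at the given level (1 = finest)."""
    if not 1 <= level <= decomposition.levels:
        raise ValueError(
            f"level {level} out of range 1..{decomposition.levels}"
        )
    return decomposition.details[level - 1]
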