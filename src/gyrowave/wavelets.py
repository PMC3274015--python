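"""Dyadic DWT decomposition and sub-band energy statistics.

The transform is the standard iterated two-channel filter bank with
periodic (circular) boundary extension, so a length-N signal yields
ceil(N/2^j) detail coefficients at level j and the same count of
approximation coefficients at the final level — for N = 1,600 and levels
up to 5 exactly N/2^j.  Filters come from PyWavelets; the sub-band energy
statistics built on top of them live here:

* total coefficient energy  E_T = A_i A_i' + sum_j D_j D_j'
* energy distribution ratios  EDR_A = ||A_i||^2 / E_T,
  EDR_Dj = ||D_j||^2 / E_T  (nonnegative, summing to one)
* per-vector means/variances and summary statistics of the EDR_Dj list.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt

__all__ = [
    "FAMILY_ORDERS",
    "PYWT_PREFIX",
    "WaveletSpec",
    "get_wavelet",
    "parse_wavelet",
    "iter_catalogue",
    "WaveletDecomposition",
    "coeff_lengths",
    "dwt_decompose",
    "idwt_reconstruct",
    "total_energy",
    "edr",
    "CoeffStats",
    "coeff_stats",
]

_BIOR_ORDERS = ("1.1", "1.3", "1.5", "2.2", "2.4", "2.6", "2.8",
                "3.1", "3.3", "3.5", "3.7", "3.9", "4.4", "5.5", "6.8")

#: Supported (family -> orders) catalogue.  ``None`` marks a single-member
#: family without an order parameter.
FAMILY_ORDERS: dict[str, tuple] = {
    "haar": (None,),
    "daubechies": tuple(range(2, 33)),
    "symlet": tuple(range(2, 9)),
    "coiflet": tuple(range(1, 6)),
    "biorthogonal": _BIOR_ORDERS,
    "reverse_biorthogonal": _BIOR_ORDERS,
    "discrete_meyer": (None,),
}

PYWT_PREFIX = {
    "haar": "haar",
    "daubechies": "db",
    "symlet": "sym",
    "coiflet": "coif",
    "biorthogonal": "bior",
    "reverse_biorthogonal": "rbio",
    "discrete_meyer": "dmey",
}

_ORTHOGONAL = {"haar", "daubechies", "symlet", "coiflet", "discrete_meyer"}


def _catalogue_text() -> str:
    parts = []
    for fam, orders in FAMILY_ORDERS.items():
        if orders == (None,):
            parts.append(fam)
        else:
            parts.append(f"{fam} orders {', '.join(str(o) for o in orders)}")
    return "; ".join(parts)


@dataclass(frozen=True)
class WaveletSpec:
    """One catalogued wavelet: filters plus its headline properties.

    ``support_width`` is the pair (decomposition, reconstruction).  For the
    orthogonal families it equals filter length − 1 on both sides; for the
    spline biorthogonal families it follows the order-based convention
    (bior M.N -> (2M+1, 2N+1); the reverse family swaps the two), matching
    how these widths are conventionally tabulated.
    """

    family: str
    order: int | str | None
    name: str  # PyWavelets name
    dec_lo: np.ndarray
    dec_hi: np.ndarray
    rec_lo: np.ndarray
    rec_hi: np.ndarray
    orthogonal: bool

    @property
    def support_width(self) -> tuple[int, int]:
        if self.family in ("biorthogonal", "reverse_biorthogonal"):
            m, n = (int(v) for v in str(self.order).split("."))
            if self.family == "reverse_biorthogonal":
                return (2 * n + 1, 2 * m + 1)
            return (2 * m + 1, 2 * n + 1)
        return (len(self.dec_lo) - 1, len(self.rec_lo) - 1)

    @property
    def vanishing_moments(self) -> int:
        return pywt.Wavelet(self.name).vanishing_moments_psi

    def filter_bank(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (self.dec_lo, self.dec_hi, self.rec_lo, self.rec_hi)


def _pywt_name(family: str, order) -> str:
    prefix = PYWT_PREFIX[family]
    if order is None:
        return prefix
    return f"{prefix}{order}"


@lru_cache(maxsize=None)
def get_wavelet(family: str, order: int | str | None = None) -> WaveletSpec:
    """Look up one wavelet of the supported catalogue.

    ``order`` is family-specific (e.g. 16 for daubechies, "3.1" for the
    biorthogonal families) and must be omitted for haar / discrete_meyer.
    """
    if family not in FAMILY_ORDERS:
        raise ValueError(
            f"unknown wavelet family {family!r}; catalogue: {_catalogue_text()}")
    orders = FAMILY_ORDERS[family]
    if orders != (None,):
        order = str(order) if family.endswith("biorthogonal") else order
        if isinstance(order, str) and family in ("daubechies", "symlet", "coiflet"):
            order = int(order)
    if order not in orders:
        raise ValueError(
            f"unsupported order {order!r} for family {family!r}; "
            f"catalogue: {_catalogue_text()}")
    w = pywt.Wavelet(_pywt_name(family, order))
    return WaveletSpec(
        family=family,
        order=order,
        name=w.name,
        dec_lo=np.asarray(w.dec_lo),
        dec_hi=np.asarray(w.dec_hi),
        rec_lo=np.asarray(w.rec_lo),
        rec_hi=np.asarray(w.rec_hi),
        orthogonal=family in _ORTHOGONAL,
    )


def parse_wavelet(name: str) -> WaveletSpec:
    """Parse a short name such as ``db16``, ``rbio3.1``, ``haar``, ``dmey``."""
    name = name.strip().lower()
    for family, prefix in sorted(PYWT_PREFIX.items(),
                                 key=lambda kv: -len(kv[1])):
        if name == prefix and FAMILY_ORDERS[family] == (None,):
            return get_wavelet(family)
        if name.startswith(prefix) and len(name) > len(prefix):
            tail = name[len(prefix):]
            order = tail if "." in tail else (int(tail) if tail.isdigit() else tail)
            return get_wavelet(family, order)
    raise ValueError(f"cannot parse wavelet name {name!r}; "
                     f"catalogue: {_catalogue_text()}")


def iter_catalogue(families=None):
    """Yield every catalogued :class:`WaveletSpec` (optionally one family)."""
    names = FAMILY_ORDERS if families is None else families
    for family in names:
        for order in FAMILY_ORDERS[family]:
            yield get_wavelet(family, order)


# --------------------------------------------------------------------------
# decomposition
# --------------------------------------------------------------------------

def coeff_lengths(n_samples: int, level: int) -> tuple[int, list[int]]:
    """(len(A_level), [len(D_1), ..., len(D_level)]) under ceil-halving."""
    detail = []
    cur = int(n_samples)
    for _ in range(level):
        cur = math.ceil(cur / 2)
        detail.append(cur)
    return detail[-1], detail


@dataclass
class WaveletDecomposition:
    """Approximation vector A_level plus detail vectors D_1..D_level."""

    approx: np.ndarray
    details: list[np.ndarray]  # details[j-1] = D_j
    level: int
    n_samples: int
    wavelet: WaveletSpec

    def coefficient_vectors(self) -> list[np.ndarray]:
        """All vectors in the order (A_level, D_1, ..., D_level)."""
        return [self.approx, *self.details]


def dwt_decompose(x, wavelet: WaveletSpec, level: int) -> WaveletDecomposition:
    """Iterated analysis filter bank with periodic boundary extension."""
    if level < 1:
        raise ValueError("decomposition level must be >= 1")
    if level > 8:
        raise ValueError("decomposition level must be <= 8")
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("dwt_decompose expects a one-dimensional signal")
    with warnings.catch_warnings():
        # deep levels on short signals are intentional here
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet.name, mode="periodization", level=level)
    approx = coeffs[0]
    details = list(reversed(coeffs[1:]))  # D_1 first
    return WaveletDecomposition(approx=approx, details=details, level=level,
                                n_samples=len(x), wavelet=wavelet)


def idwt_reconstruct(decomp: WaveletDecomposition,
                     wavelet: WaveletSpec | None = None) -> np.ndarray:
    """Synthesis filter bank; inverts :func:`dwt_decompose`."""
    wavelet = wavelet or decomp.wavelet
    _, expected = coeff_lengths(decomp.n_samples, decomp.level)
    got = [len(d) for d in decomp.details]
    if got != expected or len(decomp.approx) != expected[-1]:
        raise ValueError(
            f"inconsistent coefficient lengths {got} (approx {len(decomp.approx)}); "
            f"expected details {expected} for {decomp.n_samples} samples "
            f"at level {decomp.level}")
    coeffs = [decomp.approx, *reversed(decomp.details)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        out = pywt.waverec(coeffs, wavelet.name, mode="periodization")
    return out[: decomp.n_samples]


# --------------------------------------------------------------------------
# energy statistics
# --------------------------------------------------------------------------

def total_energy(decomp: WaveletDecomposition) -> float:
    """Total coefficient energy over A_level and all D_j (sum of squares)."""
    return float(sum(float(v @ v) for v in decomp.coefficient_vectors()))


def edr(decomp: WaveletDecomposition) -> np.ndarray:
    """Energy distribution ratios [EDR_A, EDR_D1, ..., EDR_Dlevel].

    Each entry is that vector's energy divided by the total energy; the
    entries are nonnegative and sum to one.  Raises on an all-zero
    decomposition, where the ratios are undefined.
    """
    energies = np.array([float(v @ v) for v in decomp.coefficient_vectors()])
    e_total = energies.sum()
    if e_total <= 0.0:
        raise ValueError("energy distribution ratios are undefined for a "
                         "zero-energy segment")
    return energies / e_total


@dataclass(frozen=True)
class CoeffStats:
    """Per-vector means/variances plus summary statistics of the EDR_Dj list.

    ``means``/``variances`` are ordered (A_level, D_1, ..., D_level); the
    variances use the unbiased (n−1) denominator.  The EDR summary (min,
    max, mean, variance over {EDR_Dj}) uses the population variance so a
    single-entry list (level 1) yields variance 0.
    """

    means: np.ndarray
    variances: np.ndarray
    edr_d_min: float
    edr_d_max: float
    edr_d_mean: float
    edr_d_var: float


def coeff_stats(decomp: WaveletDecomposition) -> CoeffStats:
    vectors = decomp.coefficient_vectors()
    for v in vectors:
        if len(v) < 2:
            raise ValueError("variance needs at least two coefficients per "
                             f"vector; got a vector of length {len(v)}")
    means = np.array([float(np.mean(v)) for v in vectors])
    variances = np.array([float(np.var(v, ddof=1)) for v in vectors])
    edr_d = edr(decomp)[1:]
    return CoeffStats(
        means=means,
        variances=variances,
        edr_d_min=float(edr_d.min()),
        edr_d_max=float(edr_d.max()),
        edr_d_mean=float(edr_d.mean()),
        edr_d_var=float(np.var(edr_d)),
    )
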