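"""Feature extractors for condensed protein profiles.

The primary descriptor is the "local energy" of the 2-D discrete
analytic signal: the condensed 20x20 profile is extended to a complex
matrix whose spectrum occupies a single frequency orthant (the 2-D
discrete Hilbert transform, DHT), and the element-wise modulus is
flattened into a 400-dimensional vector.  Comparator descriptors (DCT,
FFT modulus, single-level Haar DWT, per-column auto-covariance) share
the same interface.

The analytic-signal construction is the frequency-domain one: take the
DFT, zero the negative-frequency half (doubling the positive half,
keeping DC and Nyquist), and invert.  The real part of the result equals
the input and the imaginary part is its Hilbert transform.  The 2-D
version applies the separable single-orthant mask h(u)h(v), which is
identical to running the 1-D transform along every column and then
every row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import fft as sfft

from .io_formats import Profile
from .profiles import CondensedMatrix

_DESCRIPTOR_KINDS = ("dht", "dct", "fft", "dwt", "ac")


@dataclass
class AnalyticMatrix:
    """The 2-D discrete analytic signal of a condensed profile."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != (20, 20):
            raise ValueError(f"analytic matrix must be 20x20, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("analytic matrix contains non-finite entries")


@dataclass
class ProteinDescriptor:
    """A fixed-length real feature vector for one protein."""

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.kind not in _DESCRIPTOR_KINDS:
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        if self.kind in ("dht", "dct", "fft") and self.values.size != 400:
            raise ValueError(
                f"{self.kind} descriptor must have 400 entries, got {self.values.size}"
            )

    @property
    def dim(self) -> int:
        return self.values.size


def _analytic_mask(n: int) -> np.ndarray:
    """One-sided spectral mask h: h(0)=1, h(k)=2 for 0<k<n/2, h(n/2)=1
    for even n, h(k)=0 for k>n/2."""
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[1 : (n + 1) // 2] = 2.0
    return h


def dht1(x: np.ndarray, n: int | None = None) -> np.ndarray:
    """1-D discrete analytic signal of a real vector.

    ``n`` pads with zeros / truncates the input before transforming
    (defaults to the input length).  Complex input has its imaginary
    part discarded with a warning.
    """
    x = np.asarray(x)
    if np.iscomplexobj(x):
        warnings.warn("dht1 ignores the imaginary part of complex input")
        x = x.real
    x = np.asarray(x, dtype=float).ravel()
    if n is None:
        n = x.size
    if n < 1:
        raise ValueError("n must be >= 1")
    if x.size < n:
        x = np.pad(x, (0, n - x.size))
    elif x.size > n:
        x = x[:n]
    return np.fft.ifft(np.fft.fft(x) * _analytic_mask(n))


def dht2(M: CondensedMatrix | np.ndarray) -> AnalyticMatrix:
    """2-D discrete analytic signal of a 20x20 real matrix.

    Uses the separable single-orthant mask h(u)h(v); equivalent to
    applying :func:`dht1` to every column and then every row.
    """
    values = M.values if isinstance(M, CondensedMatrix) else np.asarray(M, dtype=float)
    if values.shape != (20, 20):
        raise ValueError(f"dht2 expects a 20x20 matrix, got {values.shape}")
    h = _analytic_mask(20)
    spectrum = np.fft.fft2(values) * np.outer(h, h)
    return AnalyticMatrix(values=np.fft.ifft2(spectrum))


def dht_features(
    M: CondensedMatrix | np.ndarray, energy: str = "modulus"
) -> ProteinDescriptor:
    """400-d local-energy descriptor: |analytic signal| flattened row-major.

    ``energy='squared'`` uses the squared modulus instead.
    """
    amplitude = np.abs(dht2(M).values)
    if energy == "squared":
        amplitude = amplitude**2
    elif energy != "modulus":
        raise ValueError(f"unknown energy mode {energy!r}")
    return ProteinDescriptor(values=amplitude.ravel(), kind="dht")


def alt_features(
    obj: CondensedMatrix | Profile | np.ndarray,
    kind: str,
    ac_lag: int = 5,
) -> ProteinDescriptor:
    """Comparator descriptors: ``dct``, ``fft``, ``dwt`` on a 20x20
    condensed matrix; ``ac`` on the pre-condensation U x 20 profile.

    * dct: 2-D DCT-II coefficients, row-major flatten (400-d).
    * fft: modulus of the 2-D DFT, row-major flatten (400-d).
    * dwt: single-level 2-D Haar decomposition; the four 10x10 subbands
      (approximation, horizontal, vertical, diagonal) concatenated (400-d).
    * ac: per-column auto-covariance at lags 1..g,
      AC(j,g) = (1/(U-g)) * sum_t (P[t,j]-mean_j)(P[t+g,j]-mean_j),
      ordered column-major by amino acid then lag (20*g-d).
    """
    if kind == "ac":
        P = obj.values if isinstance(obj, Profile) else np.asarray(obj, dtype=float)
        if P.ndim != 2 or P.shape[1] != 20:
            raise ValueError("ac expects a U x 20 profile")
        U = P.shape[0]
        if U <= ac_lag:
            raise ValueError(
                f"profile has {U} rows; auto-covariance needs more rows than the "
                f"maximum lag ({ac_lag}) — use a smaller lag"
            )
        centered = P - P.mean(axis=0)
        feats = np.empty((20, ac_lag))
        for g in range(1, ac_lag + 1):
            feats[:, g - 1] = (centered[:-g] * centered[g:]).sum(axis=0) / (U - g)
        return ProteinDescriptor(values=feats.ravel(), kind="ac")

    values = (
        obj.values if isinstance(obj, CondensedMatrix) else np.asarray(obj, dtype=float)
    )
    if values.shape != (20, 20):
        raise ValueError(f"{kind} expects a 20x20 condensed matrix")
    if kind == "dct":
        coeffs = sfft.dctn(values, type=2, norm="ortho")
        return ProteinDescriptor(values=coeffs.ravel(), kind="dct")
    if kind == "fft":
        return ProteinDescriptor(values=np.abs(np.fft.fft2(values)).ravel(), kind="fft")
    if kind == "dwt":
        cA, (cH, cV, cD) = pywt.dwt2(values, "haar")
        return ProteinDescriptor(
            values=np.concatenate([cA.ravel(), cH.ravel(), cV.ravel(), cD.ravel()]),
            kind="dwt",
        )
    raise ValueError(f"unknown descriptor kind {kind!r}")


def extract_descriptor(
    profile: Profile,
    kind: str = "dht",
    condense_mode: str = "crossproduct",
    energy: str = "modulus",
    ac_lag: int = 5,
) -> ProteinDescriptor:
    """Profile -> descriptor convenience: condenses (except for ``ac``)
    and dispatches to the configured extractor."""
    from .profiles import condense

    if kind == "ac":
        return alt_features(profile, "ac", ac_lag=ac_lag)
    M = condense(profile, mode=condense_mode)
    if kind == "dht":
        return dht_features(M, energy=energy)
    return alt_features(M, kind)
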