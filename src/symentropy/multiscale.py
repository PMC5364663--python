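"""Multiscale entropy (MSE): coarse-graining plus sample entropy.

Sample entropy follows the standard definition: with templates of length m
drawn from the first N − m positions, B counts template pairs (i < j) whose
Chebyshev distance is within the tolerance r, A counts the same pairs at
length m + 1, and SampEn = −ln(A/B).  Self-matches are excluded.  When either
count is zero the estimate is undefined and reported as NaN, never silently
zero.

The MSE curve evaluates sample entropy on successively coarse-grained
versions of the signal (non-overlapping window means of width τ), holding r
fixed at ``r_frac`` times the population SD of the original, scale-1 series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import Segment

__all__ = ["MSEParams", "MSECurve", "coarse_grain", "sample_entropy", "mse_curve"]


@dataclass(frozen=True)
class MSEParams:
    """Template length m, tolerance fraction r_frac (of the original SD) and
    the scale grid."""

    m: int = 1
    r_frac: float = 0.25
    scales: Sequence[int] = tuple(range(1, 21))

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("template length m must be >= 1")
        if not self.r_frac > 0:
            raise ValueError("r_frac must be > 0")
        scales = tuple(int(s) for s in self.scales)
        if not scales or scales[0] < 1 or any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError("scales must be >= 1 and strictly increasing")
        object.__setattr__(self, "scales", scales)


@dataclass(frozen=True)
class MSECurve:
    """Sample entropy per scale; undefined entries are NaN."""

    scales: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        scales = np.asarray(self.scales, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if scales.shape != values.shape:
            raise ValueError("scales and values must have matching length")
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "values", values)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def _as_array(segment: Union[Segment, Sequence[float], np.ndarray]) -> np.ndarray:
    return segment.samples if isinstance(segment, Segment) else np.asarray(segment, float)


def coarse_grain(segment: Union[Segment, Sequence[float], np.ndarray],
                 tau: int) -> np.ndarray:
    """Non-overlapping window means of width τ; output length floor(N/τ)."""
    x = _as_array(segment)
    if tau < 1:
        raise ValueError("scale tau must be >= 1")
    if tau > x.size:
        raise ValueError(f"scale tau={tau} exceeds series length {x.size}")
    n = x.size // tau
    return x[: n * tau].reshape(n, tau).mean(axis=1)


def _count_pairs_within(templates: np.ndarray, r: float, block: int = 512) -> int:
    """Number of template pairs (i < j) with Chebyshev distance <= r."""
    nt = templates.shape[0]
    total = 0
    for i0 in range(0, nt, block):
        chunk = templates[i0 : i0 + block]
        # distances to all templates from i0 onward; mask keeps j > i
        d = np.abs(chunk[:, None, :] - templates[None, i0:, :]).max(axis=-1)
        within = d <= r
        rows = np.arange(chunk.shape[0])[:, None]
        cols = np.arange(within.shape[1])[None, :]
        total += int(np.count_nonzero(within & (cols > rows)))
    return total


def sample_entropy(segment: Union[Segment, Sequence[float], np.ndarray],
                   m: int = 1, r: float = 0.2) -> float:
    """SampEn(m, r) in nats; NaN when no template pairs match at either
    length (undefined estimate, common for short or widely-spread series)."""
    x = _as_array(segment)
    if not r > 0:
        raise ValueError("tolerance r must be > 0")
    if x.size <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {x.size}")
    nt = x.size - m  # templates considered at both lengths
    xm = sliding_window_view(x, m)[:nt]
    xm1 = sliding_window_view(x, m + 1)
    b = _count_pairs_within(np.ascontiguousarray(xm), r)
    if b == 0:
        return math.nan
    a = _count_pairs_within(np.ascontiguousarray(xm1), r)
    if a == 0:
        return math.nan
    return -math.log(a / b)


def mse_curve(segment: Union[Segment, Sequence[float], np.ndarray],
              params: MSEParams = MSEParams()) -> MSECurve:
    """Sample entropy of the coarse-grained series at every scale, with the
    tolerance fixed from the original series (r = r_frac · population SD)."""
    x = _as_array(segment)
    max_scale = max(params.scales)
    if max_scale > x.size:
        raise ValueError(f"largest scale {max_scale} exceeds series length {x.size}")
    r = params.r_frac * float(x.std())  # population SD of the scale-1 series
    if r == 0.0:
        # constant signal: any positive tolerance gives SampEn 0 at all scales
        r = np.finfo(float).tiny
    values = []
    for tau in params.scales:
        cg = coarse_grain(x, tau)
        if cg.size <= params.m + 1:
            values.append(math.nan)
        else:
            values.append(sample_entropy(cg, m=params.m, r=r))
    return MSECurve(scales=np.array(params.scales), values=np.array(values))
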