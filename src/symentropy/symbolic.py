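"""Threshold-dependent symbolic entropy of amplitude time series.

The analysis chain is:

1. **Symbolization** — each sample of a series ``T = {T_i}`` is mapped to a
   binary symbol by comparing it with a threshold θ derived from the series
   mean.  The default rule sets ``s_i = 1`` iff ``T_i >= mean(T) + ξ`` where
   ξ >= 0 is the threshold offset swept by the analysis (ξ = 0 reduces to the
   plain mean threshold).  An alternative deviation rule marks samples whose
   absolute deviation from the mean reaches ξ.
2. **Word formation** — overlapping windows of L consecutive symbols
   (N − L + 1 words, moving one step at a time).
3. **Coding** — each word is mapped to a unique integer in ``[0, Ψ^L)`` by
   positional encoding with the earliest symbol most significant.
4. **Entropy** — the Shannon entropy (bits) of the code distribution, a
   finite-sample bias correction ``(C_R − 1)/(2 M ln 2)`` where ``C_R`` is the
   number of distinct observed codes, and normalization by the maximum
   attainable corrected entropy, yielding the normalized corrected Shannon
   entropy NCSE ∈ [0, 1].

Two conventions for the correction denominator ``M`` are provided:
``"cardinality"`` (default) uses the alphabet size Ψ^L, ``"tokens"`` uses the
word count N − L + 1 (the classical finite-sample bias correction).  The
normalizer always uses the alphabet-saturated maximum, so NCSE stays in
[0, 1] under both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import Segment

__all__ = [
    "SymbolizationParams",
    "SymbolSeries",
    "CodeSeries",
    "WordHistogram",
    "EntropyResult",
    "NCSEProfile",
    "effective_threshold",
    "symbolize",
    "build_words",
    "encode_words",
    "decode_code",
    "word_histogram",
    "shannon_entropy",
    "corrected_shannon_entropy",
    "cse_max",
    "ncse",
    "ncse_from_symbols",
    "ncse_sweep",
]

Rule = Literal["ge_mean_plus_xi", "abs_dev_ge_xi"]
Convention = Literal["cardinality", "tokens"]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class SymbolizationParams:
    """Quantization level Ψ, threshold offset ξ (signal units) and rule."""

    psi: int = 2
    xi: float = 0.0
    rule: Rule = "ge_mean_plus_xi"

    def __post_init__(self) -> None:
        if self.psi < 2:
            raise ValueError("quantization level psi must be >= 2")
        if self.xi < 0:
            raise ValueError("threshold offset xi must be >= 0")
        if self.rule not in ("ge_mean_plus_xi", "abs_dev_ge_xi"):
            raise ValueError(f"unknown symbolization rule {self.rule!r}")


@dataclass(frozen=True)
class SymbolSeries:
    """Symbolized series with the mean and effective threshold it used."""

    symbols: np.ndarray
    mu: float
    theta: float
    params: SymbolizationParams

    def __post_init__(self) -> None:
        s = np.asarray(self.symbols, dtype=np.int64)
        if s.ndim != 1:
            raise ValueError("symbols must be 1-D")
        if s.size and (s.min() < 0 or s.max() >= self.params.psi):
            raise ValueError("symbols out of range [0, psi)")
        object.__setattr__(self, "symbols", s)

    def __len__(self) -> int:
        return int(self.symbols.size)


@dataclass(frozen=True)
class CodeSeries:
    """Positional integer codes of the overlapping L-symbol words."""

    codes: np.ndarray
    L: int
    psi: int

    def __post_init__(self) -> None:
        c = np.asarray(self.codes, dtype=np.int64)
        if self.L < 1:
            raise ValueError("word length L must be >= 1")
        if c.size and (c.min() < 0 or c.max() >= self.psi**self.L):
            raise ValueError("codes out of range [0, psi**L)")
        object.__setattr__(self, "codes", c)

    def __len__(self) -> int:
        return int(self.codes.size)


@dataclass(frozen=True)
class WordHistogram:
    """Code-frequency table: counts, token total M and observed-code count C_R."""

    counts: dict[int, int]
    M_tokens: int
    C_R: int
    L: int
    psi: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.M_tokens:
            raise ValueError("counts must sum to M_tokens")
        if len(self.counts) != self.C_R:
            raise ValueError("C_R must equal the number of distinct codes")
        if self.C_R > min(self.M_tokens, self.psi**self.L):
            raise ValueError("C_R exceeds min(M_tokens, psi**L)")

    @property
    def probabilities(self) -> np.ndarray:
        return np.array(list(self.counts.values()), dtype=float) / self.M_tokens


@dataclass(frozen=True)
class EntropyResult:
    """SE, CSE, CSE^max (bits) and the normalized value NCSE ∈ [0, 1]."""

    se: float
    cse: float
    cse_max: float
    ncse: float
    convention: Convention = "cardinality"


@dataclass(frozen=True)
class NCSEProfile:
    """NCSE over a grid of threshold offsets for a collection of segments.

    ``values[i, j]`` is the NCSE of segment *i* at offset ``xis[j]``;
    ``mean``/``sd`` aggregate across segments per offset.
    """

    xis: np.ndarray
    values: np.ndarray
    params: SymbolizationParams
    L: int
    mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    sd: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        xis = np.asarray(self.xis, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != xis.size:
            raise ValueError("values must be (n_segments, n_offsets)")
        if values.size and (values.min() < 0 or values.max() > 1):
            raise ValueError("NCSE values must lie in [0, 1]")
        object.__setattr__(self, "xis", xis)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mean", values.mean(axis=0))
        object.__setattr__(self, "sd", values.std(axis=0, ddof=1) if len(values) > 1
                           else np.zeros(xis.size))


def _as_samples(segment: Union[Segment, Sequence[float], np.ndarray]) -> np.ndarray:
    x = segment.samples if isinstance(segment, Segment) else np.asarray(segment, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return x


def effective_threshold(
    segment: Union[Segment, Sequence[float], np.ndarray],
    params: SymbolizationParams = SymbolizationParams(),
) -> float:
    """Threshold actually compared against: ``mean + ξ`` for the default rule,
    the band half-width ξ for the deviation rule."""
    x = _as_samples(segment)
    if params.rule == "ge_mean_plus_xi":
        return float(x.mean() + params.xi)
    return float(params.xi)


def symbolize(
    segment: Union[Segment, Sequence[float], np.ndarray],
    params: SymbolizationParams = SymbolizationParams(),
) -> SymbolSeries:
    """Map each sample to a binary symbol (Ψ = 2 rules only).

    ``ge_mean_plus_xi``: symbol 1 iff sample >= mean + ξ (ties included, no
    epsilon).  ``abs_dev_ge_xi``: symbol 1 iff |sample − mean| >= ξ.
    """
    if params.psi != 2:
        raise ValueError("binary symbolization rules require psi == 2")
    x = _as_samples(segment)
    mu = float(x.mean())
    if params.rule == "ge_mean_plus_xi":
        theta = mu + params.xi
        symbols = (x >= theta).astype(np.int64)
    else:
        theta = params.xi
        symbols = (np.abs(x - mu) >= params.xi).astype(np.int64)
    return SymbolSeries(symbols, mu=mu, theta=theta, params=params)


def build_words(symbols: Union[SymbolSeries, np.ndarray], L: int) -> np.ndarray:
    """All N − L + 1 overlapping L-symbol windows, in temporal order.

    Returns an ``(N − L + 1, L)`` integer array; row *i* is
    ``symbols[i : i + L]``.
    """
    s = symbols.symbols if isinstance(symbols, SymbolSeries) else np.asarray(symbols, np.int64)
    if L < 1:
        raise ValueError("word length L must be >= 1")
    if L > s.size:
        raise ValueError(f"word length L={L} exceeds series length {s.size}")
    return sliding_window_view(s, L).copy()


def encode_words(words: np.ndarray, psi: int = 2) -> CodeSeries:
    """Positional code of each word, earliest symbol most significant:
    ``code = Σ_k word[k] · Ψ^(L−1−k)``."""
    w = np.asarray(words, dtype=np.int64)
    if w.ndim == 1:
        w = w[None, :]
    if w.size and (w.min() < 0 or w.max() >= psi):
        raise ValueError(f"symbols must lie in [0, {psi})")
    L = w.shape[1]
    weights = psi ** np.arange(L - 1, -1, -1, dtype=np.int64)
    return CodeSeries(w @ weights, L=L, psi=psi)


def decode_code(code: int, L: int, psi: int = 2) -> np.ndarray:
    """Inverse of :func:`encode_words` for a single code."""
    if not 0 <= code < psi**L:
        raise ValueError(f"code {code} out of range for psi={psi}, L={L}")
    word = np.empty(L, dtype=np.int64)
    for k in range(L - 1, -1, -1):
        word[k] = code % psi
        code //= psi
    return word


def word_histogram(codes: Union[CodeSeries, np.ndarray], L: Optional[int] = None,
                   psi: int = 2) -> WordHistogram:
    """Exact code-occurrence counts; probabilities are count / M_tokens."""
    if isinstance(codes, CodeSeries):
        arr, L, psi = codes.codes, codes.L, codes.psi
    else:
        arr = np.asarray(codes, dtype=np.int64)
        if L is None:
            raise ValueError("L is required when passing a bare code array")
    if arr.size == 0:
        raise ValueError("empty code series")
    uniq, counts = np.unique(arr, return_counts=True)
    return WordHistogram(
        counts={int(u): int(c) for u, c in zip(uniq, counts)},
        M_tokens=int(arr.size),
        C_R=int(uniq.size),
        L=int(L),
        psi=int(psi),
    )


def shannon_entropy(hist: WordHistogram) -> float:
    """SE = −Σ p log2 p over observed codes (bits); 0·log 0 := 0."""
    p = hist.probabilities
    return float(-np.sum(p * np.log2(p)))


def corrected_shannon_entropy(hist: WordHistogram,
                              convention: Convention = "cardinality") -> float:
    """CSE = SE + (C_R − 1)/(2 M ln 2).

    ``convention`` picks M: the alphabet size Ψ^L (``"cardinality"``,
    default) or the token count N − L + 1 (``"tokens"``, the classical
    finite-sample bias correction).
    """
    M = hist.psi**hist.L if convention == "cardinality" else hist.M_tokens
    return shannon_entropy(hist) + (hist.C_R - 1) / (2.0 * M * _LN2)


def cse_max(L: int, psi: int = 2, convention: Convention = "cardinality",
            m_tokens: Optional[int] = None) -> float:
    """Maximum corrected entropy, attained by the uniform distribution over
    all Ψ^L codes: ``log2(Ψ^L) + (Ψ^L − 1)/(2 Ψ^L ln 2)``.

    The normalizer is alphabet-based under both conventions so that NCSE is
    bounded by 1; ``convention`` and ``m_tokens`` are accepted for interface
    symmetry but do not change the value.  Strictly increasing in L at
    fixed Ψ.
    """
    if L < 1 or psi < 2:
        raise ValueError("require L >= 1 and psi >= 2")
    M = psi**L
    return L * math.log2(psi) + (M - 1) / (2.0 * M * _LN2)


def ncse_from_symbols(symbols: Union[SymbolSeries, np.ndarray], L: int = 3,
                      psi: int = 2,
                      convention: Convention = "cardinality") -> EntropyResult:
    """NCSE of an already-symbolized series (words → codes → histogram →
    CSE / CSE^max)."""
    words = build_words(symbols, L)
    hist = word_histogram(encode_words(words, psi))
    se = shannon_entropy(hist)
    cse = corrected_shannon_entropy(hist, convention)
    mx = cse_max(L, psi, convention, hist.M_tokens)
    return EntropyResult(se=se, cse=cse, cse_max=mx, ncse=cse / mx,
                         convention=convention)


def ncse(segment: Union[Segment, Sequence[float], np.ndarray],
         params: SymbolizationParams = SymbolizationParams(),
         L: int = 3,
         convention: Convention = "cardinality") -> EntropyResult:
    """Normalized corrected Shannon entropy of an amplitude series.

    Runs the full chain symbolize → words → codes → histogram →
    CSE / CSE^max.  A degenerate series (single observed code, e.g. a
    constant signal) yields NCSE = 0, not an error.
    """
    x = _as_samples(segment)
    if x.size < L + 1:
        raise ValueError(f"need at least L+1={L + 1} samples, got {x.size}")
    return ncse_from_symbols(symbolize(x, params), L=L, psi=params.psi,
                             convention=convention)


def ncse_sweep(segments: Iterable[Union[Segment, np.ndarray]],
               xis: Sequence[float],
               params: SymbolizationParams = SymbolizationParams(),
               L: int = 3,
               convention: Convention = "cardinality") -> NCSEProfile:
    """NCSE of every segment at every threshold offset of an increasing,
    non-negative grid; aggregates a per-offset mean ± SD across segments."""
    xis_arr = np.asarray(list(xis), dtype=float)
    if xis_arr.size == 0:
        raise ValueError("offset grid is empty")
    if xis_arr.min() < 0:
        raise ValueError("offsets must be non-negative")
    if xis_arr.size > 1 and not np.all(np.diff(xis_arr) > 0):
        raise ValueError("offset grid must be strictly increasing")
    seg_list = list(segments)
    rows = []
    for idx, seg in enumerate(seg_list):
        x = _as_samples(seg)
        if x.size < L + 1:
            raise ValueError(f"segment {idx} too short for word length {L}")
        rows.append([
            ncse(x, replace(params, xi=float(xi)), L=L, convention=convention).ncse
            for xi in xis_arr
        ])
    return NCSEProfile(xis=xis_arr, values=np.array(rows), params=params, L=L)
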