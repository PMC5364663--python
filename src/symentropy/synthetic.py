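"""Seeded surrogate generators for every input the analysis consumes.

Signal models are deliberately simple — sinusoidal rhythms, Gaussian
broadband noise and spike-wave templates — because the symbolic analysis
consumes only amplitude statistics: what matters is the balance between
rhythmic (regular, low-entropy) and broadband (irregular, high-entropy)
content and the overall amplitude scale, not physiological realism.

Three single-channel regimes mirror the standard clinical picture:

* **healthy-like resting EEG** — scalp amplitudes of a few tens of µV, a
  moderate alpha (8–13 Hz) rhythm on top of dominant broadband activity;
  eyes-closed variants increase the alpha amplitude, eyes-open variants the
  broadband share.
* **interictal-like** — intracranial amplitudes around 100 µV: a prominent
  slow (theta) rhythm, sparse epileptiform spikes and background noise.
* **ictal-like** — hypersynchronous ~3 Hz spike-wave discharge whose
  voltages reach ~1000 µV, with low background noise.

Discrete Bernoulli/Markov symbol sources with analytically known entropies
exercise the word/entropy machinery directly.  The multichannel generator
emulates a 19-electrode eyes-closed/eyes-open resting study in which the
eyes-closed condition carries elevated occipital alpha power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

from .io import BONN_FS, MULTICHANNEL_FS, Montage, Recording, Segment, load_montage

__all__ = [
    "SyntheticSpec",
    "OCCIPITAL",
    "gen_bernoulli_symbols",
    "gen_markov_symbols",
    "gen_resting_eeg",
    "gen_interictal_like",
    "gen_ictal_like",
    "gen_multichannel_ec_eo",
]

#: electrodes carrying the elevated eyes-closed alpha rhythm
OCCIPITAL = ("O1", "O2", "P7", "P8", "Pz")

#: default segment duration (s) mirroring the single-channel corpus
#: (23.6 s at 173.61 Hz -> 4097 samples)
DEFAULT_DURATION_S = 23.6


def _n_samples(fs: float, duration_s: float) -> int:
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    return int(round(fs * duration_s))


def gen_bernoulli_symbols(q: float, n: int, seed: int) -> np.ndarray:
    """i.i.d. binary symbols with P(symbol = 1) = q; the L-word Shannon
    entropy converges to L·H(q) bits (H = binary entropy)."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return (rng.random(n) < q).astype(np.int64)


def gen_markov_symbols(transition: Sequence[Sequence[float]], n: int,
                       seed: int) -> np.ndarray:
    """Stationary two-or-more-state Markov symbol chain; started from the
    stationary distribution so L-word probabilities are exactly
    π(w_0)·Π P(w_k|w_k−1)."""
    P = np.asarray(transition, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("rows of the transition matrix must sum to 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    # stationary distribution: left eigenvector of eigenvalue 1
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    pi = np.abs(pi) / np.abs(pi).sum()
    rng = np.random.default_rng(seed)
    k = P.shape[0]
    out = np.empty(n, dtype=np.int64)
    out[0] = rng.choice(k, p=pi)
    cum = P.cumsum(axis=1)
    u = rng.random(n - 1)
    for i in range(1, n):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i - 1], side="right")
    return out


def gen_resting_eeg(alpha_amp: float = 15.0, alpha_freq: float = 10.0,
                    broadband_sd: float = 25.0, fs: float = BONN_FS,
                    duration_s: float = DEFAULT_DURATION_S, seed: int = 0,
                    label: str = "O") -> Segment:
    """Resting-state surrogate: an alpha-band sinusoid (seeded phase) plus
    Gaussian broadband noise.

    The defaults describe an eyes-open healthy scalp segment (broadband
    dominant, moderate alpha).  An eyes-closed-like segment raises
    ``alpha_amp`` (e.g. 40–50 µV) and lowers ``broadband_sd``.
    """
    if not fs > 2 * alpha_freq:
        raise ValueError("sampling rate must exceed twice the rhythm frequency")
    rng = np.random.default_rng(seed)
    n = _n_samples(fs, duration_s)
    t = np.arange(n) / fs
    phase = rng.uniform(0.0, 2.0 * math.pi)
    x = alpha_amp * np.sin(2.0 * math.pi * alpha_freq * t + phase)
    x = x + rng.normal(0.0, broadband_sd, size=n) if broadband_sd > 0 else x + 0.0
    return Segment(x, fs=fs, label=label)


def gen_interictal_like(rhythm_amp: float = 100.0, rhythm_freq: float = 5.0,
                        spike_amp: float = 300.0, spike_rate: float = 1.0,
                        background_sd: float = 20.0, fs: float = BONN_FS,
                        duration_s: float = DEFAULT_DURATION_S, seed: int = 0,
                        label: str = "N") -> Segment:
    """Seizure-free epileptogenic-zone surrogate: dominant slow rhythm,
    sparse sharp spikes, moderate background noise (amplitudes ~100 µV,
    typical of intracranial recordings)."""
    rng = np.random.default_rng(seed)
    n = _n_samples(fs, duration_s)
    t = np.arange(n) / fs
    phase = rng.uniform(0.0, 2.0 * math.pi)
    x = rhythm_amp * np.sin(2.0 * math.pi * rhythm_freq * t + phase)
    x += rng.normal(0.0, background_sd, size=n)
    n_spikes = int(duration_s * spike_rate)
    if n_spikes > 0 and spike_amp > 0:
        centers = rng.uniform(0.0, duration_s, size=n_spikes)
        width = 0.02  # 20 ms sharp transient
        for c in centers:
            sel = np.abs(t - c) < 5 * width
            x[sel] += spike_amp * np.exp(-((t[sel] - c) ** 2) / (2 * width**2))
    return Segment(x, fs=fs, label=label)


def gen_ictal_like(spike_amp: float = 1000.0, spike_rate: float = 3.0,
                   noise_sd: float = 30.0, fs: float = BONN_FS,
                   duration_s: float = DEFAULT_DURATION_S, seed: int = 0,
                   label: str = "S") -> Segment:
    """Seizure surrogate: periodic spike-wave discharge with per-cycle timing
    jitter plus low noise; peak voltages reach ``spike_amp`` (~1000 µV)."""
    if not spike_rate < fs / 4:
        raise ValueError("spike rate must be below fs/4")
    rng = np.random.default_rng(seed)
    n = _n_samples(fs, duration_s)
    t = np.arange(n) / fs
    x = rng.normal(0.0, noise_sd, size=n)
    period = 1.0 / spike_rate
    n_cycles = int(duration_s * spike_rate)
    jitter = rng.normal(0.0, 0.02 * period, size=n_cycles)
    spike_w, wave_w = 0.012, 0.06  # sharp spike then slower wave (s)
    for k in range(n_cycles):
        c = k * period + 0.5 * period + jitter[k]
        sel = (t > c - 0.3 * period) & (t < c + 0.7 * period)
        ts = t[sel]
        x[sel] += spike_amp * np.exp(-((ts - c) ** 2) / (2 * spike_w**2))
        x[sel] -= 0.35 * spike_amp * np.exp(-((ts - c - 0.15) ** 2) / (2 * wave_w**2))
    return Segment(x, fs=fs, label=label)


def gen_multichannel_ec_eo(
    n_subjects: int = 16,
    montage: Optional[Montage] = None,
    seed: int = 0,
    effect: float = 3.0,
    alpha_amp: float = 20.0,
    alpha_freq: float = 10.0,
    broadband_sd: float = 15.0,
    fs: float = MULTICHANNEL_FS,
    duration_s: float = 10.0,
) -> list[tuple[Recording, Recording]]:
    """Per subject, one eyes-closed and one eyes-open 19-channel recording.

    Eyes-closed recordings carry the occipital alpha elevation: at O1, O2,
    P7, P8 and Pz the alpha amplitude is ``effect`` times the eyes-open
    amplitude; elsewhere the conditions share the same signal model.
    ``effect = 1`` makes the two conditions statistically exchangeable (a
    null construction for calibration).  Per-subject multiplicative gains
    and all phases/noise are drawn from a single seeded stream.
    """
    if not effect >= 1.0:
        raise ValueError("effect must be >= 1 (1 = null construction)")
    if montage is None:
        montage = load_montage()
    rng = np.random.default_rng(seed)
    n = _n_samples(fs, duration_s)
    t = np.arange(n) / fs
    pairs: list[tuple[Recording, Recording]] = []
    for s in range(n_subjects):
        gain = float(rng.lognormal(mean=0.0, sigma=0.2))
        sid = f"S{s + 1:02d}"
        recs = {}
        for condition in ("EC", "EO"):
            channels = {}
            for name in montage.electrodes:
                boost = effect if (condition == "EC" and name in OCCIPITAL) else 1.0
                amp = alpha_amp * gain * boost * float(rng.lognormal(0.0, 0.1))
                phase = rng.uniform(0.0, 2.0 * math.pi)
                x = amp * np.sin(2.0 * math.pi * alpha_freq * t + phase)
                x += rng.normal(0.0, broadband_sd * gain, size=n)
                channels[name] = Segment(x, fs=fs, label=condition, electrode=name)
            recs[condition] = Recording(channels, condition=condition, subject_id=sid)
        pairs.append((recs["EC"], recs["EO"]))
    return pairs


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative, seeded description of a synthetic source; ``generate()``
    dispatches to the matching generator."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    _KINDS = ("bernoulli_symbols", "markov_symbols", "resting_eeg",
              "ictal_like", "interictal_like", "multichannel_ec_eo")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; one of {self._KINDS}")

    def generate(self):
        fn = {
            "bernoulli_symbols": gen_bernoulli_symbols,
            "markov_symbols": gen_markov_symbols,
            "resting_eeg": gen_resting_eeg,
            "ictal_like": gen_ictal_like,
            "interictal_like": gen_interictal_like,
            "multichannel_ec_eo": gen_multichannel_ec_eo,
        }[self.kind]
        return fn(**self.params, seed=self.seed)
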