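"""The 97 RNA-sequence descriptors.

84 overlapping k-mer frequencies (4 mono + 16 di + 64 tri, lexicographic
over A,C,G,U) plus 13 periodicity statistics of the discrete-Fourier
power spectrum of the purine-indicator signal (A,G -> 1; C,U -> 0,
mean-removed).  The DFT is the unnormalized forward transform; power
|X_f|^2 is taken over frequencies f = 1..floor(n/2) — the DC term is
excluded because the signal is mean-removed.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

BASES = "ACGU"
MIN_LENGTH = 10
PURINES = frozenset("AG")

KMER_FEATURE_NAMES: list[str] = [
    f"{prefix}_{''.join(kmer)}"
    for k, prefix in ((1, "mono"), (2, "di"), (3, "tri"))
    for kmer in itertools.product(BASES, repeat=k)
]

FOURIER_FEATURE_NAMES: list[str] = [
    "power_mean",
    "power_median",
    "power_max",
    "power_min",
    "power_peak_position",
    "power_std",
    "power_p25",
    "power_p50",
    "power_p75",
    "power_amplitude",
    "power_variance",
    "power_skewness",
    "power_kurtosis",
]

RNA_FEATURE_NAMES: list[str] = KMER_FEATURE_NAMES + FOURIER_FEATURE_NAMES


def validate_rna_sequence(seq: str, min_length: int = MIN_LENGTH) -> str:
    """Uppercase, map T->U, check alphabet (position named) and length."""
    seq = seq.strip().upper().replace("T", "U")
    if len(seq) < min_length:
        raise ValueError(f"RNA sequence length {len(seq)} < {min_length}")
    for i, base in enumerate(seq):
        if base not in BASES:
            raise ValueError(f"ambiguous or invalid base {base!r} at position {i}")
    return seq


def kmer_frequencies(seq: str, k: int) -> np.ndarray:
    """Overlapping k-mer frequencies in lexicographic order (sum to 1)."""
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    seq = validate_rna_sequence(seq, min_length=k)
    n_windows = len(seq) - k + 1
    index = {"".join(kmer): i for i, kmer in enumerate(itertools.product(BASES, repeat=k))}
    counts = np.zeros(4**k, dtype=float)
    for i in range(n_windows):
        counts[index[seq[i : i + k]]] += 1
    return counts / n_windows


def power_spectrum(seq: str) -> np.ndarray:
    """Power |X_f|^2 of the mean-removed purine indicator, f = 1..n//2."""
    seq = validate_rna_sequence(seq)
    signal = np.array([1.0 if b in PURINES else 0.0 for b in seq])
    signal -= signal.mean()
    spectrum = np.fft.rfft(signal)
    return np.abs(spectrum[1 : len(seq) // 2 + 1]) ** 2


def fourier_periodicity(seq: str) -> np.ndarray:
    """The 13 fixed-order statistics of the power spectrum.

    Skewness and kurtosis of a constant spectrum (e.g. a homopolymer,
    whose mean-removed signal is identically zero) are defined as 0 so
    every statistic is finite for any valid sequence.
    """
    power = power_spectrum(seq)
    mx, mn = float(power.max()), float(power.min())
    degenerate = np.isclose(mx, mn)
    if degenerate:
        skewness = kurtosis = 0.0
    else:
        skewness = float(stats.skew(power))
        kurtosis = float(stats.kurtosis(power))
    peak_position = (int(np.argmax(power)) + 1) / len(power)
    return np.array(
        [
            float(power.mean()),
            float(np.median(power)),
            mx,
            mn,
            peak_position,
            float(np.std(power, ddof=1)) if len(power) > 1 else 0.0,
            float(np.percentile(power, 25)),
            float(np.percentile(power, 50)),
            float(np.percentile(power, 75)),
            mx - mn,
            float(np.var(power, ddof=1)) if len(power) > 1 else 0.0,
            skewness,
            kurtosis,
        ],
        dtype=float,
    )


def rna_descriptors(seq: str) -> np.ndarray:
    """Compute the fixed-order 97-vector of RNA descriptors."""
    seq = validate_rna_sequence(seq)
    return np.concatenate(
        [
            kmer_frequencies(seq, 1),
            kmer_frequencies(seq, 2),
            kmer_frequencies(seq, 3),
            fourier_periodicity(seq),
        ]
    )
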