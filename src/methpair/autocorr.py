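"""Autocorrelation of chromosome-ordered difference profiles vs a permutation null.

rho(k) is the Pearson correlation between the difference sequence and itself
shifted by k positions (positional lag in CpG rank, not basepairs), computed
per chromosome and aggregated as the median — first over the chromosomes of a
pair, then over pairs.  The null band comes from profiles whose values are
randomly permuted within each chromosome, destroying order while preserving
chromosome lengths and value distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .profiles import PairProfile


class AutocorrError(ValueError):
    pass


@dataclass
class AutocorrCurve:
    """Per-chromosome and median-aggregated lag correlations for one pair."""

    lags: np.ndarray  # 1..max_lag
    per_chromosome: dict[str, np.ndarray]
    rho: np.ndarray  # median across chromosomes per lag


@dataclass
class PermutationBand:
    """Per-lag quantile bounds of the aggregated curve under permutation."""

    lags: np.ndarray
    quantiles: dict[float, np.ndarray]  # level -> per-lag bound
    median: np.ndarray  # per-lag median of permuted aggregated curves
    n_perm: int
    seed: int


def _lagged_pearson(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Exact Pearson correlation of (x_1..x_{n-k}) with (x_{1+k}..x_n) for
    k = 1..max_lag, via cumulative sums and an FFT cross-term."""
    n = len(x)
    if np.ptp(x) == 0:
        raise AutocorrError("constant sequence: correlation undefined")
    if max_lag >= n:
        raise AutocorrError(f"max_lag {max_lag} >= sequence length {n}")
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    raw = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]  # sum x_t x_{t+k}

    k = np.arange(1, max_lag + 1)
    m = (n - k).astype(float)
    s1a = cs[n - k]  # sum of first n-k values
    s1b = cs[n] - cs[k]  # sum of last n-k values
    s2a = cs2[n - k]
    s2b = cs2[n] - cs2[k]
    cov = raw[1:] - s1a * s1b / m
    va = s2a - s1a**2 / m
    vb = s2b - s1b**2 / m
    denom = np.sqrt(np.maximum(va, 0.0) * np.maximum(vb, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, cov / denom, np.nan)
    return np.clip(rho, -1.0, 1.0)


def _curve_from_sequences(
    seqs: Mapping[str, np.ndarray], max_lag: int
) -> AutocorrCurve:
    per_chrom = {}
    for chrom, x in seqs.items():
        if max_lag >= len(x):
            raise AutocorrError(
                f"max_lag {max_lag} >= length of chromosome {chrom} ({len(x)})"
            )
        per_chrom[chrom] = _lagged_pearson(np.asarray(x, float), max_lag)
    mat = np.vstack(list(per_chrom.values()))
    return AutocorrCurve(
        lags=np.arange(1, max_lag + 1),
        per_chromosome=per_chrom,
        rho=np.nanmedian(mat, axis=0),
    )


def autocorr_curve(profile: PairProfile, max_lag: int = 100) -> AutocorrCurve:
    """Lag-k Pearson autocorrelation per chromosome, median-aggregated.

    Lags start at 1; every chromosome must be longer than ``max_lag`` and
    non-constant.
    """
    if max_lag < 1:
        raise AutocorrError("lags start at 1: max_lag must be >= 1")
    return _curve_from_sequences(profile.chromosome_deltas(), max_lag)


def aggregate_median(curves: Sequence[AutocorrCurve]) -> np.ndarray:
    """Median over pairs of the per-pair aggregated curves."""
    return np.nanmedian(np.vstack([c.rho for c in curves]), axis=0)


def permutation_band(
    profiles: Sequence[PairProfile],
    max_lag: int = 100,
    n_perm: int = 1000,
    seed: int = 0,
    levels: Sequence[float] = (0.005, 0.25, 0.75, 0.995),
) -> PermutationBand:
    """Quantile band of the aggregated autocorrelation under within-chromosome
    permutation of the difference values.

    Each permutation shuffles every chromosome sequence of every profile,
    recomputes the per-pair curves and their across-pair median, and the
    requested quantiles are taken per lag over the ``n_perm`` aggregated
    curves.
    """
    if n_perm < 1:
        raise AutocorrError("n_perm must be >= 1")
    if max_lag < 1:
        raise AutocorrError("lags start at 1: max_lag must be >= 1")
    rng = np.random.default_rng(seed)
    seq_sets = [p.chromosome_deltas() for p in profiles]
    agg = np.empty((n_perm, max_lag))
    for r in range(n_perm):
        curves = []
        for seqs in seq_sets:
            shuffled = {c: rng.permutation(x) for c, x in seqs.items()}
            curves.append(_curve_from_sequences(shuffled, max_lag))
        agg[r] = aggregate_median(curves)
    return PermutationBand(
        lags=np.arange(1, max_lag + 1),
        quantiles={lv: np.quantile(agg, lv, axis=0) for lv in levels},
        median=np.median(agg, axis=0),
        n_perm=n_perm,
        seed=seed,
    )
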