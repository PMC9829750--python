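"""Three-state Gaussian HMM for patient-matched methylation difference profiles.

States "-", "=", "+" model CpGs with decreased, unchanged and increased
methylation in the intracranial relative to the extracranial metastasis.
Training is maximum-a-posteriori Baum-Welch over all chromosome sequences of
all pair profiles jointly: Normal priors pin the emission means of the altered
states near -3/+3 (precision kappa, "scaleMeans") and inverse-gamma-type
priors stabilize the emission variances (shape alpha, "shapeSds", prior mode
equal to the configured initial SD squared).  Per-CpG states are assigned by
posterior decoding (argmax of the forward-backward marginals).

The penalized objective maximized by EM is

    log L(theta) - sum_i kappa_i (mu_i - m_i)^2 / (2 sigma_i^2)
                 - sum_i [ (alpha_i + 1) log sigma_i^2 + beta_i / sigma_i^2 ]

with beta_i = (alpha_i + 1) s_i^2 so the variance-prior mode is s_i^2.
Setting kappa_i = 0 and alpha_i = 0 removes the corresponding prior term and
the M-step reduces to plain maximum-likelihood Baum-Welch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import PairProfile

STATES = ("-", "=", "+")
N_STATES = 3

_LOG2PI = float(np.log(2.0 * np.pi))


class HMMError(ValueError):
    pass


class DegenerateStateError(HMMError):
    """A state received (numerically) zero posterior mass and has no prior
    support (kappa = 0), so its emission parameters are unidentifiable."""


def _check_simplex(p: np.ndarray, name: str, tol: float = 1e-12) -> None:
    if (p < 0).any() or abs(float(p.sum()) - 1.0) > max(tol, 1e-8):
        raise HMMError(f"{name} is not a probability simplex: {p}")


@dataclass
class HMMConfig:
    """Initialization and prior hyperparameters of the three-state model.

    ``scale_means`` (kappa) is the precision of the Normal prior on each
    state mean; ``shape_sds`` (alpha) the shape of the variance prior, with
    0 meaning a flat (absent) prior.
    """

    init_means: tuple[float, float, float] = (-3.0, 0.0, 3.0)
    init_sds: tuple[float, float, float] = (0.3, 0.5, 0.3)
    init_start: tuple[float, float, float] = (0.1, 0.8, 0.1)
    scale_means: tuple[float, float, float] = (1e6, 1e3, 1e6)
    shape_sds: tuple[float, float, float] = (5e5, 10.0, 5e5)
    init_trans_row: tuple[float, float, float] = (0.1, 0.8, 0.1)
    max_iter: int = 500
    tol: float = 1e-4
    variance_floor: float = 1e-6

    def validate(self) -> None:
        start = np.asarray(self.init_start, dtype=float)
        _check_simplex(start, "init_start")
        _check_simplex(np.asarray(self.init_trans_row, float), "init_trans_row")
        if min(self.init_sds) <= 0:
            raise HMMError("initial SDs must be positive")
        if min(self.scale_means) < 0:
            raise HMMError("scale_means (kappa) must be >= 0")
        if min(self.shape_sds) < 0:
            raise HMMError("shape_sds (alpha) must be >= 0 (0 = flat prior)")
        if self.max_iter < 1 or self.tol <= 0:
            raise HMMError("max_iter >= 1 and tol > 0 required")


@dataclass
class HMMParams:
    """Current model: emission means/SDs, start distribution, transitions."""

    means: np.ndarray  # (3,)
    sds: np.ndarray  # (3,)
    start: np.ndarray  # (3,)
    trans: np.ndarray  # (3, 3) row-stochastic

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.start = np.asarray(self.start, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        if (self.sds <= 0).any():
            raise HMMError("emission SDs must be positive")
        _check_simplex(self.start, "start")
        for i in range(N_STATES):
            if abs(float(self.trans[i].sum()) - 1.0) > 1e-10:
                raise HMMError(f"transition row {i} does not sum to 1")

    def copy(self) -> "HMMParams":
        return HMMParams(
            self.means.copy(), self.sds.copy(), self.start.copy(), self.trans.copy()
        )


@dataclass
class StateCalls:
    """Per-CpG decoded states and posteriors for one pair profile."""

    pair_id: str
    patient_id: str
    records: pd.DataFrame
    # columns: cpg_id, chrom, pos, delta, state, gamma_minus, gamma_eq, gamma_plus

    def state_counts(self) -> dict[str, int]:
        vc = self.records["state"].value_counts()
        return {s: int(vc.get(s, 0)) for s in STATES}

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class TrainingTrace:
    """Per-iteration penalized log-likelihood and parameter snapshots."""

    penalized_loglik: list[float] = field(default_factory=list)
    params: list[HMMParams] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def init_model(config: HMMConfig) -> HMMParams:
    """Model at the configured initialization; every transition row equals
    ``init_trans_row`` (by default 0.1/0.8/0.1, mirroring the start
    distribution)."""
    config.validate()
    return HMMParams(
        means=np.asarray(config.init_means, float),
        sds=np.asarray(config.init_sds, float),
        start=np.asarray(config.init_start, float),
        trans=np.tile(np.asarray(config.init_trans_row, float), (N_STATES, 1)),
    )


# ---------------------------------------------------------------------------
# forward-backward (scaled recursions, batched over sequences)


def _batch_log_emissions(params: HMMParams, xs: np.ndarray) -> np.ndarray:
    """log N(x; mu_i, sigma_i) for a (B, T) padded observation array -> (B, T, 3)."""
    x = xs[..., None]
    var = params.sds**2
    return -0.5 * (_LOG2PI + np.log(var) + (x - params.means) ** 2 / var)


def _batch_forward_backward(
    params: HMMParams, seqs: Sequence[np.ndarray]
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Scaled forward-backward for a batch of sequences.

    Returns per-sequence posteriors gamma (T_b, 3), per-sequence summed
    transition expectations xi (3, 3), and per-sequence log-likelihoods.
    Emission densities are max-shifted per position before the scaled
    recursion, so sequences of 1e5+ CpGs are handled without underflow even
    when variances collapse.
    """
    B = len(seqs)
    lengths = np.array([len(s) for s in seqs], dtype=int)
    T = int(lengths.max())
    X = np.zeros((B, T))
    for b, s in enumerate(seqs):
        X[b, : lengths[b]] = s

    logb = _batch_log_emissions(params, X)  # (B, T, 3)
    shift = logb.max(axis=2)  # (B, T)
    bprob = np.exp(logb - shift[:, :, None])
    # padded region: uninformative emissions, no contribution to anything read
    for b in range(B):
        bprob[b, lengths[b] :, :] = 1.0
        shift[b, lengths[b] :] = 0.0

    A = params.trans
    alphas = np.empty((B, T, N_STATES))
    c = np.empty((B, T))

    a = params.start[None, :] * bprob[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alphas[:, 0, :] = a / c[:, 0][:, None]
    for t in range(1, T):
        a = (alphas[:, t - 1, :] @ A) * bprob[:, t, :]
        ct = a.sum(axis=1)
        c[:, t] = ct
        alphas[:, t, :] = a / ct[:, None]

    if not np.all(np.isfinite(c)) or (c <= 0).any():
        raise HMMError("forward recursion underflow/overflow")

    logliks = np.empty(B)
    for b in range(B):
        L = lengths[b]
        logliks[b] = float(np.log(c[b, :L]).sum() + shift[b, :L].sum())

    # backward + posteriors + transition expectations
    gam = np.empty((B, T, N_STATES))
    xi_sum = np.zeros((B, N_STATES, N_STATES))
    beta = np.ones((B, N_STATES))
    last = lengths - 1
    gam[np.arange(B), last, :] = alphas[np.arange(B), last, :]  # beta = 1 at end
    for t in range(T - 2, -1, -1):
        bb = bprob[:, t + 1, :] * beta  # (B, 3)
        xi_t = alphas[:, t, :, None] * A[None, :, :] * bb[:, None, :]
        xi_t /= c[:, t + 1][:, None, None]
        beta_new = (bb @ A.T) / c[:, t + 1][:, None]
        active = t < last
        xi_sum += xi_t * active[:, None, None]
        gam[:, t, :] = np.where(
            active[:, None], alphas[:, t, :] * beta_new, gam[:, t, :]
        )
        beta = np.where(active[:, None], beta_new, beta)
        # restart sequences whose true end is position t
        ended = last == t
        if ended.any():
            beta[ended] = 1.0
            gam[ended, t, :] = alphas[ended, t, :]

    gammas = []
    for b in range(B):
        g = gam[b, : lengths[b], :]
        g /= g.sum(axis=1, keepdims=True)
        gammas.append(g)
    xis = [xi_sum[b] for b in range(B)]
    return gammas, xis, logliks


def forward_backward(
    params: HMMParams, sequence: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact posterior marginals for one observation sequence.

    Returns (gamma, xi, loglik): gamma[t, i] is the posterior probability of
    state i at position t, xi[i, j] the expected number of i->j transitions
    summed over positions, and loglik the log marginal likelihood.
    """
    x = np.asarray(sequence, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise HMMError("observation sequence must be non-empty and 1-D")
    if not np.all(np.isfinite(x)):
        idx = int(np.flatnonzero(~np.isfinite(x))[0])
        raise HMMError(f"non-finite observation at index {idx}")
    gammas, xis, logliks = _batch_forward_backward(params, [x])
    return gammas[0], xis[0], float(logliks[0])


# ---------------------------------------------------------------------------
# MAP Baum-Welch


def _log_prior(params: HMMParams, config: HMMConfig) -> float:
    kappa = np.asarray(config.scale_means, float)
    alpha = np.asarray(config.shape_sds, float)
    m = np.asarray(config.init_means, float)
    s2 = np.asarray(config.init_sds, float) ** 2
    var = params.sds**2
    lp = 0.0
    mask_k = kappa > 0
    lp -= float(np.sum(kappa[mask_k] * (params.means[mask_k] - m[mask_k]) ** 2
                       / (2.0 * var[mask_k])))
    mask_a = alpha > 0
    beta = (alpha + 1.0) * s2
    lp -= float(np.sum((alpha[mask_a] + 1.0) * np.log(var[mask_a])
                       + beta[mask_a] / var[mask_a]))
    return lp


def _relabel_sorted(params: HMMParams) -> HMMParams:
    """Reorder states so the trained means satisfy mu(-) < mu(=) < mu(+)."""
    order = np.argsort(params.means)
    if (order == np.arange(N_STATES)).all():
        return params
    return HMMParams(
        means=params.means[order],
        sds=params.sds[order],
        start=params.start[order],
        trans=params.trans[np.ix_(order, order)],
    )


def map_baum_welch(
    config: HMMConfig, sequences: Sequence[np.ndarray]
) -> tuple[HMMParams, TrainingTrace]:
    """Joint MAP Baum-Welch training over all chromosome sequences.

    Every sequence (each chromosome of each pair profile) shares one
    parameter set; the start distribution applies independently at each
    sequence start.  Iteration stops when the relative change of the
    penalized log-likelihood drops below ``config.tol`` or after
    ``config.max_iter`` iterations (in which case the trace is flagged
    non-converged rather than raising).
    """
    config.validate()
    seqs = [np.asarray(s, dtype=float) for s in sequences]
    if len(seqs) == 0:
        raise HMMError("at least one observation sequence required")
    for s in seqs:
        if len(s) == 0:
            raise HMMError("empty observation sequence")
        if not np.all(np.isfinite(s)):
            raise HMMError("non-finite observation in training data")
    n_obs = sum(len(s) for s in seqs)
    if n_obs < 10:
        raise HMMError(f"too few observations for training ({n_obs} < 10)")

    kappa = np.asarray(config.scale_means, float)
    alpha = np.asarray(config.shape_sds, float)
    m0 = np.asarray(config.init_means, float)
    s2_0 = np.asarray(config.init_sds, float) ** 2
    beta0 = (alpha + 1.0) * s2_0

    params = init_model(config)
    trace = TrainingTrace()
    prev_obj = -np.inf

    for it in range(config.max_iter):
        gammas, xis, logliks = _batch_forward_backward(params, seqs)
        obj = float(logliks.sum()) + _log_prior(params, config)
        trace.penalized_loglik.append(obj)
        trace.params.append(params.copy())
        trace.n_iter = it + 1
        if it > 0:
            denom = abs(prev_obj) if prev_obj != 0 else 1.0
            if abs(obj - prev_obj) / denom < config.tol:
                trace.converged = True
                break
        prev_obj = obj

        # M-step
        N = np.zeros(N_STATES)
        Sx = np.zeros(N_STATES)
        Sxx = np.zeros(N_STATES)
        start_counts = np.zeros(N_STATES)
        trans_counts = np.zeros((N_STATES, N_STATES))
        for g, xi, s in zip(gammas, xis, seqs):
            N += g.sum(axis=0)
            Sx += g.T @ s
            Sxx += g.T @ (s * s)
            start_counts += g[0]
            trans_counts += xi

        if ((N < 1e-12) & (kappa == 0)).any():
            raise DegenerateStateError(
                "a state with kappa=0 received no posterior mass"
            )

        mu = (kappa * m0 + Sx) / (kappa + N)
        S = Sxx - 2.0 * mu * Sx + N * mu**2  # sum_t gamma (x - mu)^2
        S = np.maximum(S, 0.0)
        num = S + kappa * (mu - m0) ** 2
        den = N.copy()
        active = alpha > 0
        num[active] += 2.0 * beta0[active]
        den[active] += 2.0 * (alpha[active] + 1.0)
        var = np.maximum(num / np.maximum(den, 1e-300), config.variance_floor)

        start = start_counts / start_counts.sum()
        rows = trans_counts.sum(axis=1, keepdims=True)
        trans = np.where(rows > 0, trans_counts / np.where(rows > 0, rows, 1.0),
                         params.trans)

        params = HMMParams(means=mu, sds=np.sqrt(var), start=start, trans=trans)

    return _relabel_sorted(params), trace


# ---------------------------------------------------------------------------
# decoding and conformity


def posterior_decode(params: HMMParams, profile: PairProfile) -> StateCalls:
    """Assign each CpG its maximum-posterior state, per chromosome.

    An exact posterior tie is resolved to "=": no alteration is claimed
    without a posterior majority.
    """
    frames = []
    for chrom, grp in profile.records.groupby("chrom", sort=False):
        x = grp["delta"].to_numpy(dtype=float)
        gamma, _, _ = forward_backward(params, x)
        best = np.argmax(gamma, axis=1)
        # tie -> "=" (state index 1)
        top = gamma[np.arange(len(x)), best]
        tie = np.abs(gamma - top[:, None]) < 1e-12
        best = np.where(tie.sum(axis=1) > 1, 1, best)
        frames.append(
            pd.DataFrame(
                {
                    "cpg_id": grp["cpg_id"].to_numpy(),
                    "chrom": chrom,
                    "pos": grp["pos"].to_numpy(),
                    "delta": x,
                    "state": np.array(STATES)[best],
                    "gamma_minus": gamma[:, 0],
                    "gamma_eq": gamma[:, 1],
                    "gamma_plus": gamma[:, 2],
                }
            )
        )
    return StateCalls(
        pair_id=profile.pair_id,
        patient_id=profile.patient_id,
        records=pd.concat(frames, ignore_index=True),
    )


def conformity(calls_a: StateCalls, calls_b: StateCalls) -> float:
    """Percentage of shared CpGs with identical decoded states."""
    a = calls_a.records.set_index("cpg_id")["state"]
    b = calls_b.records.set_index("cpg_id")["state"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise HMMError("no shared CpGs between the two call sets")
    return 100.0 * float((a.loc[shared].to_numpy() == b.loc[shared].to_numpy()).mean())


def _exact_ranksum_p(within: np.ndarray, between: np.ndarray) -> tuple[float, float]:
    """One-sided exact p (within > between) by enumerating group assignments.

    Midranks handle ties; returns (rank-sum statistic of `within`, p)."""
    pooled = np.concatenate([within, between])
    ranks = stats.rankdata(pooled)
    n1 = len(within)
    w_obs = float(ranks[:n1].sum())
    idx = range(len(pooled))
    count = 0
    total = 0
    for comb in combinations(idx, n1):
        total += 1
        if float(ranks[list(comb)].sum()) >= w_obs - 1e-9:
            count += 1
    return w_obs, count / total


def conformity_group_test(
    within: Sequence[float], between: Sequence[float]
) -> dict[str, float]:
    """One-sided Wilcoxon rank-sum test that within-patient conformities
    exceed between-patient conformities.

    Exact enumeration for combined n <= 10, otherwise the normal
    approximation with tie correction.  Returns medians, the rank-sum
    statistic of the within group, and the one-sided p.
    """
    w = np.asarray(list(within), dtype=float)
    b = np.asarray(list(between), dtype=float)
    if len(w) == 0 or len(b) == 0:
        raise HMMError("both conformity groups must be non-empty")
    med_w = float(np.median(w))
    med_b = float(np.median(b))
    if len(np.unique(np.concatenate([w, b]))) == 1:
        import warnings

        warnings.warn("all conformities tied across both groups; p = 1")
        return {
            "median_within": med_w,
            "median_between": med_b,
            "statistic": float(stats.rankdata(np.concatenate([w, b]))[: len(w)].sum()),
            "p_value": 1.0,
        }
    if len(w) + len(b) <= 10:
        stat, p = _exact_ranksum_p(w, b)
    else:
        res = stats.mannwhitneyu(w, b, alternative="greater", method="asymptotic")
        ranks = stats.rankdata(np.concatenate([w, b]))
        stat = float(ranks[: len(w)].sum())
        p = float(res.pvalue)
    return {
        "median_within": med_w,
        "median_between": med_b,
        "statistic": float(stat),
        "p_value": float(p),
    }


# ---------------------------------------------------------------------------
# serialization


def params_to_dict(params: HMMParams, trace: TrainingTrace | None = None) -> dict:
    d = {
        "states": list(STATES),
        "means": params.means.tolist(),
        "sds": params.sds.tolist(),
        "start": params.start.tolist(),
        "trans": params.trans.tolist(),
    }
    if trace is not None:
        d["training"] = {
            "n_iter": trace.n_iter,
            "converged": trace.converged,
            "penalized_loglik_first": trace.penalized_loglik[0],
            "penalized_loglik_last": trace.penalized_loglik[-1],
        }
    return d


def params_from_dict(d: dict) -> HMMParams:
    return HMMParams(
        means=np.asarray(d["means"], float),
        sds=np.asarray(d["sds"], float),
        start=np.asarray(d["start"], float),
        trans=np.asarray(d["trans"], float),
    )
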