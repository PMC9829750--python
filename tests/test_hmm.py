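import warnings
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from methpair import (
    HMMConfig,
    SimConfig,
    conformity,
    conformity_group_test,
    forward_backward,
    init_model,
    map_baum_welch,
    posterior_decode,
    simulate_cohort,
)
from methpair.hmm import HMMError, HMMParams, StateCalls
from methpair.profiles import PairProfile


# ---------------------------------------------------------------------------
# oracles


def enumeration_oracle(params, x):
    """Posterior marginals and log-likelihood by summing over all 3^n paths."""
    n = len(x)
    logb = norm.logpdf(np.asarray(x)[:, None], params.means, params.sds)
    log_start = np.log(params.start)
    log_trans = np.log(params.trans)
    lps = []
    paths = list(product(range(3), repeat=n))
    for path in paths:
        lp = log_start[path[0]] + logb[0, path[0]]
        for t in range(1, n):
            lp += log_trans[path[t - 1], path[t]] + logb[t, path[t]]
        lps.append(lp)
    lps = np.asarray(lps)
    ll = logsumexp(lps)
    gamma = np.zeros((n, 3))
    w = np.exp(lps - ll)
    for path, wi in zip(paths, w):
        for t, s in enumerate(path):
            gamma[t, s] += wi
    return gamma, float(ll)


def ml_baum_welch_oracle(x, means, sds, start, trans, n_iter):
    """Plain maximum-likelihood Baum-Welch in log space, one sequence.

    Independent of the package's scaled batched implementation; used to pin
    the MAP M-step's reduction to ML when all priors are switched off."""
    means, sds = np.array(means, float), np.array(sds, float)
    start, trans = np.array(start, float), np.array(trans, float)
    T = len(x)
    for _ in range(n_iter):
        lb = norm.logpdf(x[:, None], means, sds)
        la = np.zeros((T, 3))
        la[0] = np.log(start) + lb[0]
        for t in range(1, T):
            la[t] = logsumexp(la[t - 1][:, None] + np.log(trans), axis=0) + lb[t]
        lbb = np.zeros((T, 3))
        for t in range(T - 2, -1, -1):
            lbb[t] = logsumexp(
                np.log(trans) + lb[t + 1][None, :] + lbb[t + 1][None, :], axis=1
            )
        ll = logsumexp(la[-1])
        g = np.exp(la + lbb - ll)
        xi = np.zeros((3, 3))
        for t in range(T - 1):
            xi += np.exp(
                la[t][:, None]
                + np.log(trans)
                + lb[t + 1][None, :]
                + lbb[t + 1][None, :]
                - ll
            )
        start = g[0] / g[0].sum()
        trans = xi / xi.sum(axis=1, keepdims=True)
        N = g.sum(axis=0)
        means = (g * x[:, None]).sum(axis=0) / N
        var = (g * (x[:, None] - means) ** 2).sum(axis=0) / N
        sds = np.sqrt(np.maximum(var, 1e-6))
    return means, sds, start, trans


def _random_params(rng):
    start = rng.dirichlet(np.ones(3))
    trans = rng.dirichlet(np.ones(3), size=3)
    means = np.sort(rng.normal(0, 3, 3))
    sds = rng.uniform(0.2, 1.5, 3)
    return HMMParams(means=means, sds=sds, start=start, trans=trans)


# ---------------------------------------------------------------------------
# initialization


def test_init_model_uses_configured_values():
    p = init_model(HMMConfig())
    assert np.allclose(p.means, (-3, 0, 3))
    assert np.allclose(p.sds, (0.3, 0.5, 0.3))
    assert np.allclose(p.start, (0.1, 0.8, 0.1))
    assert np.allclose(p.trans.sum(axis=1), 1.0)
    assert np.allclose(p.trans, np.tile([0.1, 0.8, 0.1], (3, 1)))


def test_init_model_rejects_invalid_config():
    with pytest.raises(HMMError):
        init_model(HMMConfig(init_sds=(0.3, -0.5, 0.3)))
    with pytest.raises(HMMError):
        init_model(HMMConfig(init_start=(0.5, 0.4, 0.2)))


# ---------------------------------------------------------------------------
# forward-backward


def test_single_observation_posterior_matches_bayes_rule():
    p = init_model(HMMConfig())
    gamma, xi, ll = forward_backward(p, np.array([3.0]))
    lik = p.start * norm.pdf(3.0, p.means, p.sds)
    assert np.allclose(gamma[0], lik / lik.sum(), atol=1e-12)
    assert gamma[0, 2] > 0.999
    assert np.allclose(xi, 0.0)


def test_uninformative_emissions_return_chain_marginals():
    p = HMMParams(
        means=np.zeros(3),
        sds=np.ones(3),
        start=np.array([0.1, 0.8, 0.1]),
        trans=np.tile([0.1, 0.8, 0.1], (3, 1)),
    )
    gamma, _, _ = forward_backward(p, np.array([0.3, -0.5, 1.0, 0.0]))
    # identical emission densities: posterior equals the chain marginal,
    # which here is (0.1, 0.8, 0.1) at every position
    assert np.allclose(gamma, np.tile([0.1, 0.8, 0.1], (4, 1)), atol=1e-12)


def test_forward_backward_matches_path_enumeration():
    rng = np.random.default_rng(42)
    for _ in range(10):
        p = _random_params(rng)
        n = int(rng.integers(1, 9))
        x = rng.normal(0, 2, n)
        gamma, _, ll = forward_backward(p, x)
        g0, ll0 = enumeration_oracle(p, x)
        assert np.abs(gamma - g0).max() < 1e-10
        assert abs(ll - ll0) < 1e-10


def test_forward_backward_rejects_bad_input():
    p = init_model(HMMConfig())
    with pytest.raises(HMMError):
        forward_backward(p, np.array([]))
    with pytest.raises(HMMError, match="index 1"):
        forward_backward(p, np.array([0.0, np.nan, 1.0]))


def test_gamma_rows_normalized_on_long_sequence():
    p = init_model(HMMConfig())
    x = np.random.default_rng(0).normal(0, 1.5, 100_000)
    gamma, _, ll = forward_backward(p, x)
    assert np.abs(gamma.sum(axis=1) - 1.0).max() < 1e-8
    assert np.isfinite(ll)


# ---------------------------------------------------------------------------
# MAP Baum-Welch


def test_huge_kappa_pins_altered_means():
    rng = np.random.default_rng(1)
    cfg = HMMConfig(scale_means=(1e12, 1e3, 1e12), max_iter=50)
    seqs = [rng.normal(0.5, 1.0, 500) for _ in range(3)]
    params, _ = map_baum_welch(cfg, seqs)
    assert abs(params.means[0] - (-3.0)) < 1e-3
    assert abs(params.means[2] - 3.0) < 1e-3


def test_map_reduces_to_ml_with_priors_off():
    rng = np.random.default_rng(7)
    states = rng.choice(3, size=200, p=[0.2, 0.6, 0.2])
    x = rng.normal(np.array([-3.0, 0.0, 3.0])[states], [0.4, 0.6, 0.4][1])
    cfg = HMMConfig(
        scale_means=(0.0, 0.0, 0.0),
        shape_sds=(0.0, 0.0, 0.0),
        max_iter=6,
        tol=1e-300,
    )
    params, trace = map_baum_welch(cfg, [x])
    m, s, st, tr = ml_baum_welch_oracle(
        x,
        cfg.init_means,
        cfg.init_sds,
        cfg.init_start,
        np.tile([0.1, 0.8, 0.1], (3, 1)),
        n_iter=6,
    )
    assert np.abs(params.means - m).max() < 1e-8
    assert np.abs(params.sds - s).max() < 1e-8
    assert np.abs(params.start - st).max() < 1e-8
    assert np.abs(params.trans - tr).max() < 1e-8


def test_penalized_loglik_monotone_over_seeded_runs():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        seqs = [rng.normal(0, 1.6, 400) for _ in range(4)]
        _, trace = map_baum_welch(HMMConfig(max_iter=40, tol=1e-9), seqs)
        diffs = np.diff(trace.penalized_loglik)
        assert (diffs >= -1e-8).all()


def test_parameter_recovery_from_generative_model():
    cfg_sim = SimConfig(
        n_patients=6,
        pairs_per_patient=[1] * 6,
        n_chromosomes=2,
        cpgs_per_chromosome=2000,
        pair_truth_noise=0.0,
        seed=5,
    )
    _, profiles, truth = simulate_cohort(cfg_sim)
    seqs = [x for p in profiles for x in p.chromosome_deltas().values()]
    params, trace = map_baum_welch(HMMConfig(), seqs)
    assert abs(params.means[1]) < 0.05
    assert np.abs(params.sds / np.array([0.3, 0.5, 0.3]) - 1).max() < 0.10
    # decoding accuracy on one pair
    calls = posterior_decode(params, profiles[0])
    tr = truth.states[profiles[0].pair_id]
    merged = calls.records.merge(tr, on="cpg_id", suffixes=("", "_true"))
    acc = (merged["state"] == merged["state_true"]).mean()
    assert acc >= 0.95


def test_nonconvergence_is_flagged_not_raised():
    rng = np.random.default_rng(3)
    seqs = [rng.normal(0, 1.5, 200)]
    _, trace = map_baum_welch(HMMConfig(max_iter=2, tol=1e-300), seqs)
    assert not trace.converged
    assert trace.n_iter == 2


def test_training_rejects_too_few_observations():
    with pytest.raises(HMMError):
        map_baum_welch(HMMConfig(), [np.array([1.0, 2.0])])


def test_trained_state_order_is_sorted_by_mean():
    rng = np.random.default_rng(9)
    seqs = [rng.normal(0, 2.0, 1000) for _ in range(2)]
    params, _ = map_baum_welch(HMMConfig(max_iter=30), seqs)
    assert params.means[0] < params.means[1] < params.means[2]


# ---------------------------------------------------------------------------
# decoding


def _profile_from_values(x, pair_id="p", patient="P01"):
    df = pd.DataFrame(
        {
            "cpg_id": [f"cg{i}" for i in range(len(x))],
            "chrom": "chr1",
            "pos": np.arange(1, len(x) + 1) * 10,
            "delta": x,
        }
    )
    return PairProfile(pair_id, patient, "lung", df)


def test_decode_single_cpg_high_value_is_increased():
    p = init_model(HMMConfig())
    calls = posterior_decode(p, _profile_from_values([3.0]))
    assert calls.records["state"].tolist() == ["+"]


def test_decode_tie_resolves_to_unchanged():
    # symmetric model, observation 0 between the two altered states:
    # gamma(-) == gamma(+) while "=" is excluded by a far-away mean
    p = HMMParams(
        means=np.array([-1.0, 50.0, 1.0]),
        sds=np.array([1.0, 1.0, 1.0]),
        start=np.array([0.45, 0.1, 0.45]),
        trans=np.tile([0.45, 0.1, 0.45], (3, 1)),
    )
    calls = posterior_decode(p, _profile_from_values([0.0]))
    assert calls.records["state"].tolist() == ["="]


def test_decode_uninformative_emissions_follow_chain_prior():
    p = HMMParams(
        means=np.zeros(3),
        sds=np.ones(3),
        start=np.array([0.1, 0.8, 0.1]),
        trans=np.tile([0.1, 0.8, 0.1], (3, 1)),
    )
    calls = posterior_decode(p, _profile_from_values([0.5, -0.5, 0.1, 2.0]))
    assert (calls.records["state"] == "=").all()


# ---------------------------------------------------------------------------
# conformity


def _calls_from_states(states, pair_id="a"):
    df = pd.DataFrame(
        {
            "cpg_id": [f"cg{i}" for i in range(len(states))],
            "chrom": "chr1",
            "pos": np.arange(1, len(states) + 1),
            "delta": 0.0,
            "state": list(states),
            "gamma_minus": 0.0,
            "gamma_eq": 0.0,
            "gamma_plus": 0.0,
        }
    )
    return StateCalls(pair_id, "P01", df)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("-=+-", "-=+-", 100.0),
        ("----", "++++", 0.0),
        ("-=+-", "-=-+", 50.0),
    ],
)
def test_conformity_percentages(a, b, expected):
    assert conformity(_calls_from_states(a), _calls_from_states(b, "b")) == expected


def test_conformity_is_symmetric():
    a = _calls_from_states("-=+--=++")
    b = _calls_from_states("-=+=+=--", "b")
    assert conformity(a, b) == conformity(b, a)


def test_ranksum_exact_p_for_separated_groups():
    res = conformity_group_test([90, 89, 88], [80, 81, 82])
    assert res["p_value"] == pytest.approx(1 / 20)
    assert res["median_within"] == 89
    assert res["median_between"] == 81


def test_ranksum_no_separation_gives_large_p():
    res = conformity_group_test([1, 2, 3], [1, 2, 3])
    assert res["p_value"] >= 0.5


def test_ranksum_exact_enumeration_is_a_valid_null():
    # P(W >= w) + P(W <= w) = 1 + P(W = w): the two one-sided exact
    # p-values of the swapped test sum to 1 plus the mass at the observed
    # statistic
    within, between = [5.0, 3.0, 9.0], [4.0, 1.0, 2.0]
    p_fwd = conformity_group_test(within, between)["p_value"]
    p_rev = conformity_group_test(between, within)["p_value"]
    assert p_fwd + p_rev > 1.0
    assert p_fwd < p_rev


def test_ranksum_all_tied_warns_p_one():
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        res = conformity_group_test([5, 5], [5, 5, 5])
    assert res["p_value"] == 1.0
    assert len(w) == 1
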