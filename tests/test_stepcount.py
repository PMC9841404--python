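"""Step detection, histograms and binomial stoichiometry fits."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smcount import synthgen
from smcount.stepcount import (
    StepHistogram,
    binomial_pmf,
    build_histogram,
    compare_n,
    detect_binding,
    fit_binomial,
    fit_steps,
    truncated_binomial_pmf,
)


# ---------------------------------------------------------------------------
# independent oracle: exhaustive change-point search
# ---------------------------------------------------------------------------

def exhaustive_step_fit(y, max_cps=4, tol=1e-9):
    """Smallest change-point set that reproduces a noiseless trace exactly.

    Enumerates every change-point combination up to ``max_cps`` and returns
    the first (fewest points) whose piecewise-constant fit has SSE <= tol.
    Feasible only for short traces; serves as the ground-truth reference
    for the greedy fitter.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    for k in range(max_cps + 1):
        best = None
        for cps in itertools.combinations(range(1, n), k):
            bounds = [0, *cps, n]
            sse = sum(((y[s:e] - y[s:e].mean()) ** 2).sum()
                      for s, e in zip(bounds[:-1], bounds[1:]))
            if best is None or sse < best[0]:
                best = (sse, list(cps))
        if best is not None and best[0] <= tol:
            return best[1]
    raise AssertionError("no exact segmentation found")


def staircase(n, cps, levels):
    y = np.empty(n)
    bounds = [0, *cps, n]
    for (s, e), lv in zip(zip(bounds[:-1], bounds[1:]), levels):
        y[s:e] = lv
    return y


@st.composite
def noiseless_staircases(draw):
    n = draw(st.integers(12, 30))
    k = draw(st.integers(0, 3))
    cps = sorted(draw(st.sets(st.integers(1, n - 1), min_size=k,
                              max_size=k)))
    levels = [draw(st.integers(0, 6)) for _ in range(k + 1)]
    # adjacent plateaus must differ or the change point does not exist
    for i in range(1, len(levels)):
        if levels[i] == levels[i - 1]:
            levels[i] = levels[i - 1] + 1
    return staircase(n, cps, [float(v) for v in levels]), cps


@settings(max_examples=80, derandomize=True, deadline=None)
@given(noiseless_staircases())
def test_fit_steps_matches_exhaustive_oracle_on_noiseless_traces(case):
    y, true_cps = case
    sf = fit_steps(y)
    assert sf.change_points == exhaustive_step_fit(y) == true_cps


def test_noiseless_descending_staircase_counted_exactly():
    y = staircase(28, [5, 12, 18, 24], [0.0, 3.0, 2.0, 1.0, 0.0])
    sf = fit_steps(y)
    assert sf.change_points == [5, 12, 18, 24]
    assert sf.bind_frame == 5
    assert sf.n_bleach_steps == 3
    np.testing.assert_allclose(sf.levels, [0, 3, 2, 1, 0], atol=1e-12)


def test_constant_trace_has_no_change_points():
    sf = fit_steps(np.full(50, 7.3))
    assert sf.change_points == []
    assert sf.bind_frame is None
    assert sf.n_bleach_steps == 0


def test_short_trace_rejected():
    with pytest.raises(ValueError):
        fit_steps(np.zeros(9))


def test_binding_detection_flat_and_staircase():
    assert detect_binding(np.zeros(40)) is None
    y = staircase(60, [20], [0.0, 2.0])
    assert detect_binding(y) == 20


def test_binding_frame_recovered_on_noisy_simulations():
    """Binding jumps located within one frame on >=99% of visible traces."""
    cfg = synthgen.SimConfig()
    hits = total = 0
    for i in range(500):
        tr, truth = synthgen.simulate_photobleaching_trace(
            2, 1.0, cfg=cfg, seed=np.random.default_rng([20, i]))
        b = detect_binding(tr)
        total += 1
        hits += b is not None and abs(b - truth.bind_frame) <= 1
    assert hits / total >= 0.99


def test_dimer_traces_counted_as_two_steps():
    """m=2, all-fluorescent, noise 0.15: >=95% counted as exactly 2."""
    cfg = synthgen.SimConfig()
    exact = 0
    for i in range(1000):
        tr, _ = synthgen.simulate_photobleaching_trace(
            2, 1.0, cfg=cfg, seed=np.random.default_rng([22, i]))
        exact += fit_steps(tr).n_bleach_steps == 2
    assert exact / 1000 >= 0.95


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

def test_build_histogram_examples():
    h = build_histogram([1, 1, 2, 2])
    assert h.freqs == {1: 0.5, 2: 0.5}
    assert h.n_max == 2
    h = build_histogram([4])
    assert h.freqs == {4: 1.0} and h.n_max == 4


@pytest.mark.parametrize("bad", [[], [0, 1], [-1], [1.5]])
def test_build_histogram_rejects_invalid_counts(bad):
    with pytest.raises(ValueError):
        build_histogram(bad)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.integers(1, 8), min_size=1, max_size=200))
def test_histogram_frequencies_normalized(counts):
    h = build_histogram(counts)
    assert h.n_max == max(counts)
    assert sum(h.freqs.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# binomial model and fits
# ---------------------------------------------------------------------------

def test_binomial_pmf_values():
    assert binomial_pmf(2, 2, 1.0) == pytest.approx(1.0)
    assert binomial_pmf(1, 2, 0.5) == pytest.approx(0.5)
    # dark-complex probability of a tetramer: (1 - 0.61)^4
    assert binomial_pmf(0, 4, 0.61) == pytest.approx(0.02313441, abs=1e-8)
    with pytest.raises(ValueError):
        binomial_pmf(3, 2, 0.5)


@pytest.mark.parametrize("n", range(1, 11))
@pytest.mark.parametrize("p", [0.0, 0.25, 0.5, 0.75, 1.0])
def test_binomial_pmf_normalized(n, p):
    assert sum(binomial_pmf(k, n, p) for k in range(n + 1)) == \
        pytest.approx(1.0)


def test_truncated_pmf_renormalizes_and_handles_p_zero_limit():
    n, p = 4, 0.61
    norm = 1.0 - (1.0 - p) ** n
    for k in range(1, n + 1):
        assert truncated_binomial_pmf(k, n, p) == \
            pytest.approx(binomial_pmf(k, n, p) / norm)
    assert truncated_binomial_pmf(1, 3, 0.0) == 1.0
    assert truncated_binomial_pmf(2, 3, 0.0) == 0.0


def test_fit_binomial_self_consistent_on_exact_model_frequencies():
    """Feeding the fitter its own truncated pmf must return p exactly."""
    p_true, n = 0.63, 2
    hist = StepHistogram({k: truncated_binomial_pmf(k, n, p_true)
                          for k in range(1, n + 1)})
    fit = fit_binomial(hist, n_fixed=n, truncated=True)
    assert fit.p_hat == pytest.approx(p_true, abs=1e-6)
    assert fit.chi_sq == pytest.approx(0.0, abs=1e-10)


def test_fit_binomial_degenerate_single_bin():
    hist = StepHistogram({1: 1.0})
    fit = fit_binomial(hist, n_fixed=1, truncated=False)
    assert fit.p_hat == pytest.approx(1.0)
    assert fit.chi_sq == pytest.approx(0.0, abs=1e-12)


def test_fit_binomial_requires_n_at_least_n_max():
    hist = build_histogram([1, 2, 3])
    with pytest.raises(ValueError):
        fit_binomial(hist, n_fixed=2)


def test_fit_binomial_refinement_never_worsens_chi_sq():
    rng = np.random.default_rng(3)
    hist = build_histogram(list(rng.integers(1, 5, size=400)))
    coarse = fit_binomial(hist, n_fixed=4, refine_tol=1e-4)
    fine = fit_binomial(hist, n_fixed=4, refine_tol=1e-10)
    assert fine.chi_sq <= coarse.chi_sq + 1e-15


def test_compare_n_reports_without_selecting():
    assert len(compare_n(build_histogram([1, 2]), [])) == 0
    rng = np.random.default_rng(7)
    ks = rng.binomial(2, 0.7, size=10000)
    hist = build_histogram([int(k) for k in ks if k >= 1])
    table = compare_n(hist, [2, 3, 4])
    assert list(table["n"]) == [2, 3, 4]
    assert all(0 <= p <= 1 for p in table["p_hat"])


def _sample_truncated(rng, n, p, size):
    pmf = np.array([truncated_binomial_pmf(k, n, p)
                    for k in range(1, n + 1)])
    return rng.choice(np.arange(1, n + 1), size=size, p=pmf)


def test_mixture_rejected_by_parametric_bootstrap():
    """A dimer/tetramer mixture misfits Binomial(4, p): its chi^2 exceeds
    the 99th percentile of chi^2 under the fitted pure model."""
    rng = np.random.default_rng(11)
    n_obs = 10000
    ks = np.concatenate([_sample_truncated(rng, 2, 0.8, n_obs // 2),
                         _sample_truncated(rng, 4, 0.8, n_obs // 2)])
    fit_obs = fit_binomial(build_histogram(list(ks)), n_fixed=4)
    boots = []
    for _ in range(200):
        resamp = _sample_truncated(rng, 4, fit_obs.p_hat, n_obs)
        boots.append(fit_binomial(build_histogram(list(resamp)),
                                  n_fixed=4).chi_sq)
    assert fit_obs.chi_sq > np.percentile(boots, 99)
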