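"""Ground-truth structure and determinism of the simulators."""

import numpy as np
import pytest
from scipy import stats

from smcount import synthgen
from smcount.synthgen import (
    SimConfig,
    UnwindKinetics,
    simulate_experiment,
    simulate_field_movie,
    simulate_photobleaching_trace,
    simulate_regression_fret,
    simulate_unwinding_fret,
)


def test_simconfig_validation():
    with pytest.raises(ValueError):
        SimConfig(frame_interval=0.0)
    with pytest.raises(ValueError):
        SimConfig(n_frames=1)
    with pytest.raises(ValueError):
        SimConfig(noise_sigma=-0.1)


@pytest.mark.parametrize("sim", [
    lambda s: simulate_photobleaching_trace(3, 0.6, cfg=SimConfig(n_frames=80),
                                            seed=s),
    lambda s: simulate_unwinding_fret(SimConfig(n_frames=200), seed=s),
    lambda s: simulate_regression_fret(SimConfig(n_frames=200), seed=s),
    lambda s: simulate_field_movie(5, cfg=SimConfig(n_frames=3), seed=s,
                                   shape=(48, 48)),
])
def test_simulators_are_seed_deterministic(sim):
    a, b = sim(123), sim(123)
    flat_a = [x for x in np.ravel([np.asarray(getattr(t, "values", t))
              for t in np.atleast_1d(a[0] if not isinstance(a[0], dict)
                                     else list(a[0].values()))], order="K")]
    flat_b = [x for x in np.ravel([np.asarray(getattr(t, "values", t))
              for t in np.atleast_1d(b[0] if not isinstance(b[0], dict)
                                     else list(b[0].values()))], order="K")]
    np.testing.assert_array_equal(flat_a, flat_b)


def test_noiseless_dimer_trace_has_two_unit_steps():
    cfg = SimConfig(noise_sigma=0.0)
    tr, truth = simulate_photobleaching_trace(2, 1.0, cfg=cfg, seed=5)
    d = np.diff(tr.values)
    ups = np.flatnonzero(d > 0)
    downs = np.flatnonzero(d < 0)
    assert truth.fluorescent_count == 2
    assert len(ups) == 1 and ups[0] + 1 == truth.bind_frame
    # two downward unit steps unless both fluorophores bleach together
    assert len(downs) == len(set(truth.bleach_frames))
    assert np.allclose(np.abs(d[d != 0]) % cfg.unit_step, 0.0) or \
        np.allclose(sorted(-d[downs]), cfg.unit_step)


def test_all_dark_complex_is_flat_and_invisible():
    cfg = SimConfig(noise_sigma=0.0)
    tr, truth = simulate_photobleaching_trace(4, 0.0, cfg=cfg, seed=1)
    assert truth.fluorescent_count == 0
    assert not truth.visible
    np.testing.assert_array_equal(tr.values, cfg.background)


def test_staircase_monotone_after_binding_without_noise():
    cfg = SimConfig(noise_sigma=0.0)
    for i in range(20):
        tr, truth = simulate_photobleaching_trace(4, 0.8, cfg=cfg, seed=i)
        post = tr.values[truth.bind_frame:]
        assert np.all(np.diff(post) <= 1e-12)


def test_invalid_parameters_raise():
    with pytest.raises(ValueError):
        simulate_photobleaching_trace(2, 0.5, bleach_rate=0.0, seed=0)
    with pytest.raises(ValueError):
        simulate_photobleaching_trace(2, 1.5, seed=0)
    with pytest.raises(ValueError):
        simulate_photobleaching_trace(0, 0.5, seed=0)


def test_fluorescent_counts_follow_binomial_dark_fraction():
    """Subunit visibility over many complexes is Binomial(m, p): the dark
    fraction matches (1-p)^m and a chi^2 test does not reject at 1%."""
    m, p, n_rep = 4, 0.61, 10000
    cfg = SimConfig(n_frames=30)
    counts = np.zeros(m + 1, dtype=int)
    for i in range(n_rep):
        _, truth = simulate_photobleaching_trace(
            m, p, cfg=cfg, seed=np.random.default_rng([21, i]))
        counts[truth.fluorescent_count] += 1
    assert counts[0] / n_rep == pytest.approx((1 - p) ** m, abs=0.006)
    expected = stats.binom.pmf(np.arange(m + 1), m, p) * n_rep
    assert stats.chisquare(counts, expected).pvalue > 0.01


def test_inactive_unwinding_trace_is_static():
    cfg = SimConfig(noise_sigma=0.0, n_frames=100)
    d, a, truth = simulate_unwinding_fret(cfg, active=False, seed=3)
    e = a.values / (a.values + d.values)
    assert truth.events == [] and not truth.active
    assert np.allclose(e, e[0])


def test_unwinding_cycles_complete_and_conserve_intensity():
    cfg = SimConfig(noise_sigma=0.0)
    d, a, truth = simulate_unwinding_fret(cfg, active=True, seed=9)
    kinds = [k for k, _ in truth.events]
    starts = truth.frames_of("unwind_start")
    rewinds = truth.frames_of("rewind")
    assert len(starts) == len(rewinds) >= 2
    assert all(r > s for s, r in zip(starts, rewinds))
    # abrupt recovery: E back at the high state one frame after rewind
    e = a.values / (a.values + d.values)
    kin = UnwindKinetics()
    for r in rewinds:
        assert e[r] == pytest.approx(kin.e_high, abs=1e-9)
    np.testing.assert_allclose(d.values + a.values, cfg.unit_step,
                               atol=1e-12)


def test_regression_completion_loses_both_channels_in_same_frame():
    cfg = SimConfig(noise_sigma=0.0)
    d, a, truth = simulate_regression_fret(cfg, repetitive=False, seed=4)
    (hj,) = truth.frames_of("hj_formation")
    (diss,) = truth.frames_of("dissociation")
    assert hj < diss
    e = np.divide(a.values, a.values + d.values,
                  out=np.zeros(len(a)), where=(a.values + d.values) > 0)
    assert np.all(e[:hj] < 0.7)          # fork state below the high band
    assert d.values[diss - 1] > 0 and a.values[diss - 1] > 0
    np.testing.assert_array_equal(d.values[diss:], cfg.background)
    np.testing.assert_array_equal(a.values[diss:], cfg.background)


def test_repetitive_regression_has_cycles_but_no_dissociation():
    cfg = SimConfig(noise_sigma=0.0)
    for i in range(10):
        _, _, truth = simulate_regression_fret(cfg, repetitive=True, seed=i)
        assert len(truth.frames_of("hj_formation")) >= 2
        assert truth.frames_of("dissociation") == []


def test_field_movie_background_only_and_placement_limits():
    cfg = SimConfig(n_frames=3, noise_sigma=0.0)
    stacks, pos = simulate_field_movie(0, cfg=cfg, seed=0, shape=(32, 32),
                                       background=10.0)
    assert pos.shape == (0, 2)
    # Poisson background only: mean close to 10, no bright structure
    assert abs(stacks["a"].mean() - 10.0) < 1.0
    with pytest.raises(ValueError):
        simulate_field_movie(500, cfg=cfg, seed=0, shape=(24, 24))


def test_experiment_bundle_reproducible_and_validated():
    recipe = {"substrate": "forked", "n_molecules": 4, "p_fluor": 0.7,
              "seed": 2, "config": {"n_frames": 60}}
    ds1 = simulate_experiment(recipe)
    ds2 = simulate_experiment(recipe)
    assert ds1["manifest"] == ds2["manifest"]
    for m1, m2 in zip(ds1["molecules"], ds2["molecules"]):
        np.testing.assert_array_equal(m1["gfp"].values, m2["gfp"].values)
        np.testing.assert_array_equal(m1["donor"].values,
                                      m2["donor"].values)
    with pytest.raises(ValueError):
        simulate_experiment({"substrate": "plasmid", "seed": 1})
    with pytest.raises(ValueError):
        simulate_experiment({"substrate": "forked"})
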