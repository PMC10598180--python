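"""Shared fixtures.

The expensive study-scale computations (Morris screening, the subset
reduction, and the replicate recovery study) are session-scoped so every
test that needs them shares one run.
"""

import numpy as np
import pytest

from murinecv import (SUBSET_11, SolverConfig, fisher_information,
                      fit_parameters, generate_noisy_traces,
                      local_sensitivity, make_reference_mouse, morris_screen,
                      nominal_parameters, parameter_confidence, preprocess,
                      reduce_subset, response_intervals, simulate)

try:
    from hypothesis import settings
    settings.register_profile("ci", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def nominal_params():
    return nominal_parameters()


@pytest.fixture(scope="session")
def preset1_mouse():
    return make_reference_mouse(1)


@pytest.fixture(scope="session")
def preset1_sim(preset1_mouse):
    res = simulate(preset1_mouse.params)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def nominal_sim(nominal_params):
    res = simulate(nominal_params)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def morris_smoke(preset1_mouse):
    """Morris screening at smoke scale (20 trajectories)."""
    return morris_screen(preset1_mouse.params, n_trajectories=20)


@pytest.fixture(scope="session")
def subset_reduction(preset1_mouse, morris_smoke):
    """Local sensitivities of the retained set, F, and the reduction."""
    S = local_sensitivity(preset1_mouse.params, morris_smoke.retained)
    return {"S": S,
            "fisher": fisher_information(S),
            "trace": reduce_subset(S)}


@pytest.fixture(scope="session")
def recovery_study(preset1_mouse, preset1_sim):
    """Twenty replicate fits to preset-1 noisy data with interval sets.

    Each replicate draws a fresh 20-beat noisy acquisition, runs the full
    preprocessing chain, calibrates the 11-parameter subset starting from
    the nominal values, and computes the asymptotic parameter intervals
    plus pointwise prediction bands.  Held-out averaged beats from an
    independent acquisition measure prediction-interval sample coverage.
    """
    mouse = preset1_mouse
    truth = mouse.truth_log()
    p0 = nominal_parameters(mouse=1)
    reps = []
    for rep in range(20):
        traces = generate_noisy_traces(mouse, n_beats=20, seed=1000 + rep,
                                       base=preset1_sim)
        beat = preprocess(traces)
        data = beat.to_calibration_data()
        fit = fit_parameters(data, SUBSET_11, p0)
        iv = response_intervals(fit)
        held = preprocess(generate_noisy_traces(
            mouse, n_beats=20, seed=5000 + rep, base=preset1_sim))
        y_held = held.to_calibration_data().vector()
        pi_cover = float(np.mean((iv.pi_lower <= y_held)
                                 & (y_held <= iv.pi_upper)))
        ci_cover = ((iv.ci_log_lower <= truth)
                    & (truth <= iv.ci_log_upper))
        reps.append({"fit": fit, "intervals": iv,
                     "err": fit.theta_log - truth,
                     "ci_cover": ci_cover, "pi_cover": pi_cover})
    return {"mouse": mouse, "truth": truth, "reps": reps}
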