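"""Morris screening, local sensitivities, Fisher information, reduction."""

import numpy as np
import pytest

from murinecv import (MorrisDesign, fisher_information, local_sensitivity,
                      morris_sample, nominal_parameters, output_sensitivity,
                      reduce_subset)
from murinecv.sensitivity import (SensitivityMatrix, elementary_effects,
                                  morris_index)
from murinecv.circulation import CALIBRATION_STREAMS


def _toy_design(k=2, r=1, seed=7, **kw):
    return MorrisDesign(names=[f"p{i}" for i in range(k)],
                        lower=np.ones(k), upper=2 * np.ones(k),
                        n_trajectories=r, seed=seed, **kw)


def test_morris_trajectory_structure():
    design = _toy_design(k=2, r=1)
    traj = morris_sample(design)
    assert traj.shape == (1, 3, 2)
    for j in range(1, 3):
        moved = np.nonzero(traj[0, j] != traj[0, j - 1])[0]
        assert moved.size == 1
        assert abs(traj[0, j, moved[0]] - traj[0, j - 1, moved[0]]) == \
            pytest.approx(design.delta)
    assert np.all(traj >= 0.0) and np.all(traj <= 1.0)


def test_morris_design_deterministic():
    a = morris_sample(_toy_design(k=5, r=4, seed=11))
    b = morris_sample(_toy_design(k=5, r=4, seed=11))
    np.testing.assert_array_equal(a, b)
    c = morris_sample(_toy_design(k=5, r=4, seed=12))
    assert not np.array_equal(a, c)


def _stream_dict(value):
    return {s: np.atleast_1d(np.asarray(value, dtype=float))
            for s in CALIBRATION_STREAMS}


def test_elementary_effects_analytic_model():
    """EEs of f(x) = x1 + x2^2 match a brute-force enumeration."""
    design = _toy_design(k=2, r=6, seed=3)
    traj = morris_sample(design)

    def f_scalar(v):
        return v[0] + v[1] ** 2

    def evaluate(values, names):
        return _stream_dict(f_scalar(values))

    ee, dropped = elementary_effects(design, traj, evaluate)
    assert dropped == 0
    # oracle: recompute every step by hand with the same distance rule
    for tr in range(traj.shape[0]):
        for j in range(1, traj.shape[1]):
            moved = int(np.nonzero(traj[tr, j] != traj[tr, j - 1])[0][0])
            va = design.to_natural(traj[tr, j - 1])
            vb = design.to_natural(traj[tr, j])
            d = abs(f_scalar(vb) - f_scalar(va)) / abs(f_scalar(va))
            step = abs(traj[tr, j, moved] - traj[tr, j - 1, moved])
            assert ee[0, tr, moved] == pytest.approx(d / step, rel=1e-12)


def test_elementary_effects_inert_parameter():
    design = _toy_design(k=3, r=4, seed=5)
    traj = morris_sample(design)

    def evaluate(values, names):
        return _stream_dict(values[0] + values[1])  # p2 inert

    ee, _ = elementary_effects(design, traj, evaluate)
    assert np.all(ee[:, :, 2] == 0.0)
    res = morris_index(ee, design.names)
    assert res.M[0, 2] == 0.0


def test_morris_index_formulas():
    # mu* = 3, s = 4 -> M = 5; constant EEs -> s^2 = 0, M = mu*
    ee = np.zeros((1, 2, 2))
    ee[0, :, 0] = [3 - 4 / np.sqrt(2) * 1, 3 + 4 / np.sqrt(2)]  # mean 3
    ee[0, :, 1] = [2.0, 2.0]
    res = morris_index(ee, ["a", "b"])
    assert res.mu_star[0, 0] == pytest.approx(3.0, rel=1e-12)
    assert res.s2[0, 0] == pytest.approx(16.0, rel=1e-12)
    assert res.M[0, 0] == pytest.approx(5.0, rel=1e-12)  # 3-4-5
    assert res.M[0, 1] == pytest.approx(2.0, rel=1e-12)
    assert res.s2[0, 1] == 0.0


def test_morris_linear_model_never_prefers_inert_parameter():
    """On an additive-linear model, a zero-coefficient parameter is fixed
    while every nonzero-coefficient parameter is kept."""
    k = 6
    coef = np.array([5.0, 3.0, 2.0, 1.5, 1.0, 0.0])
    design = MorrisDesign(names=[f"p{i}" for i in range(k)],
                          lower=np.ones(k), upper=2 * np.ones(k),
                          n_trajectories=8, seed=2)
    traj = morris_sample(design)

    def evaluate(values, names):
        return _stream_dict(10.0 + coef @ values)

    ee, _ = elementary_effects(design, traj, evaluate)
    res = morris_index(ee, design.names)
    assert res.below_mean[-1]
    assert not res.below_mean[0]


def test_local_sensitivity_log_slope():
    """Scaled sensitivity of f = theta^2 is the log-log slope 2."""
    p = nominal_parameters()

    def evaluate(values):
        return [values["R_sys"] ** 2]

    S = output_sensitivity(p, ["R_sys"], scaled=True, evaluate=evaluate)
    assert S.S[0, 0] == pytest.approx(2.0, rel=1e-4)

    def evaluate_id(values):
        return [values["R_sys"]]

    S1 = output_sensitivity(p, ["R_sys"], scaled=True, evaluate=evaluate_id)
    assert S1.S[0, 0] == pytest.approx(1.0, rel=1e-4)

    def evaluate_const(values):
        return [3.14]

    S0 = output_sensitivity(p, ["R_sys"], scaled=True,
                            evaluate=evaluate_const)
    assert S0.S[0, 0] == pytest.approx(0.0, abs=1e-12)


def test_fisher_information_properties():
    rng = np.random.default_rng(0)
    # orthonormal columns -> identity, cond 1
    q, _ = np.linalg.qr(rng.normal(size=(10, 3)))
    fi = fisher_information(q)
    np.testing.assert_allclose(fi.F, np.eye(3), atol=1e-12)
    assert fi.cond == pytest.approx(1.0, rel=1e-9)
    # brute-force accumulation over rows
    S = rng.normal(size=(10, 3))
    F_brute = sum(np.outer(S[t], S[t]) for t in range(10))
    np.testing.assert_allclose(fisher_information(S).F, F_brute, rtol=1e-12)
    # duplicated column -> numerically singular
    S_dup = np.column_stack([S, S[:, 0]])
    assert fisher_information(S_dup).cond > 1e14


def test_reduce_subset_trivial_and_collinear():
    rng = np.random.default_rng(1)
    q, _ = np.linalg.qr(rng.normal(size=(30, 4)))
    S_ok = SensitivityMatrix(q, list("abcd"), 0.01, np.zeros(30), True)
    tr = reduce_subset(S_ok)
    assert tr.removed == []
    assert tr.final == list("abcd")
    # a duplicated column pair: one of the two must go before termination
    base = rng.normal(size=(30, 3))
    dup = np.column_stack([base, base[:, 0] * 0.9])
    S_bad = SensitivityMatrix(dup, list("abcd"), 0.01, np.zeros(30), True)
    tr2 = reduce_subset(S_bad)
    assert ("a" in tr2.removed) or ("d" in tr2.removed)
    assert tr2.final_cond <= 1e5
    # condition number does not increase when the smaller of the pair goes
    assert tr2.conds[-1] <= tr2.conds[0]
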