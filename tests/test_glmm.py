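"""ZTP GLMM estimation: oracle equivalence, quadrature, recovery, contracts."""

import numpy as np
import pandas as pd
import pytest

from buzzpause.glmm import ZeroTruncatedPoissonGLMM, fit_ztp_glmm
from buzzpause.synth import OutcomeModelParams, sample_outcome_table
from buzzpause.ztp import ztp_rate_for_mean

from conftest import calibrated_table


def test_intercept_only_solves_truncated_mean_equation():
    """All responses 3: the MLE solves lam/(1-e^-lam) = 3, beta0 = log lam."""
    df = pd.DataFrame({"pause_ms": [3] * 100})
    m = ZeroTruncatedPoissonGLMM(fixed=(), random=None).fit(df)
    lam_hat = ztp_rate_for_mean(3.0)
    assert lam_hat == pytest.approx(2.8214, abs=1e-4)
    assert m.coef_[0] == pytest.approx(np.log(lam_hat), abs=1e-6)


def test_matches_independent_ztp_regression_oracle():
    """No-random-effects fit equals statsmodels' truncated Poisson MLE."""
    from statsmodels.discrete.truncated_model import TruncatedLFPoisson

    rng = np.random.default_rng(10)
    df = calibrated_table(rng)
    m = ZeroTruncatedPoissonGLMM(fixed=("outcome",), random=None).fit(df)
    X = pd.get_dummies(df["outcome"], drop_first=True, dtype=float)
    X.insert(0, "const", 1.0)
    oracle = TruncatedLFPoisson(df["pause_ms"], X, truncation=0).fit(disp=0)
    assert np.allclose(m.coef_, oracle.params.values, atol=1e-6)
    assert m.loglik_ == pytest.approx(oracle.llf, abs=1e-6)


def test_zero_variance_glmm_collapses_to_fixed_effects_fit():
    rng = np.random.default_rng(11)
    df = calibrated_table(rng)
    fe = ZeroTruncatedPoissonGLMM(fixed=("outcome",), random=None).fit(df)
    mm = fit_ztp_glmm(df)  # data carry no real group effects
    assert mm.boundary_  # sigmas end on the 0 boundary
    assert np.allclose(mm.coef_, fe.coef_, atol=1e-6)
    assert mm.loglik_ == pytest.approx(fe.loglik_, abs=1e-5)


def test_aghq_agrees_with_laplace_on_well_separated_data():
    params = OutcomeModelParams(sd_bat=0.10, sd_date=0.05)
    df = sample_outcome_table(250, n_bats=8, n_dates=4, params=params, seed=3)
    mL = fit_ztp_glmm(df, method="laplace")
    mA = fit_ztp_glmm(df, method="aghq", n_nodes=15)
    assert np.allclose(mL.coef_, mA.coef_, atol=1e-3)
    assert abs(mL.loglik_ - mA.loglik_) < 0.01


def test_aghq_loglik_converges_with_nodes():
    params = OutcomeModelParams(sd_bat=0.15, sd_date=0.08)
    df = sample_outcome_table(120, n_bats=6, n_dates=3, params=params, seed=5)
    theta = None
    lls = []
    for nodes in (1, 5, 15):
        m = fit_ztp_glmm(df, method="aghq", n_nodes=nodes)
        lls.append(m.loglik_)
    # successive refinements change the loglik less and less
    assert abs(lls[2] - lls[1]) <= abs(lls[1] - lls[0]) + 1e-9


def test_parameter_recovery_with_random_effects():
    params = OutcomeModelParams(sd_bat=0.10, sd_date=0.05)
    df = sample_outcome_table(2000, n_bats=20, n_dates=5, params=params, seed=7)
    m = fit_ztp_glmm(df)
    b = dict(zip(m.coef_names_, m.coef_))
    means = {
        "captured": np.exp(b["(Intercept)"]),
        "dropped": np.exp(b["(Intercept)"] + b["outcome[dropped]"]),
        "failed": np.exp(b["(Intercept)"] + b["outcome[failed]"]),
    }
    for level, target in [("captured", 200), ("dropped", 153), ("failed", 114)]:
        assert means[level] == pytest.approx(target, rel=0.02)
    # bat SD is informed by 20 bats; date SD by only 5 draws, so test it loosely
    assert m.sigma_inner_ == pytest.approx(0.10, rel=0.25)
    assert m.sigma_outer_ == pytest.approx(0.05, abs=0.05)


def test_contrast_vectors_ignore_shared_intercept_shifts():
    """Rate ratios depend on coefficient differences, never the intercept."""
    from buzzpause.inference import pairwise_contrasts

    rng = np.random.default_rng(13)
    df = calibrated_table(rng, n_per_level=(400, 400, 400))
    m = fit_ztp_glmm(df)
    ratios = {c.pair: c.ratio for c in pairwise_contrasts(m)}
    # shift every response's log-rate by a constant: refit on scaled calibration
    df2 = calibrated_table(
        np.random.default_rng(13), n_per_level=(400, 400, 400),
        means=tuple(m_ * np.exp(0.3) for m_ in (200.0, 153.0, 114.0)),
    )
    m2 = fit_ztp_glmm(df2)
    ratios2 = {c.pair: c.ratio for c in pairwise_contrasts(m2)}
    for pair in ratios:
        assert ratios2[pair] == pytest.approx(ratios[pair], rel=0.05)
    b, b2 = m.coef_, m2.coef_
    assert b2[0] - b[0] == pytest.approx(0.3, abs=0.05)  # only the intercept moved


def test_input_validation():
    df = pd.DataFrame({"pause_ms": [1, 2, 0], "outcome": list("abc")})
    with pytest.raises(ValueError):
        fit_ztp_glmm(df, random=None)
    df2 = pd.DataFrame({"pause_ms": [1, 2, 3], "outcome": ["a", "a", "a"]})
    with pytest.raises(ValueError):
        fit_ztp_glmm(df2, random=None)  # single-level factor
    df3 = pd.DataFrame({"pause_ms": [1, 2, 3]})
    with pytest.raises(ValueError):
        ZeroTruncatedPoissonGLMM(fixed=(), random=None, method="bogus").fit(df3)


def test_predict_returns_truncation_corrected_means():
    df = pd.DataFrame({"pause_ms": [3] * 50})
    m = ZeroTruncatedPoissonGLMM(fixed=(), random=None).fit(df)
    assert m.predict(pd.DataFrame(index=range(2)))[0] == pytest.approx(3.0, abs=1e-5)


def test_sklearn_param_interface():
    est = ZeroTruncatedPoissonGLMM(method="aghq", n_nodes=9)
    params = est.get_params()
    assert params["method"] == "aghq" and params["n_nodes"] == 9
    est.set_params(method="laplace")
    assert est.method == "laplace"


def test_matches_glmmtmb_oracle():
    """Independent mixed-model oracle: glmmTMB truncated-Poisson fit via Rscript."""
    import shutil
    import subprocess
    import tempfile
    from pathlib import Path

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    params = OutcomeModelParams(sd_bat=0.15, sd_date=0.08)
    df = sample_outcome_table(300, n_bats=12, n_dates=4, params=params, seed=42)
    m = fit_ztp_glmm(df)
    with tempfile.TemporaryDirectory() as tmp:
        csv = Path(tmp) / "obs.csv"
        df.to_csv(csv, index=False)
        script = Path(tmp) / "fit.R"
        script.write_text(
            "suppressMessages(library(glmmTMB))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmmTMB(pause_ms ~ outcome + (1|date/bat_id),"
            " family=truncated_poisson, data=d)\n"
            "cat(fixef(m)$cond, as.numeric(logLik(m)), sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.strip().splitlines()]
    assert np.allclose(m.coef_, vals[:3], atol=1e-4)
    assert m.loglik_ == pytest.approx(vals[3], abs=1e-3)
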