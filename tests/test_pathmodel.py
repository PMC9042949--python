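"""Model structure, density oracles, standardisation and sampler behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import morphopath as mp
from morphopath.pathmodel import OUTCOMES, _Blocks, format_estimate


def _random_data(n, mediators, rng):
    df = pd.DataFrame({"age": rng.standard_normal(n),
                       "bmi": rng.standard_normal(n)})
    for m in mediators:
        df[m] = rng.standard_normal(n)
    for o in OUTCOMES:
        df[o] = rng.standard_normal(n)
    return df


# --- structure --------------------------------------------------------------

@pytest.mark.parametrize("variant, colour_mode, expected", [
    ("default", "channels",
     dict(intercepts=9, slopes=29, mediator_variances=6,
          mediator_covariances=15, outcome_variances=2,
          outcome_covariances=1)),
    ("extended", "channels",
     dict(intercepts=11, slopes=37, mediator_variances=8,
          mediator_covariances=28, outcome_variances=2,
          outcome_covariances=1)),
    ("shape_dominance_only", "channels",
     dict(intercepts=10, slopes=33, mediator_variances=7,
          mediator_covariances=21, outcome_variances=2,
          outcome_covariances=1)),
    ("shape_sextypicality_only", "channels",
     dict(intercepts=10, slopes=33, mediator_variances=7,
          mediator_covariances=21, outcome_variances=2,
          outcome_covariances=1)),
    ("default", "factor",
     dict(intercepts=7, slopes=21, mediator_variances=4,
          mediator_covariances=6, outcome_variances=2,
          outcome_covariances=1)),
])
def test_parameter_counts(variant, colour_mode, expected):
    manifest = mp.build_model(mp.PathModelSpec(variant=variant,
                                               colour_mode=colour_mode))
    assert manifest.counts() == expected
    # combinatorial identities: slopes = 4m + 5, correlations = C(m, 2)
    m = manifest.n_mediators
    assert expected["slopes"] == 4 * m + 5
    assert expected["mediator_covariances"] == m * (m - 1) // 2
    names = manifest.names
    assert len(names) == len(set(names))


def test_unknown_variant_rejected():
    with pytest.raises(ValueError, match="variant"):
        mp.PathModelSpec(variant="everything")


# --- standardisation --------------------------------------------------------

def test_standardize_and_round_trip(rng):
    df = pd.DataFrame({"sex": ["f"] * 30 + ["m"] * 30,
                       "x": rng.normal(5, 2, 60),
                       "y": rng.normal(-1, 0.3, 60)})
    out, transform = mp.standardize(df, ["x", "y"], by=["sex"])
    for _, grp in out.groupby("sex"):
        assert abs(grp["x"].mean()) < 1e-12
        assert np.isclose(grp["x"].std(ddof=0), 1.0)
    back = mp.inverse_standardize(out, transform, by=["sex"])
    np.testing.assert_allclose(back["x"], df["x"], atol=1e-12)
    np.testing.assert_allclose(back["y"], df["y"], atol=1e-12)


def test_standardize_constant_column_named():
    df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="'x'"):
        mp.standardize(df, ["x", "y"])


# --- log density ------------------------------------------------------------

def test_prior_only_density_closed_form():
    """With no data, the density at the zero/identity/unit point equals the
    sum of closed-form prior log densities (LKJ terms vanish at identity)."""
    manifest = mp.build_model(mp.PathModelSpec())
    o = manifest._offsets()
    theta = np.zeros(manifest.n_parameters)
    theta[o["aux_sd"]] = 1.0
    theta[o["mediator_sds"]] = 1.0
    theta[o["outcome_sds"]] = 1.0
    got = mp.log_density(manifest, theta, data=None)
    n_int = len(manifest.intercept_names)
    n_slope = len(manifest.slope_names)
    expected = (n_int * stats.norm(0, 0.2).logpdf(0.0)
                + n_slope * stats.norm(0, 0.5).logpdf(0.0)
                + 9 * stats.expon().logpdf(1.0))
    assert np.isclose(got, expected)


def test_log_density_single_specimen_hand_oracle(rng):
    """Likelihood at one specimen matches scipy multivariate-normal logpdfs
    composed by hand."""
    spec = mp.PathModelSpec(colour_mode="factor")  # 4 mediators
    manifest = mp.build_model(spec)
    med = manifest.mediators
    data = _random_data(1, med, rng)
    theta = rng.uniform(-0.3, 0.3, manifest.n_parameters)
    o = manifest._offsets()
    theta[o["aux_sd"]] = 0.8
    theta[o["mediator_sds"]] = [0.9, 1.1, 0.7, 1.3]
    theta[o["mediator_corrs"]] = 0.0
    theta[np.arange(manifest.n_parameters)[o["mediator_corrs"]][0]] = 0.4
    theta[o["outcome_sds"]] = [1.2, 0.6]
    theta[o["outcome_corr"]] = 0.5

    got = mp.log_density(manifest, theta, data)
    prior = mp.log_density(manifest, theta, data=None)

    from morphopath.pathmodel import _unpack_weights
    intercepts = theta[o["intercepts"]]
    slopes = theta[o["slopes"]]
    w_b, w_m, w_o = _unpack_weights(manifest, intercepts, slopes)
    row = data.iloc[0]
    x_b = np.array([1.0, row["age"]])
    ll = stats.norm(x_b @ w_b, 0.8).logpdf(row["bmi"])
    x_m = np.array([1.0, row["age"], row["bmi"]])
    sds_m = np.asarray(theta[o["mediator_sds"]])
    r_m = np.eye(4)
    r_m[0, 1] = r_m[1, 0] = 0.4
    cov_m = np.outer(sds_m, sds_m) * r_m
    ll += stats.multivariate_normal(x_m @ w_m, cov_m).logpdf(
        row[med].to_numpy(dtype=float))
    x_o = np.concatenate([[1.0, row["age"], row["bmi"]],
                          row[med].to_numpy(dtype=float)])
    sds_o = np.asarray(theta[o["outcome_sds"]])
    cov_o = np.outer(sds_o, sds_o) * np.array([[1.0, 0.5], [0.5, 1.0]])
    ll += stats.multivariate_normal(x_o @ w_o, cov_o).logpdf(
        row[list(OUTCOMES)].to_numpy(dtype=float))
    assert np.isclose(got, prior + ll)


def test_log_density_non_positive_definite_is_minus_inf(rng):
    manifest = mp.build_model(mp.PathModelSpec())
    o = manifest._offsets()
    theta = np.zeros(manifest.n_parameters)
    theta[o["aux_sd"]] = theta[o["mediator_sds"]] = theta[o["outcome_sds"]] = 1.0
    theta[o["mediator_corrs"]] = 0.95  # equicorrelation 0.95 on 6x6 is PD
    base = mp.log_density(manifest, theta)
    assert np.isfinite(base)
    bad = theta.copy()
    corr_idx = np.arange(manifest.n_parameters)[o["mediator_corrs"]]
    bad[corr_idx[0]] = -0.95  # breaks positive definiteness
    assert mp.log_density(manifest, bad) == -np.inf
    neg = theta.copy()
    neg[o["aux_sd"]] = -0.5
    assert mp.log_density(manifest, neg) == -np.inf


def test_log_density_peaks_near_generative_slopes(rng):
    """Monte-Carlo probe: pushing any slope far from truth lowers the joint
    density on a large synthetic dataset."""
    truth = mp.preset_truth("czech_men", seed=1)
    data = mp.simulate_path_table(truth, 2000, rng)
    manifest = mp.build_model(mp.PathModelSpec())
    tv = mp.true_parameter_values(truth)
    theta = np.array([tv[nm] for nm in manifest.names])
    blocks = _Blocks(manifest, data)
    at_truth = mp.log_density(manifest, theta, blocks=blocks)
    for nm in ["slope[age->bmi]", "slope[bmi->fwhr]",
               "slope[sshd->perceived_sextypicality]"]:
        moved = theta.copy()
        moved[manifest.index(nm)] += 1.0
        assert mp.log_density(manifest, moved, blocks=blocks) < at_truth


# --- sampler ----------------------------------------------------------------

def test_no_data_fit_recovers_prior_moments():
    manifest = mp.build_model(mp.PathModelSpec(colour_mode="factor"))
    draws = mp.fit(manifest, None, seed=8, n_draws=4000, chains=2)
    s = mp.summarize(draws)
    slope_rows = s.loc[manifest.slope_names]
    assert abs(slope_rows["mean"].mean()) < 0.05
    flat = draws.to_frame()
    assert abs(flat["slope[age->bmi]"].std() - 0.5) < 0.05
    assert abs(flat["sd[fwhr]"].mean() - 1.0) < 0.1  # Exponential(1)


def test_fit_matches_conjugate_posterior(rng):
    """With sd[bmi] fixed, the BMI-block margin has an exact normal
    posterior; MCMC must match it within Monte-Carlo error."""
    n = 80
    age = rng.standard_normal(n)
    bmi = 0.4 * age + rng.standard_normal(n)
    data = _random_data(n, ["L", "a", "b", "fwhr", "sshd", "dist"], rng)
    data["age"], data["bmi"] = age, bmi
    manifest = mp.build_model(mp.PathModelSpec())
    draws = mp.fit(manifest, data, seed=2, n_draws=6000, chains=3,
                   fixed={"sd[bmi]": 1.0})
    x = np.column_stack([np.ones(n), age])
    lam = x.T @ x + np.diag([1 / 0.2 ** 2, 1 / 0.5 ** 2])
    mean = np.linalg.solve(lam, x.T @ bmi)
    cov = np.linalg.inv(lam)
    flat = draws.to_frame()
    for k, nm in enumerate(["intercept[bmi]", "slope[age->bmi]"]):
        mc = flat[nm]
        se = mc.std() / np.sqrt(200)          # conservative ESS
        assert abs(mc.mean() - mean[k]) < 3 * se + 1e-3
        assert abs(mc.std() - np.sqrt(cov[k, k])) < 0.1 * mc.std()


def test_posterior_contracts_with_sample_size():
    truth = mp.preset_truth("czech_men", seed=4)
    manifest = mp.build_model(mp.PathModelSpec())
    sds = []
    for n in (50, 200, 800):
        rng = np.random.default_rng(77)
        data = mp.simulate_path_table(truth, n, rng)
        data, _ = mp.standardize(data, list(data.columns))
        draws = mp.fit(manifest, data, seed=5, n_draws=1000, chains=2)
        sds.append(draws.to_frame()["slope[bmi->perceived_dominance]"].std())
    assert sds[0] > sds[1] > sds[2]


def test_label_invariance_under_permutation(rng):
    truth = mp.preset_truth("czech_women", seed=6)
    data = mp.simulate_path_table(truth, 150, rng)
    data, _ = mp.standardize(data, list(data.columns))
    manifest = mp.build_model(mp.PathModelSpec())
    d1 = mp.fit(manifest, data, seed=9, n_draws=1500, chains=2)
    perm = data.sample(frac=1.0, random_state=1).reset_index(drop=True)
    d2 = mp.fit(manifest, perm, seed=9, n_draws=1500, chains=2)
    s1, s2 = mp.summarize(d1), mp.summarize(d2)
    for nm in manifest.slope_names:
        se = d1.to_frame()[nm].std() / np.sqrt(100)
        assert abs(s1.loc[nm, "mean"] - s2.loc[nm, "mean"]) < 3 * se + 5e-3


def test_summarize_and_formatting(rng):
    manifest = mp.build_model(mp.PathModelSpec(colour_mode="factor"))
    p = manifest.n_parameters
    const = mp.PosteriorDraws(
        draws=np.full((1, 100, p), 0.42), parameter_names=manifest.names,
        seed=0, rhat=np.ones(p), ess=np.full(p, 1e4), converged=True)
    s = mp.summarize(const)
    assert np.allclose(s["upper95"] - s["lower95"], 0.0)
    # quantile oracle on standard-normal draws
    z = rng.standard_normal((1, 20000, p))
    normal = mp.PosteriorDraws(
        draws=z, parameter_names=manifest.names, seed=0,
        rhat=np.ones(p), ess=np.full(p, 2e4), converged=True)
    sn = mp.summarize(normal)
    assert np.allclose(sn["lower95"], -1.96, atol=0.06)
    assert np.allclose(sn["upper95"], 1.96, atol=0.06)
    assert format_estimate(0.423, 0.158, 0.641) == "0.42 (CI: 0.16, 0.64)"
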