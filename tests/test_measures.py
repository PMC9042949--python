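"""BMI/fWHR arithmetic, repeatability gate, ICC, parallel analysis and the
colour factor, checked against hand computations and independent packages."""

import numpy as np
import pytest

import morphopath as mp
from morphopath.exceptions import RepeatabilityError, SchemaError
from morphopath.measures import RatingMatrix


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return RatingMatrix(values=values,
                        rater_ids=[f"r{i}" for i in range(values.shape[0])],
                        stimulus_ids=[f"s{j}" for j in range(values.shape[1])])


# --- bmi / fwhr ------------------------------------------------------------

def test_bmi_arithmetic():
    assert np.isclose(mp.bmi(70, 1.75), 70 / 1.75 ** 2)
    assert mp.bmi(1, 1) == 1
    assert np.isclose(mp.bmi(70, 3.5), mp.bmi(70, 1.75) / 4)
    with pytest.raises(ValueError):
        mp.bmi(-1, 1.7)


def test_fwhr_arithmetic():
    assert mp.fwhr(100, 100) == 1
    assert mp.fwhr(140, 70) == 2.0
    with pytest.raises(ValueError):
        mp.fwhr(140, 0)


# --- repeatability gate ----------------------------------------------------

def _pair_with_exact_r(n, r, rng):
    """Closed-form construction of two vectors with sample correlation r."""
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= x * (x @ z) / (x @ x)          # orthogonalise
    z /= z.std()
    y = r * x + np.sqrt(1 - r ** 2) * z
    return x, y


def test_repeatability_identical_accepted(rng):
    v = rng.standard_normal(10)
    np.testing.assert_allclose(mp.repeatability_gate(v, v), v)


def test_repeatability_anticorrelated_rejected(rng):
    v = rng.standard_normal(10)
    with pytest.raises(RepeatabilityError) as err:
        mp.repeatability_gate(v, -v)
    assert np.isclose(err.value.r, -1.0)


@pytest.mark.parametrize("r, ok", [(0.95, True), (0.85, False)])
def test_repeatability_constructed_correlations(r, ok, rng):
    x, y = _pair_with_exact_r(50, r, rng)
    assert np.isclose(np.corrcoef(x, y)[0, 1], r)
    if ok:
        np.testing.assert_allclose(mp.repeatability_gate(x, y), (x + y) / 2)
    else:
        with pytest.raises(RepeatabilityError) as err:
            mp.repeatability_gate(x, y)
        assert np.isclose(err.value.r, r)


# --- ICC(3,k) ---------------------------------------------------------------

def test_icc_identical_raters_is_one():
    col = np.array([1.0, 4.0, 7.0, 3.0])
    assert np.isclose(mp.icc_3k(_matrix(np.tile(col, (3, 1)))), 1.0)


def test_icc_matches_hand_anova_on_4x3():
    """Explicit two-way sums-of-squares decomposition as the oracle."""
    x = np.array([[2.0, 4.0, 6.0, 3.0],
                  [3.0, 5.0, 5.0, 4.0],
                  [2.0, 6.0, 7.0, 2.0]])  # raters x stimuli
    stim = x.T                            # stimuli x raters, n=4, k=3
    grand = stim.mean()
    ss_rows = 3 * ((stim.mean(axis=1) - grand) ** 2).sum()
    ss_cols = 4 * ((stim.mean(axis=0) - grand) ** 2).sum()
    ss_err = ((stim - grand) ** 2).sum() - ss_rows - ss_cols
    ms_rows = ss_rows / 3
    ms_err = ss_err / 6
    expected = (ms_rows - ms_err) / ms_rows
    assert np.isclose(mp.icc_3k(_matrix(x)), expected)


def test_icc_agrees_with_pingouin(rng):
    import pandas as pd
    import pingouin as pg

    values = np.clip(np.round(rng.normal(4, 1.2, size=(6, 20))), 1, 7)
    ours = mp.icc_3k(_matrix(values))
    long = pd.DataFrame({
        "rater": np.repeat(np.arange(6), 20),
        "stim": np.tile(np.arange(20), 6),
        "score": values.reshape(-1),
    })
    ref = pg.intraclass_corr(long, targets="stim", raters="rater",
                             ratings="score")
    icc3k = float(ref.loc[ref["Type"] == "ICC(C,k)", "ICC"].values[0])
    assert np.isclose(ours, icc3k, atol=1e-10)


def test_icc_shift_invariance_and_bounds(rng):
    values = np.clip(np.round(rng.normal(3, 1, size=(4, 12))), 1, 6)
    base = mp.icc_3k(_matrix(values))
    shifted = mp.icc_3k(_matrix(values + 1))
    assert np.isclose(base, shifted)
    assert base <= 1.0


def test_icc_too_few_raters():
    with pytest.raises(SchemaError):
        _matrix(np.array([[1.0, 2.0, 3.0]]))


def test_mean_ratings():
    all7 = _matrix(np.full((3, 4), 7.0))
    assert np.allclose(mp.mean_ratings(all7), 7.0)
    x = np.array([[1.0, 4.0, 6.0],
                  [2.0, 4.0, 5.0],
                  [3.0, 4.0, 7.0]])
    np.testing.assert_allclose(mp.mean_ratings(_matrix(x)),
                               [2.0, 4.0, 6.0])
    # one rater's disagreement moves the mean by delta / n_raters
    y = x.copy()
    y[0, 0] += 3
    assert np.isclose(mp.mean_ratings(_matrix(y)).iloc[0], 2.0 + 3 / 3)


# --- parallel analysis ------------------------------------------------------

def test_parallel_analysis_null_is_statistically_marginal():
    """Under pure noise no systematic factor is retained: each observed
    eigenvalue sits at its random reference, so the mean-reference rule
    retains 0 in a substantial fraction of datasets and never signals a
    strong structure."""
    retained = []
    for s in range(20):
        rng = np.random.default_rng(100 + s)
        x = rng.standard_normal((5000, 3))
        retained.append(mp.parallel_analysis(x, n_random=100, seed=s))
    assert np.mean(retained) < 1.2
    assert retained.count(0) >= 5


def test_parallel_analysis_strong_factor(rng):
    for s in range(5):
        g = np.random.default_rng(1000 + s)
        f = g.standard_normal(500)
        x = np.outer(f, [0.9, 0.9, 0.9]) + 0.1 * g.standard_normal((500, 3))
        assert mp.parallel_analysis(x, n_random=100, seed=s) == 1


def test_parallel_analysis_monotone_in_factor_strength():
    counts = []
    for loading in (0.0, 0.5, 0.9):
        g = np.random.default_rng(7)
        f = g.standard_normal(2000)
        noise = g.standard_normal((2000, 3))
        x = loading * f[:, None] + np.sqrt(1 - loading ** 2) * noise
        counts.append(mp.parallel_analysis(x, n_random=100, seed=3))
    assert counts == sorted(counts)


def test_parallel_analysis_constant_column():
    x = np.random.default_rng(0).standard_normal((50, 3))
    x[:, 1] = 2.0
    with pytest.raises(ValueError, match="constant"):
        mp.parallel_analysis(x)


# --- colour factor ----------------------------------------------------------

def test_colour_factor_rank_one_limit(rng):
    latent = rng.standard_normal(300)
    x = np.outer(latent, [2.0, -1.0, 0.5])
    loadings, scores, r2 = mp.extract_colour_factor(x)
    np.testing.assert_allclose(r2, 1.0, atol=1e-6)
    assert abs(np.corrcoef(scores, latent)[0, 1]) > 0.9999
    assert loadings[0] > 0  # L*-positive orientation


def test_colour_factor_heywood_clipped_with_warning():
    """A near-unity loading at small n produces a Heywood communality, which
    is clipped at 0.995 rather than propagated."""
    g = np.random.default_rng(0)
    f = g.standard_normal(40)
    tl = np.array([0.995, 0.99, 0.3])
    x = f[:, None] * tl[None] \
        + g.standard_normal((40, 3)) * np.sqrt(1 - tl ** 2)[None]
    with pytest.warns(UserWarning, match="Heywood"):
        loadings, scores, r2 = mp.extract_colour_factor(x)
    assert np.all(loadings ** 2 <= 0.995 + 1e-12)
    assert np.all(np.isfinite(scores))


def test_colour_factor_recovers_loadings(rng):
    true_loadings = np.array([0.7, 0.9, 0.95])
    n = 2000
    f = rng.standard_normal(n)
    unique = np.sqrt(1 - true_loadings ** 2)
    x = f[:, None] * true_loadings[None] \
        + rng.standard_normal((n, 3)) * unique[None]
    loadings, scores, r2 = mp.extract_colour_factor(x)
    np.testing.assert_allclose(loadings, true_loadings, atol=0.05)
    assert abs(scores.mean()) < 1e-10
    assert scores.var() <= 1.0 + 1e-10
    # r2 is invariant to channel rescaling
    _, _, r2_scaled = mp.extract_colour_factor(x * [10.0, 0.1, 3.0])
    np.testing.assert_allclose(r2, r2_scaled, atol=1e-8)


def test_colour_factor_cross_check_sklearn(rng):
    from sklearn.decomposition import FactorAnalysis

    true_loadings = np.array([0.8, 0.9, 0.85])
    n = 4000
    f = rng.standard_normal(n)
    unique = np.sqrt(1 - true_loadings ** 2)
    x = f[:, None] * true_loadings[None] \
        + rng.standard_normal((n, 3)) * unique[None]
    loadings, _, _ = mp.extract_colour_factor(x)
    z = (x - x.mean(0)) / x.std(0)
    fa = FactorAnalysis(n_components=1, random_state=0).fit(z)
    ml = np.abs(fa.components_[0])
    np.testing.assert_allclose(np.abs(loadings), ml, atol=0.05)


def test_use_colour_factor_decision(rng):
    # strongly collinear single-factor channels -> factor mode
    f = rng.standard_normal(400)
    strong = f[:, None] * np.array([0.9, 0.95, 0.97])[None] \
        + rng.standard_normal((400, 3)) * 0.2
    assert mp.use_colour_factor(strong, seed=1)
    # moderately correlated channels -> keep separate channels
    cov = np.array([[1.0, 0.45, 0.35], [0.45, 1.0, 0.4], [0.35, 0.4, 1.0]])
    weak = rng.multivariate_normal(np.zeros(3), cov, size=400)
    assert not mp.use_colour_factor(weak, seed=1)
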