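"""Synthetic-study generator: determinism, degeneracies, moment recovery
and calibration of the sample presets."""

import numpy as np
import pytest

import morphopath as mp
from morphopath.exceptions import DegenerateShapeError, NotPositiveDefiniteError
from morphopath.simulate import FACTOR_MEDIATORS


def _zero_noise_truth():
    m = len(FACTOR_MEDIATORS)
    return mp.GroundTruth(
        colour_mode="factor",
        age_sd=0.0, bmi_sd=0.0, height_sd=0.0,
        sshd_within_sex_sd=0.0, idiosyncratic_sd=0.0, curve_jitter_sd=0.0,
        face_height_px_sd=0.0, measurement_noise_sd=0.0, rater_noise_sd=0.0,
        mediator_residual_sds=np.zeros(m),
        outcome_residual_sds=np.zeros(2),
        colour_factor_loadings=np.ones(3),
        sextypicality_sd=0.0, dominance_sd=0.0,
        seed=42)


def test_same_seed_byte_identical_outputs(tmp_path):
    truth = mp.preset_truth("cmr_women", seed=17)
    for d in ("a", "b"):
        study = mp.simulate_study(truth, 10)
        mp.write_study(study, tmp_path / d)
    for f in (tmp_path / "a").iterdir():
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name


def test_zero_noise_degeneracy():
    """All noise sds zero: ratings equal the rounded latent value and
    specimens within a sex are identical."""
    truth = _zero_noise_truth()
    study = mp.simulate_study(truth, 5)
    # every rater agrees exactly
    for matrix, mean in ((study.ratings_sextypicality,
                          truth.sextypicality_mean),
                         (study.ratings_dominance, truth.dominance_mean)):
        expected = np.clip(np.round(mean), 1, 7)
        assert np.all(matrix.values == expected)
    # identical shape within sex (after removing nuisance transforms)
    aligned = mp.gpa(study.configs, scheme=study.scheme, slide=False)
    sex = study.specimens["sex"].to_numpy()
    for s in ("female", "male"):
        idx = np.flatnonzero(sex == s)
        for i in idx[1:]:
            assert mp.procrustes_distance(aligned.aligned[idx[0]],
                                          aligned.aligned[i]) < 1e-8
    # identical covariates within sex
    for col in ("age", "L", "a", "b"):
        assert study.specimens[col].nunique() == 1
    fwhr = study.specimens["width1"] / study.specimens["height1"]
    assert fwhr.nunique() == 1


def test_outcome_residual_correlation_recovered(rng):
    """Monte-Carlo moment check: latent outcomes of a slope-free model have
    residual correlation matching the generative value within 0.05."""
    truth = mp.GroundTruth(outcome_residual_corr=0.6, seed=0)
    table = mp.simulate_path_table(truth, 1000, rng)
    r = np.corrcoef(table["perceived_sextypicality"],
                    table["perceived_dominance"])[0, 1]
    assert abs(r - 0.6) < 0.05


def test_moments_converge_to_truth():
    """Sample moments at n=2000 sit within 3 Monte-Carlo SEs of target."""
    truth = mp.preset_truth("czech_men", seed=23)
    n = 2000
    rng = np.random.default_rng(23)
    table = mp.simulate_path_table(truth, n, rng)
    se_mean = 1.0 / np.sqrt(n)
    se_sd = 1.0 / np.sqrt(2 * n)
    for col in table.columns:
        assert abs(table[col].mean()) < 3 * se_mean, col
        assert abs(table[col].std() - 1.0) < 3 * se_sd + 0.01, col
    # generative slope structure: corr(age, bmi) = bmi_on_age_slope
    r = np.corrcoef(table["age"], table["bmi"])[0, 1]
    assert abs(r - truth.bmi_on_age_slope) < 3 * se_mean


def test_icc_tends_to_one_as_rater_noise_vanishes():
    base = {}
    for noise in (1.2, 0.3, 0.0):
        truth = mp.preset_truth("czech_women", seed=31)
        truth.rater_noise_sd = noise
        study = mp.simulate_study(truth, 20)
        base[noise] = mp.icc_3k(study.ratings_sextypicality)
    assert base[0.0] > base[0.3] > base[1.2]
    assert base[0.0] == 1.0


def test_rater_main_effects_do_not_move_consistency_icc():
    """Rater leniency/harshness offsets barely move ICC(3,k): the two-way
    consistency form removes rater main effects."""
    plain = mp.preset_truth("czech_women", seed=51)
    biased = mp.preset_truth("czech_women", seed=51)
    biased.rater_bias_sd = 1.0
    icc_plain = mp.icc_3k(mp.simulate_study(plain, 25).ratings_dominance)
    icc_biased = mp.icc_3k(mp.simulate_study(biased, 25).ratings_dominance)
    assert abs(icc_plain - icc_biased) < 0.05


def test_preset_calibration_czech_women():
    """n=106 run lands near the calibration moments (within 20%)."""
    truth = mp.preset_truth("czech_women", seed=12)
    study = mp.simulate_study(truth, 106)
    focal = study.specimens[study.specimens["sex"] == "female"]
    assert abs(focal["age"].mean() - 23.09) / 23.09 < 0.2
    assert abs(focal["age"].std() - 4.12) / 4.12 < 0.2
    means = mp.mean_ratings(study.ratings_sextypicality)
    fem = means[focal["id"]]
    assert abs(fem.mean() - 4.00) / 4.00 < 0.2
    assert abs(fem.std() - 0.84) / 0.84 < 0.2


def test_preset_sshd_score_spread_calibrated():
    """Recovered per-sex SShD score SDs land in the published 0.01-0.02
    band for the Czech presets."""
    truth = mp.preset_truth("czech_women", seed=3)
    study = mp.simulate_study(truth, 80)
    aligned = mp.gpa(study.configs, scheme=study.scheme, slide=True)
    sex = study.specimens["sex"].to_numpy()
    scores = mp.sshd_scores(aligned, sex)
    for s in ("female", "male"):
        assert 0.005 < scores[sex == s].std() < 0.025
    assert scores[sex == "female"].mean() < 0 < scores[sex == "male"].mean()


def test_landmark_round_trip_recovery():
    """Injected +-0.02 shape latents are recovered by the pipeline
    (correlation > 0.9 at n=60)."""
    truth = mp.preset_truth("custom", seed=19)
    study = mp.simulate_study(truth, 30)
    aligned = mp.gpa(study.configs, scheme=study.scheme, slide=True)
    scores = mp.sshd_scores(aligned, study.specimens["sex"].to_numpy())
    lat = study.latents["shape_latent"].to_numpy()
    assert np.corrcoef(scores, lat)[0, 1] > 0.9


def test_pure_nuisance_transforms_align_to_zero(rng):
    truth = _zero_noise_truth()
    configs = mp.simulate_landmarks(truth, np.zeros(6), rng)
    aligned = mp.gpa(configs, slide=False)
    assert np.all(aligned.distances_to_consensus() < 1e-8)


def test_zero_area_template_rejected(rng):
    template = np.zeros((72, 2))
    template[:, 0] = np.linspace(-1, 1, 72)  # collinear
    template /= np.sqrt(np.sum(template ** 2))
    axis = np.zeros(144)
    axis[0] = 1.0
    truth = mp.GroundTruth(template_shape=template, dimorphism_axis=axis)
    with pytest.raises(DegenerateShapeError, match="zero area"):
        mp.simulate_landmarks(truth, np.zeros(3), rng)


def test_invalid_correlation_matrix_named():
    bad = np.eye(6)
    bad[0, 1] = bad[1, 0] = 1.5
    with pytest.raises(NotPositiveDefiniteError) as err:
        mp.GroundTruth(mediator_residual_corr=bad)
    assert err.value.name == "mediator_residual_corr"


def test_basic_validation():
    with pytest.raises(ValueError, match="n_raters"):
        mp.GroundTruth(n_raters=1)
    with pytest.raises(ValueError, match=">= 0"):
        mp.GroundTruth(rater_noise_sd=-0.1)
    with pytest.raises(ValueError, match="n_per_sex"):
        mp.simulate_study(mp.GroundTruth(), 2)


def test_factor_mode_channels_follow_latent():
    truth = mp.preset_truth("cmr_men", seed=8)
    study = mp.simulate_study(truth, 200)
    chan = study.specimens[["L", "a", "b"]].to_numpy()
    colour = study.latents["colour"].to_numpy()
    for j, loading in enumerate(truth.colour_factor_loadings):
        r = np.corrcoef(chan[:, j], colour)[0, 1]
        assert abs(r - loading) < 0.08
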