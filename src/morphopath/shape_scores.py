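"""Perception-relevant shape statistics computed on a superimposed sample.

Three per-face statistics:

* **SShD** (sexual shape dimorphism): projection of each face onto the unit
  vector connecting the male and female mean shapes, centred at the midpoint
  between the two sex means, so the two sexes land symmetrically around zero.
  Lower values are more female-like, higher values more male-like.
* **DIST** (distinctiveness): Procrustes distance of a face from the sample
  consensus; higher = less average.
* **Shape-trait scores** ("shape dominance", "shape sex-typicality"): each
  centred shape coordinate is regressed on a perceived rating and a face's
  score is the projection of its centred configuration onto the raw
  coefficient vector — the shape-explained component of that rating. The raw
  (un-normalised) coefficient vector keeps scores on the very small scale
  (~1e-4) characteristic of published per-face regression scores; since every
  variable is standardised before modelling, axis normalisation is irrelevant
  downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .procrustes import AlignedSample

__all__ = ["sshd_scores", "distinctiveness", "shape_trait_scores", "score_table"]


def _sex_masks(sex) -> tuple[np.ndarray, np.ndarray]:
    sex = np.asarray([str(s).lower() for s in sex], dtype=object)
    male = sex == "male"
    female = sex == "female"
    if not np.all(male | female):
        bad = sorted(set(sex) - {"male", "female"})
        raise ValueError(f"invalid sex labels: {bad}")
    return male, female


def sshd_scores(aligned: AlignedSample, sex) -> np.ndarray:
    """Per-specimen sexual shape dimorphism scores.

    The axis is ``d = (male mean - female mean)`` flattened and normalised to
    unit length; ``score_i = (x_i - midpoint) @ d`` with the midpoint halfway
    between the sex means. Requires both sexes with >= 2 specimens each in
    the pooled, jointly superimposed sample.
    """
    male, female = _sex_masks(sex)
    if male.sum() < 2 or female.sum() < 2:
        raise ValueError(
            "SShD axis undefined: need >= 2 specimens of each sex "
            f"(got {int(male.sum())} male, {int(female.sum())} female)"
        )
    x = aligned.flat
    if len(male) != x.shape[0]:
        raise ValueError("sex labels do not match the aligned sample")
    male_mean = x[male].mean(axis=0)
    female_mean = x[female].mean(axis=0)
    axis = male_mean - female_mean
    norm = np.linalg.norm(axis)
    if norm <= 0:
        raise ValueError("male and female mean shapes coincide; axis undefined")
    axis = axis / norm
    midpoint = 0.5 * (male_mean + female_mean)
    return (x - midpoint) @ axis


def distinctiveness(aligned: AlignedSample) -> np.ndarray:
    """Procrustes distance of each face from the consensus (always >= 0)."""
    return aligned.distances_to_consensus()


def shape_trait_scores(aligned: AlignedSample, trait,
                       indices: np.ndarray | None = None) -> np.ndarray:
    """Per-face shape component of a perceived rating.

    Regresses every centred aligned coordinate on the (standardised) trait;
    a face's score is ``(x_i - mean shape) @ b`` with ``b`` the raw
    per-coordinate slope vector. ``indices`` restricts the computation to a
    subset of the sample (the published design fits these regressions within
    sex), in which case centring uses that subset's mean shape. Scores are
    mean-zero within the fitted subset by construction.
    """
    trait = np.asarray(trait, dtype=float)
    x = aligned.flat
    if indices is not None:
        x = x[np.asarray(indices)]
    if trait.shape[0] != x.shape[0]:
        raise ValueError("trait length does not match the (sub)sample")
    if trait.shape[0] <= 2:
        raise ValueError("need n > 2 specimens to fit the shape regression")
    if not np.all(np.isfinite(trait)):
        raise ValueError("trait contains non-finite values")
    sd = trait.std()
    if sd == 0:
        raise ValueError("trait is constant; shape regression undefined")
    t = (trait - trait.mean()) / sd
    xc = x - x.mean(axis=0)
    # per-coordinate OLS slope on the standardised trait
    b = xc.T @ t / float(t @ t)
    return xc @ b


def score_table(aligned: AlignedSample, sex, specimen_ids=None) -> pd.DataFrame:
    """Delimited-table-ready frame of sshd and dist keyed by specimen id."""
    ids = specimen_ids if specimen_ids is not None else aligned.specimen_ids
    return pd.DataFrame(
        {
            "id": [str(i) for i in ids],
            "sshd": sshd_scores(aligned, sex),
            "dist": distinctiveness(aligned),
        }
    )
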