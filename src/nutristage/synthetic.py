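"""Synthetic ground truth: TR tables, demography and paired survey waves.

The generator emulates what the estimator assumes about the real data: two
cross-sectional prevalence-by-single-age tables five years apart, where the
cohort aged ``a`` in wave 1 reappears at age ``a + 5`` in wave 2 with its
category mix transformed by the fifth power of the one-year transition
matrix of its wave-1 age group.  Ground-truth rates are drawn either with
survey-like magnitudes (``paper_like``: adult tau1 of a few percent a year,
tau2 around one percent, recovery rates near zero except in childhood) or
uniformly over the feasible region (``random_feasible``).

Wave-1 age profiles are smooth logistic ramps with a mild sinusoidal ripple;
the ripple gives the five single-age columns of each group enough affine
spread on the simplex to identify all four rates.  Optional survey noise is
additive Gaussian on each prevalence entry, clipped at zero and renormalised
to the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit

from .core import (
    MAX_SURVEY_AGE,
    N_AGE_GROUPS,
    DemographicParams,
    SESGroup,
    SurveyPrevalence,
    TransferenceRateTable,
)
from .estimate import one_year_matrix

__all__ = [
    "SyntheticScenario",
    "generate_truth",
    "generate_waves",
    "baseline_profile",
    "synthetic_demography",
]

PROFILES = ("paper_like", "random_feasible")

#: Default survey years of the emulated wave pair.
WAVE1_YEAR, WAVE2_YEAR = 2005, 2010


def baseline_profile(phase: float = 0.0) -> np.ndarray:
    """Smooth wave-1 prevalence-by-age table, shape (3, 65).

    Overweight rises logistically through adulthood, obesity with a later
    midpoint; sinusoids of a few percentage points emulate the age-to-age
    heterogeneity real survey prevalences show.  That heterogeneity carries
    the identification: without it the five columns of an age group are
    nearly collinear on the simplex and the two recovery rates are poorly
    identified.  ``phase`` shifts the ripple so strata are not identical.
    """
    a = np.arange(MAX_SURVEY_AGE + 1, dtype=float)
    p_ow = 0.06 + 0.36 * expit((a - 22.0) / 6.0) + 0.04 * np.sin(0.9 * a + phase)
    p_ob = 0.03 + 0.16 * expit((a - 30.0) / 7.0) + 0.025 * np.sin(
        1.7 * a + 1.0 + phase
    )
    P = np.vstack([1.0 - p_ow - p_ob, p_ow, p_ob])
    if np.any(P <= 0.0):  # pragma: no cover - guards future edits
        raise AssertionError("baseline profile left the simplex interior")
    return P


def synthetic_demography(
    *, theta=(0.85, 0.11, 0.04), fertility_level: float = 2.0
) -> tuple[DemographicParams, np.ndarray]:
    """Coherent demography: age-increasing mortality, flat fertility and a
    gently tapering population pyramid (thousands of people per group)."""
    mortality = np.array(
        [0.004, 0.0005, 0.0005, 0.001, 0.0015, 0.0015,
         0.0016, 0.002, 0.003, 0.004, 0.006, 0.009]
    )
    fertility = {year: fertility_level for year in range(2000, 2041)}
    demo = DemographicParams(
        mortality=mortality, fertility=fertility, mu=0.523, theta=np.asarray(theta)
    )
    populations = 4200.0 * 0.93 ** np.arange(N_AGE_GROUPS)
    return demo, populations


@dataclass(frozen=True)
class SyntheticScenario:
    """Reproducible ground truth for one generator draw."""

    seed: int
    profile: str
    truth: Mapping[SESGroup, TransferenceRateTable]
    demography: DemographicParams
    populations: np.ndarray
    noise_sd: float = 0.0
    strata: tuple[SESGroup, ...] = (SESGroup.ALL,)
    wave_years: tuple[int, int] = (WAVE1_YEAR, WAVE2_YEAR)


def _draw_paper_like(rng: np.random.Generator) -> np.ndarray:
    """Rates with survey-like magnitudes: adult tau1 in [0.005, 0.04], tau2
    in [0.002, 0.017], recovery rates near zero except for the childhood
    groups (large tau4 at 0-4, large tau3 at 10-14)."""
    tau = np.zeros((N_AGE_GROUPS, 4))
    tau[:, 0] = rng.uniform(0.005, 0.04, N_AGE_GROUPS)
    tau[:, 1] = rng.uniform(0.002, 0.017, N_AGE_GROUPS)
    tau[:, 2] = rng.uniform(0.0, 1e-4, N_AGE_GROUPS)
    tau[:, 3] = rng.uniform(0.0, 1e-4, N_AGE_GROUPS)
    tau[0, 0] = rng.uniform(0.001, 0.007)
    tau[0, 3] = rng.uniform(0.02, 0.05)
    tau[2, 0] = rng.uniform(0.0, 0.002)
    tau[2, 2] = rng.uniform(0.015, 0.045)
    return tau


def _draw_random_feasible(rng: np.random.Generator) -> np.ndarray:
    tau = rng.uniform(0.0, 0.5, (N_AGE_GROUPS, 4))
    over = tau[:, 1] + tau[:, 3]
    bad = over > 1.0
    tau[bad, 1] /= over[bad]
    tau[bad, 3] /= over[bad]
    return tau


def generate_truth(
    seed: int,
    profile: str = "paper_like",
    *,
    strata: tuple[SESGroup | str, ...] = (SESGroup.ALL,),
    noise_sd: float = 0.0,
) -> SyntheticScenario:
    """Draw a full reproducible scenario: per-stratum truth TR tables plus a
    shared demography.  The same seed always yields the same scenario."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {PROFILES}")
    strata = tuple(SESGroup(s) for s in strata)
    rng = np.random.default_rng(seed)
    draw = _draw_paper_like if profile == "paper_like" else _draw_random_feasible
    truth = {ses: TransferenceRateTable(draw(rng), ses=ses) for ses in strata}
    demo, populations = synthetic_demography()
    return SyntheticScenario(
        seed=int(seed),
        profile=profile,
        truth=truth,
        demography=demo,
        populations=populations,
        noise_sd=float(noise_sd),
        strata=strata,
    )


def _add_noise(P: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    noisy = P + rng.normal(0.0, sd, P.shape)
    noisy = np.clip(noisy, 0.0, None)
    return noisy / noisy.sum(axis=0, keepdims=True)


def generate_waves(
    scn: SyntheticScenario, ses: SESGroup | str = None
) -> dict[SESGroup, tuple[SurveyPrevalence, SurveyPrevalence]]:
    """Generate the paired survey waves for every stratum of ``scn``.

    Wave 1 is the smooth baseline profile (ripple phase varies by stratum);
    wave-2 ages ``5i+5 .. 5i+9`` are the wave-1 columns of group ``i``
    pushed through ``A_i^5``.  Wave-2 ages 0-4 (cohorts born between the
    waves, unused by the estimator) reuse the wave-1 columns.  With
    ``noise_sd = 0`` the estimation objective is exactly zero at the truth;
    with noise, entries are perturbed then renormalised.  Deterministic
    given ``scn.seed``.
    """
    strata = (SESGroup(ses),) if ses is not None else scn.strata
    rng = np.random.default_rng(np.random.SeedSequence([scn.seed, 2**20]))
    y1, y2 = scn.wave_years
    out = {}
    for k, s in enumerate(strata):
        table = scn.truth[s]
        P1 = baseline_profile(phase=0.7 * k)
        P2 = np.empty_like(P1)
        P2[:, :5] = P1[:, :5]
        for i in range(N_AGE_GROUPS):
            B = np.linalg.matrix_power(one_year_matrix(table.tau[i]), 5)
            P2[:, 5 * i + 5 : 5 * i + 10] = B @ P1[:, 5 * i : 5 * i + 5]
        if scn.noise_sd > 0.0:
            P1 = _add_noise(P1, scn.noise_sd, rng)
            P2 = _add_noise(P2, scn.noise_sd, rng)
        out[s] = (
            SurveyPrevalence(wave=y1, P=P1, ses=s),
            SurveyPrevalence(wave=y2, P=P2, ses=s),
        )
    return out
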