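"""Synthetic longitudinal mood cohorts with retained ground truth.

The generator emulates the statistical structure the downstream analysis
assumes:

* a weekly three-state episode Markov chain (euthymic / depressive / manic)
  per patient, with latent depression and mania severities following
  episode-mean + AR(1)-residual dynamics;
* weekly 10-item ordinal self-reports driven by the two latent severities
  through a factor-loading + graded-threshold model (the two nonspecific
  items load mostly on the depression factor);
* monthly clinician assessments (MADRS / YMRS, optionally item-level) whose
  scores are noisy linear maps of the latent severities, scheduled every
  fourth week with a +/-3-day jitter;
* per-patient adherence (probability of filing each weekly report) drawn
  from a Beta distribution calibrated to the observed mean 0.78 (SD 0.183)
  response rate.

Ground truth — per patient-week latent states and severities, the adherence
draws, and the analytically implied fixed slopes linking the self-report
subscores to the clinician totals — is retained in :class:`SyntheticTruth`
so parameter-recovery tests have exact targets.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import roots_hermitenorm
from scipy.stats import norm, truncnorm

from .domain import (
    DEP_ITEMS,
    MAN_ITEMS,
    NSP_ITEMS,
    AsertResponse,
    ClinicalAssessment,
    Patient,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_cohort",
    "ordinal_item",
    "beta_shape_parameters",
    "implied_fixed_slopes",
    "write_cohort",
]

logger = logging.getLogger(__name__)

STATE_EUTHYMIC, STATE_DEPRESSIVE, STATE_MANIC = 0, 1, 2
STATE_LABELS = {STATE_EUTHYMIC: "eut", STATE_DEPRESSIVE: "dep", STATE_MANIC: "man"}

_BASE_DATE = dt.date(2019, 1, 7)  # a Monday; enrollment dates are staggered from here


def _default_loadings() -> tuple[tuple[float, float], ...]:
    rows: list[tuple[float, float]] = []
    for k in range(10):
        if k in DEP_ITEMS:
            rows.append((1.0, 0.0))
        elif k in MAN_ITEMS:
            rows.append((0.0, 1.0))
        else:  # nonspecific: mostly depression, a little mania
            rows.append((0.8, 0.3))
    return tuple(rows)


def _default_thresholds() -> tuple[tuple[float, float, float, float], ...]:
    return tuple((0.5, 1.25, 2.0, 2.75) for _ in range(10))


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions.

    Units: severities are latent (dimensionless); clinician gains map latent
    units to scale points; durations are weeks; dates advance in whole days.
    """

    n_patients: int = 99
    # Follow-up length in weeks ~ truncated normal (the observed mean 754 and
    # SD 266 days correspond to about 108 and 38 weeks).
    followup_weeks_mean: float = 108.0
    followup_weeks_sd: float = 38.0
    followup_weeks_min: int = 8
    # Monthly clinician assessments: every 4th week with uniform day jitter.
    assessment_interval_weeks: int = 4
    assessment_jitter_days: int = 3
    # Weekly episode transition probabilities.
    p_stay_euthymic: float = 0.95
    p_enter_depression: float = 0.035
    p_enter_mania: float = 0.015
    p_stay_episode: float = 0.85
    # Latent severity: episode mean plus AR(1) residual.
    dep_episode_mean: float = 2.5
    man_episode_mean: float = 2.5
    ar_phi: float = 0.7
    ar_innovation_sd: float = 0.357  # stationary residual SD ~0.5 at phi=0.7
    # Clinician map: total ~ gain * severity + Gaussian noise, clipped to range.
    clinician_gain_dep: float = 8.0
    clinician_gain_man: float = 8.0
    clinician_noise_sd: float = 3.0
    include_scale_items: bool = True
    # Ordinal item model.
    loadings: tuple[tuple[float, float], ...] = field(
        default_factory=_default_loadings
    )
    thresholds: tuple[tuple[float, float, float, float], ...] = field(
        default_factory=_default_thresholds
    )
    item_noise_sd: float = 0.6
    # Adherence: per-patient weekly filing probability ~ Beta(mean, sd).
    adherence_mean: float = 0.78
    adherence_sd: float = 0.183
    # Optional extension (off by default): extra missingness during episodes.
    episode_missingness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.followup_weeks_min < 1:
            raise ValueError("followup_weeks_min must be >= 1")
        row_e = self.p_stay_euthymic + self.p_enter_depression + self.p_enter_mania
        if abs(row_e - 1.0) > 1e-9:
            raise ValueError(
                f"euthymic transition row sums to {row_e}, expected 1"
            )
        for p in (
            self.p_stay_euthymic,
            self.p_enter_depression,
            self.p_enter_mania,
            self.p_stay_episode,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("transition probabilities must lie in [0, 1]")
        if len(self.loadings) != 10 or any(len(r) != 2 for r in self.loadings):
            raise ValueError("loadings must be a 10x2 array")
        if len(self.thresholds) != 10:
            raise ValueError("thresholds must give 4 cut points per item")
        for taus in self.thresholds:
            if len(taus) != 4 or any(
                taus[i + 1] <= taus[i] for i in range(len(taus) - 1)
            ):
                raise ValueError("item thresholds must be strictly increasing")
        if self.item_noise_sd < 0 or self.clinician_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if not (0.0 < self.adherence_mean < 1.0):
            raise ValueError("adherence_mean must lie in (0, 1)")
        if not (0.0 <= self.episode_missingness <= 1.0):
            raise ValueError("episode_missingness must lie in [0, 1]")

    @property
    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic weekly transition matrix over (eut, dep, man)."""
        leave = 1.0 - self.p_stay_episode
        return np.array(
            [
                [self.p_stay_euthymic, self.p_enter_depression, self.p_enter_mania],
                [leave, self.p_stay_episode, 0.0],
                [leave, 0.0, self.p_stay_episode],
            ]
        )

    @property
    def stationary_distribution(self) -> np.ndarray:
        P = self.transition_matrix
        w, v = np.linalg.eig(P.T)
        k = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, k])
        return pi / pi.sum()


@dataclass
class SyntheticTruth:
    """Ground truth retained by the generator for recovery tests."""

    latent: pd.DataFrame  # patient_id, week, state, s_dep, s_man
    adherence: dict[str, float]
    beta_true_dep: float  # implied population slope MADRS ~ DEPNSP
    beta_true_man: float  # implied population slope YMRS ~ MAN
    config: GeneratorConfig


def beta_shape_parameters(mean: float, sd: float) -> tuple[float, float]:
    """Solve Beta(a, b) shapes for a requested mean and SD.

    If the SD is infeasible for the mean (sd^2 >= mean*(1-mean)), it is shrunk
    to 0.99x the feasible maximum with a logged warning.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError("mean must lie in (0, 1)")
    max_sd = float(np.sqrt(mean * (1.0 - mean)))
    if sd >= max_sd:
        warnings.warn(
            f"adherence SD {sd} infeasible for mean {mean}; "
            f"shrunk to {0.99 * max_sd:.4f}",
            stacklevel=2,
        )
        logger.warning("adherence SD %s infeasible for mean %s; shrunk", sd, mean)
        sd = 0.99 * max_sd
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return mean * nu, (1.0 - mean) * nu


def ordinal_item(
    latent: Sequence[float],
    loadings: Sequence[float],
    thresholds: Sequence[float],
    noise: float,
) -> int:
    """Graded-threshold ordinal response: count of thresholds strictly below
    the propensity ``loadings . latent + noise``."""
    taus = np.asarray(thresholds, dtype=float)
    if taus.ndim != 1 or np.any(np.diff(taus) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    propensity = float(np.dot(loadings, latent)) + float(noise)
    return int(np.sum(taus < propensity))


def _simulate_states(rng: np.random.Generator, config: GeneratorConfig, n_weeks: int) -> np.ndarray:
    P = config.transition_matrix
    pi = config.stationary_distribution
    states = np.empty(n_weeks, dtype=np.int64)
    states[0] = rng.choice(3, p=pi)
    for t in range(1, n_weeks):
        states[t] = rng.choice(3, p=P[states[t - 1]])
    return states


def _simulate_ar1(rng: np.random.Generator, config: GeneratorConfig, n_weeks: int) -> np.ndarray:
    phi, sd = config.ar_phi, config.ar_innovation_sd
    stat_sd = sd / np.sqrt(1.0 - phi**2) if abs(phi) < 1 else sd
    r = np.empty(n_weeks)
    r[0] = rng.normal(0.0, stat_sd)
    innov = rng.normal(0.0, sd, size=n_weeks - 1) if n_weeks > 1 else np.empty(0)
    for t in range(1, n_weeks):
        r[t] = phi * r[t - 1] + innov[t - 1]
    return r


def _clinician_items(
    rng: np.random.Generator,
    gain: float,
    noise_sd: float,
    severity: float,
    n_items: int,
    item_max: int,
) -> tuple[int, ...]:
    g = gain / n_items
    sd = noise_sd / np.sqrt(n_items)
    raw = g * severity + rng.normal(0.0, sd, size=n_items)
    return tuple(int(v) for v in np.clip(np.rint(raw), 0, item_max))


def generate_cohort(
    config: Optional[GeneratorConfig] = None,
) -> tuple[list[Patient], list[AsertResponse], list[ClinicalAssessment], SyntheticTruth]:
    """Simulate a cohort; identical config (incl. seed) gives identical output."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    a_shape, b_shape = beta_shape_parameters(
        config.adherence_mean, config.adherence_sd
    )

    n = config.n_patients
    lo = (config.followup_weeks_min - config.followup_weeks_mean) / config.followup_weeks_sd
    weeks = np.rint(
        truncnorm.rvs(
            lo,
            np.inf,
            loc=config.followup_weeks_mean,
            scale=config.followup_weeks_sd,
            size=n,
            random_state=rng,
        )
    ).astype(int)
    enroll_offsets = rng.integers(0, 365, size=n)
    adherence_draws = rng.beta(a_shape, b_shape, size=n)

    loadings = np.asarray(config.loadings, dtype=float)
    thresholds = np.asarray(config.thresholds, dtype=float)

    patients: list[Patient] = []
    asserts: list[AsertResponse] = []
    clinical: list[ClinicalAssessment] = []
    latent_rows: list[dict] = []
    adherence: dict[str, float] = {}

    width = len(str(n))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        W = int(weeks[i])
        enroll = _BASE_DATE + dt.timedelta(days=int(enroll_offsets[i]))
        exit_date = enroll + dt.timedelta(days=7 * W - 1)
        patients.append(Patient(pid, enroll, exit_date))
        adherence[pid] = float(adherence_draws[i])

        states = _simulate_states(rng, config, W)
        s_dep = config.dep_episode_mean * (states == STATE_DEPRESSIVE) + _simulate_ar1(
            rng, config, W
        )
        s_man = config.man_episode_mean * (states == STATE_MANIC) + _simulate_ar1(
            rng, config, W
        )
        for w in range(W):
            latent_rows.append(
                {
                    "patient_id": pid,
                    "week": w,
                    "state": STATE_LABELS[int(states[w])],
                    "s_dep": float(s_dep[w]),
                    "s_man": float(s_man[w]),
                }
            )

        # Weekly self-reports, missing completely at random per week (plus the
        # optional episode-state missingness extension, off by default).
        file_prob = np.full(W, adherence_draws[i])
        if config.episode_missingness > 0.0:
            file_prob = file_prob * np.where(
                states == STATE_EUTHYMIC, 1.0, 1.0 - config.episode_missingness
            )
        filed = rng.random(W) < file_prob
        noise = rng.normal(0.0, config.item_noise_sd, size=(W, 10))
        propensity = (
            loadings @ np.vstack([s_dep, s_man])
        ).T + noise  # (W, 10)
        items_all = (propensity[:, :, None] > thresholds[None, :, :]).sum(axis=2)
        for w in range(W):
            if not filed[w]:
                continue
            asserts.append(
                AsertResponse(
                    pid,
                    enroll + dt.timedelta(days=7 * w),
                    tuple(int(v) for v in items_all[w]),
                )
            )

        # Monthly clinician assessments with day jitter.
        for w in range(0, W, config.assessment_interval_weeks):
            jitter = int(
                rng.integers(
                    -config.assessment_jitter_days, config.assessment_jitter_days + 1
                )
            )
            day = int(np.clip(7 * w + jitter, 0, 7 * W - 1))
            if config.include_scale_items:
                m_items = _clinician_items(
                    rng,
                    config.clinician_gain_dep,
                    config.clinician_noise_sd,
                    float(s_dep[w]),
                    n_items=10,
                    item_max=6,
                )
                y_items = _clinician_items(
                    rng,
                    config.clinician_gain_man,
                    config.clinician_noise_sd,
                    float(s_man[w]),
                    n_items=11,
                    item_max=5,
                )
                clinical.append(
                    ClinicalAssessment(
                        pid,
                        enroll + dt.timedelta(days=day),
                        madrs_total=sum(m_items),
                        ymrs_total=sum(y_items),
                        madrs_items=m_items,
                        ymrs_items=y_items,
                    )
                )
            else:
                madrs = int(
                    np.clip(
                        np.rint(
                            config.clinician_gain_dep * s_dep[w]
                            + rng.normal(0.0, config.clinician_noise_sd)
                        ),
                        0,
                        60,
                    )
                )
                ymrs = int(
                    np.clip(
                        np.rint(
                            config.clinician_gain_man * s_man[w]
                            + rng.normal(0.0, config.clinician_noise_sd)
                        ),
                        0,
                        60,
                    )
                )
                clinical.append(
                    ClinicalAssessment(pid, enroll + dt.timedelta(days=day), madrs, ymrs)
                )

    asserts.sort(key=lambda r: (r.patient_id, r.date))
    clinical.sort(key=lambda r: (r.patient_id, r.date))
    beta_dep, beta_man = implied_fixed_slopes(config)
    truth = SyntheticTruth(
        latent=pd.DataFrame(
            latent_rows, columns=["patient_id", "week", "state", "s_dep", "s_man"]
        ),
        adherence=adherence,
        beta_true_dep=beta_dep,
        beta_true_man=beta_man,
        config=config,
    )
    return patients, asserts, clinical, truth


# ---------------------------------------------------------------------------
# Implied population slopes (deterministic quadrature, no re-simulation)


def _clipped_normal_mean(m: np.ndarray, sd: float, lo: float, hi: float) -> np.ndarray:
    """E[min(max(Y, lo), hi)] for Y ~ N(m, sd^2), elementwise in m."""
    if sd == 0.0:
        return np.clip(m, lo, hi)
    alpha = (lo - m) / sd
    beta = (hi - m) / sd
    return (
        lo * norm.cdf(alpha)
        + hi * norm.sf(beta)
        + m * (norm.cdf(beta) - norm.cdf(alpha))
        - sd * (norm.pdf(beta) - norm.pdf(alpha))
    )


def implied_fixed_slopes(
    config: GeneratorConfig, n_nodes: int = 40
) -> tuple[float, float]:
    """Population regression slopes implied by the generator parameters.

    Computes, by Gauss-Hermite quadrature over the stationary latent mixture
    (episode states x AR(1) residuals), the slope of the clinician total on
    the self-report subscore:

    * ``beta_true_dep`` — MADRS total on the depressive+nonspecific subscore;
    * ``beta_true_man`` — YMRS total on the manic subscore.

    The ordinal item moments are exact; clinician-item rounding is the only
    neglected term.  This is the target for LME slope-recovery tests.
    """
    nodes, wts = roots_hermitenorm(n_nodes)
    wts = wts / np.sqrt(2.0 * np.pi)
    phi, sd_in = config.ar_phi, config.ar_innovation_sd
    stat_sd = sd_in / np.sqrt(1.0 - phi**2) if abs(phi) < 1 else sd_in
    pi = config.stationary_distribution
    state_means = {
        STATE_EUTHYMIC: (0.0, 0.0),
        STATE_DEPRESSIVE: (config.dep_episode_mean, 0.0),
        STATE_MANIC: (0.0, config.man_episode_mean),
    }

    # Flattened mixture grid over (state, node_dep, node_man).
    sd_grid, sm_grid, w_grid = [], [], []
    for st, p_st in enumerate(pi):
        mu_d, mu_m = state_means[st]
        d = mu_d + stat_sd * nodes
        m = mu_m + stat_sd * nodes
        D, M = np.meshgrid(d, m, indexing="ij")
        Wd, Wm = np.meshgrid(wts, wts, indexing="ij")
        sd_grid.append(D.ravel())
        sm_grid.append(M.ravel())
        w_grid.append(p_st * (Wd * Wm).ravel())
    s_dep = np.concatenate(sd_grid)
    s_man = np.concatenate(sm_grid)
    w = np.concatenate(w_grid)

    loadings = np.asarray(config.loadings, dtype=float)  # (10, 2)
    thresholds = np.asarray(config.thresholds, dtype=float)  # (10, 4)
    eta = loadings[:, 0][None, :] * s_dep[:, None] + loadings[:, 1][None, :] * s_man[
        :, None
    ]  # (G, 10)
    sd_item = config.item_noise_sd
    if sd_item == 0.0:
        p_ge = (eta[:, :, None] > thresholds[None, :, :]).astype(float)
    else:
        p_ge = norm.cdf((eta[:, :, None] - thresholds[None, :, :]) / sd_item)
    e_item = p_ge.sum(axis=2)  # (G, 10) conditional item means
    coef = 2.0 * np.arange(1, 5) - 1.0
    e_item2 = (p_ge * coef[None, None, :]).sum(axis=2)
    v_item = e_item2 - e_item**2

    def slope(
        item_idx: Sequence[int],
        gain: float,
        sev: np.ndarray,
        n_items: int,
        item_max: int,
    ) -> float:
        e_x = e_item[:, list(item_idx)].sum(axis=1)
        v_x = v_item[:, list(item_idx)].sum(axis=1)
        if config.include_scale_items:
            g = gain / n_items
            isd = config.clinician_noise_sd / np.sqrt(n_items)
            e_y = n_items * _clipped_normal_mean(g * sev, isd, 0.0, item_max)
        else:
            e_y = _clipped_normal_mean(gain * sev, config.clinician_noise_sd, 0.0, 60.0)
        mean_x = float(w @ e_x)
        mean_y = float(w @ e_y)
        var_x = float(w @ (v_x + e_x**2)) - mean_x**2
        cov_xy = float(w @ (e_x * e_y)) - mean_x * mean_y
        return cov_xy / var_x

    beta_dep = slope(
        list(DEP_ITEMS) + list(NSP_ITEMS), config.clinician_gain_dep, s_dep, 10, 6
    )
    beta_man = slope(list(MAN_ITEMS), config.clinician_gain_man, s_man, 11, 5)
    return beta_dep, beta_man


def write_cohort(
    outdir: Path | str,
    patients: list[Patient],
    asserts: list[AsertResponse],
    clinical: list[ClinicalAssessment],
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write the three standard CSVs plus truth.csv and a parameter echo."""
    from . import io as _io  # local import to avoid cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": outdir / "patients.csv",
        "asert": outdir / "asert.csv",
        "clinical": outdir / "clinical.csv",
        "truth": outdir / "truth.csv",
        "params": outdir / "generator-params.json",
    }
    _io.write_patient_table(patients, paths["patients"])
    _io.write_asert_table(asserts, paths["asert"])
    _io.write_clinical_table(clinical, paths["clinical"])
    truth.latent.to_csv(paths["truth"], index=False)
    params = dataclasses.asdict(truth.config)
    params["beta_true_dep"] = truth.beta_true_dep
    params["beta_true_man"] = truth.beta_true_man
    paths["params"].write_text(json.dumps(params, indent=2, default=list))
    return paths
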