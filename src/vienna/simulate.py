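"""Seeded synthetic cohorts with the structure the analyses assume.

The generator emulates a validation cohort of healthy middle-aged and older
adults (default n = 79, ages uniform on 50-85):

* a latent navigation ability ``theta = beta_age * z(age) + eps`` drives item
  success through a logistic item-response model
  ``P(correct | theta) = logistic(a * (theta - b_item))`` with difficulty b
  increasing, on average, over the turn-type ladder
  no-turn -> single-turn -> double-turn -> full-turn;
* two deficit traits (perspective-rotation and spatial-updating), negatively
  correlated with theta, steer *which* wrong door is chosen: given an error,
  probability mass is routed to the item's rotation doors, updating doors, or
  zero-point doors via trait-dependent multinomial weights;
* a covariate battery (questionnaires and neuropsychological tests on a
  z-score scale) loads on theta and on age with test-specific noise and
  missingness, reproducing the correlation structure the association and
  regression stages expect.

Chosen doors — never scores — are the primitive output; scores are always
obtained by routing the doors through :mod:`vienna.scoring`, so the
generator cannot drift from the rubric.  Each block of draws (ages/traits,
item responses, covariates, missingness) uses its own spawned random
substream, so adding covariates does not perturb the item draws.

Default difficulty targets are calibrated to the published marginal pattern:
a mean total near 19.4 with SD near 2.6 in the upper score range without
floor or ceiling effects, right-skewed updating-error counts with median 0,
and rotation errors roughly 2.5 times as frequent as updating errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .scoring import (
    ITEM_TYPE_ORDER,
    ErrorType,
    ItemConfig,
    ItemType,
    score_participant,
    score_response,
)

__all__ = [
    "CovariateSpec",
    "ItemSimParams",
    "SimConfig",
    "SimulatedCohort",
    "default_item_configs",
    "default_vienna_profile",
    "simulate_cohort",
    "simulate_ordinal_pair",
]


@dataclass(frozen=True)
class ItemSimParams:
    """One item's geometry plus its latent difficulty b."""

    config: ItemConfig
    b: float


@dataclass(frozen=True)
class CovariateSpec:
    """Loadings of one simulated test on the latent trait and on age.

    ``sign`` records the scoring direction (+1 higher = better, -1 higher =
    worse, e.g. depression scores or reaction times); the generated value is
    ``sign * (loading_theta * z(theta) + loading_age * z(age)) + noise``.
    """

    loading_theta: float
    loading_age: float = 0.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    sign: int = 1


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a synthetic cohort."""

    items: tuple[ItemSimParams, ...]
    covariates: Mapping[str, CovariateSpec]
    n_participants: int = 79
    age_range: tuple[float, float] = (50.0, 85.0)
    discrimination: float = 1.1
    beta_age: float = -0.75
    sigma_eps: float = 1.0
    deficit_theta_loading: float = -0.4
    route_rotation_boost: float = 1.6
    route_updating_boost: float = 2.3
    route_deficit_gain: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age range must be increasing")
        if self.sigma_eps <= 0 or self.discrimination <= 0:
            raise ValueError("sigma_eps and discrimination must be positive")
        if not -1.0 < self.deficit_theta_loading < 1.0:
            raise ValueError("deficit loading must lie in (-1, 1)")
        for name, spec in self.covariates.items():
            if not 0.0 <= spec.missing_rate < 1.0:
                raise ValueError(f"{name}: missing rate outside [0, 1)")
            if spec.noise_sd <= 0:
                raise ValueError(f"{name}: noise SD must be positive")
            if spec.sign not in (-1, 1):
                raise ValueError(f"{name}: sign must be +1 or -1")
        # difficulty must rise (on average) along the turn-type ladder
        by_type: dict[ItemType, list[float]] = {}
        for ip in self.items:
            by_type.setdefault(ip.config.item_type, []).append(ip.b)
        means = [np.mean(by_type[t]) for t in ITEM_TYPE_ORDER if t in by_type]
        if any(b2 < b1 for b1, b2 in zip(means, means[1:])):
            raise ValueError(
                "mean item difficulty b must be non-decreasing over turn types"
            )

    @property
    def theta_sd(self) -> float:
        return float(np.hypot(self.beta_age, self.sigma_eps))


@dataclass(frozen=True)
class SimulatedCohort:
    """Generated cohort plus the parameter record that produced it."""

    participants: pd.DataFrame  # id, age, traits, total, error counts
    responses: pd.DataFrame  # long: participant_id, item_id, chosen_door
    item_scores: pd.DataFrame  # wide: participants x items, points 0/1/2
    covariates: pd.DataFrame  # wide battery incl. age, with missingness
    config: SimConfig


def default_item_configs() -> tuple[ItemConfig, ...]:
    """Twelve-item door-geometry set used by the default profile.

    Door layouts are not part of the published assessment materials; these
    synthetic layouts are chosen so that each item's chance-expected score
    E = (2 + #one-point doors) / n_doors matches the published per-item E to
    two decimals.  Door 1 is the correct door, updating doors follow,
    rotation doors after that.
    """

    def cfg(item_id, itype, n, n_upd, n_rot):
        upd = frozenset(range(2, 2 + n_upd))
        rot = frozenset(range(2 + n_upd, 2 + n_upd + n_rot))
        return ItemConfig(item_id, itype, n, 1, upd, rot)

    t = ItemType
    return (
        cfg("i1", t.NO_TURN, 4, 0, 0),        # E = 0.50
        cfg("i2", t.NO_TURN, 11, 2, 0),       # E = 0.36
        cfg("i3", t.NO_TURN, 19, 2, 0),       # E = 0.21
        cfg("i4", t.SINGLE_TURN, 10, 1, 0),   # E = 0.30
        cfg("i5", t.SINGLE_TURN, 11, 1, 1),   # E = 0.36
        cfg("i6", t.SINGLE_TURN, 14, 1, 1),   # E = 0.29
        cfg("i7", t.DOUBLE_TURN, 19, 1, 1),   # E = 0.21
        cfg("i8", t.DOUBLE_TURN, 7, 0, 1),    # E = 0.43
        cfg("i9", t.DOUBLE_TURN, 16, 0, 1),   # E = 0.19
        cfg("i10", t.FULL_TURN, 5, 0, 2),     # E = 0.80
        cfg("i11", t.FULL_TURN, 13, 2, 4),    # E = 0.62
        cfg("i12", t.FULL_TURN, 8, 0, 2),     # E = 0.50
    )


#: population-average success probability targeted per default item
_DEFAULT_P_CORRECT = {
    "i1": 0.975, "i2": 0.949, "i3": 0.985, "i4": 0.970, "i5": 0.886,
    "i6": 0.810, "i7": 0.696, "i8": 0.620, "i9": 0.300, "i10": 0.550,
    "i11": 0.418, "i12": 0.500,
}


def _difficulty_from_p(p: float, a: float, theta_sd: float) -> float:
    """Invert the logistic-normal mean-probability approximation.

    For theta ~ N(0, s^2), E[logistic(a (theta - b))] is approximately
    logistic(-a b / sqrt(1 + pi a^2 s^2 / 8)); solving for b turns a target
    marginal success rate into an item difficulty.
    """
    scale = np.sqrt(1.0 + np.pi * (a * theta_sd) ** 2 / 8.0) / a
    return float(-logit(p) * scale)


def default_vienna_profile(
    n_participants: int = 79, seed: int = 0
) -> SimConfig:
    """Cohort configuration matching the published marginal structure."""
    a, beta_age, sigma_eps = 1.1, -0.75, 1.0
    theta_sd = float(np.hypot(beta_age, sigma_eps))
    items = tuple(
        ItemSimParams(c, _difficulty_from_p(_DEFAULT_P_CORRECT[c.item_id], a, theta_sd))
        for c in default_item_configs()
    )
    covariates = {
        "gender": CovariateSpec(0.0, 0.0, 1.0),  # thresholded downstream
        "education_years": CovariateSpec(0.10, 0.0, 1.0),
        "cpi": CovariateSpec(0.15, 0.0, 1.0, sign=-1),
        "fsbsod": CovariateSpec(0.40, 0.0, 1.0),
        "gds": CovariateSpec(0.05, 0.0, 1.0, missing_rate=3 / 79, sign=-1),
        "mmse": CovariateSpec(0.50, -0.15, 0.9),
        "rocf_copy": CovariateSpec(0.40, -0.10, 1.0),
        "rocf_recall": CovariateSpec(0.25, -0.15, 1.0),
        "block_span_forward": CovariateSpec(0.40, -0.15, 1.0),
        "block_span_backward": CovariateSpec(0.55, -0.20, 0.9),
        "tap_speed": CovariateSpec(0.10, 0.25, 1.0, sign=-1),
        "mrt": CovariateSpec(0.45, -0.25, 1.0, missing_rate=4 / 79),
        "ptsot": CovariateSpec(0.60, -0.20, 0.8, missing_rate=1 / 79),
        "fpt_productivity": CovariateSpec(0.55, -0.25, 0.9),
        "fpt_flexibility": CovariateSpec(0.10, 0.05, 1.0, sign=-1),
        "fpt_strategy": CovariateSpec(0.25, -0.10, 1.0),
    }
    return SimConfig(
        items=items,
        covariates=covariates,
        n_participants=n_participants,
        discrimination=a,
        beta_age=beta_age,
        sigma_eps=sigma_eps,
        seed=seed,
    )


def _route_error(
    config: ItemConfig,
    r_def: float,
    u_def: float,
    sim: SimConfig,
    rng: np.random.Generator,
) -> int:
    """Pick a wrong door: trait-weighted class choice, uniform within class."""
    classes: list[tuple[float, tuple[int, ...]]] = []
    if config.rotation_doors:
        w = len(config.rotation_doors) * np.exp(
            sim.route_rotation_boost + sim.route_deficit_gain * r_def
        )
        classes.append((w, tuple(sorted(config.rotation_doors))))
    if config.updating_doors:
        w = len(config.updating_doors) * np.exp(
            sim.route_updating_boost + sim.route_deficit_gain * u_def
        )
        classes.append((w, tuple(sorted(config.updating_doors))))
    zeros = tuple(sorted(config.zero_doors))
    if zeros:
        classes.append((float(len(zeros)), zeros))
    if not classes:
        raise ValueError(f"{config.item_id}: no incorrect doors to route an error to")
    weights = np.array([c[0] for c in classes])
    doors = classes[rng.choice(len(classes), p=weights / weights.sum())][1]
    return int(doors[rng.integers(len(doors))])


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Draw one cohort; deterministic under ``config.seed``."""
    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng_traits, rng_items, rng_cov, rng_miss = map(np.random.default_rng, ss)
    n = config.n_participants
    ids = [f"p{i + 1:03d}" for i in range(n)]

    lo, hi = config.age_range
    age = rng_traits.uniform(lo, hi, n)
    z_age = (age - age.mean()) / age.std(ddof=1)
    theta = config.beta_age * z_age + rng_traits.normal(0.0, config.sigma_eps, n)
    z_theta = theta / config.theta_sd
    lam = config.deficit_theta_loading
    resid = np.sqrt(1.0 - lam**2)
    r_def = lam * z_theta + resid * rng_traits.normal(size=n)
    u_def = lam * z_theta + resid * rng_traits.normal(size=n)

    rows = []
    for ip in config.items:
        p_correct = expit(config.discrimination * (theta - ip.b))
        correct = rng_items.random(n) < p_correct
        for i in range(n):
            if correct[i]:
                door = ip.config.correct_door
            else:
                door = _route_error(ip.config, r_def[i], u_def[i], config, rng_items)
            rows.append((ids[i], ip.config.item_id, door))
    responses = pd.DataFrame(rows, columns=["participant_id", "item_id", "chosen_door"])

    configs = [ip.config for ip in config.items]
    item_ids = [c.item_id for c in configs]
    by_cfg = {c.item_id: c for c in configs}
    scores = pd.DataFrame(index=ids, columns=item_ids, dtype=int)
    part_rows = []
    for pid, grp in responses.groupby("participant_id", sort=False):
        pairs = list(zip(grp["item_id"], grp["chosen_door"]))
        ps = score_participant(configs, pairs, pid)
        for item_id, door in pairs:
            scores.loc[pid, item_id] = score_response(by_cfg[item_id], door, pid).points
        part_rows.append(
            {
                "participant_id": pid,
                "total": ps.total,
                "n_updating": ps.n_updating,
                "n_rotation": ps.n_rotation,
            }
        )
    participants = pd.DataFrame(part_rows).set_index("participant_id").loc[ids]
    participants.insert(0, "age", age)
    participants["theta"] = theta
    participants["rotation_deficit"] = r_def
    participants["updating_deficit"] = u_def

    cov = pd.DataFrame(index=pd.Index(ids, name="participant_id"))
    cov["age"] = age
    for name, spec in config.covariates.items():
        base = spec.sign * (spec.loading_theta * z_theta + spec.loading_age * z_age)
        vals = base + spec.noise_sd * rng_cov.normal(size=n)
        if name == "gender":
            vals = (vals > np.quantile(vals, 0.73)).astype(float)  # ~27% male
        if spec.missing_rate > 0:
            vals = np.where(rng_miss.random(n) < spec.missing_rate, np.nan, vals)
        cov[name] = vals
    cov["vienna_total"] = participants["total"].to_numpy(dtype=float)
    cov["rotation_errors"] = participants["n_rotation"].to_numpy(dtype=float)
    cov["updating_errors"] = participants["n_updating"].to_numpy(dtype=float)

    return SimulatedCohort(
        participants=participants,
        responses=responses,
        item_scores=scores,
        covariates=cov,
        config=config,
    )


def simulate_ordinal_pair(
    rho: float,
    thresholds_x: Sequence[float],
    thresholds_y: Sequence[float],
    n: int,
    seed: int | None = None,
) -> np.ndarray:
    """Cross-tabulated discretized bivariate-normal draws.

    Fixture generator for polychoric recovery tests: draws n points from a
    standard bivariate normal with correlation ``rho`` and bins each margin
    at the given thresholds; returns the full contingency table (including
    empty categories).
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    tx = np.asarray(thresholds_x, dtype=float)
    ty = np.asarray(thresholds_y, dtype=float)
    if (np.diff(tx) <= 0).any() or (np.diff(ty) <= 0).any():
        raise ValueError("thresholds must be strictly increasing")
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    xi = np.digitize(z[:, 0], tx)
    yi = np.digitize(z[:, 1], ty)
    table = np.zeros((tx.size + 1, ty.size + 1), dtype=int)
    np.add.at(table, (xi, yi), 1)
    return table
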