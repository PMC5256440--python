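"""Synthetic verbal speed estimates with the experiments' statistical shape.

No raw participant data exist for these experiments, so the pipeline is
exercised with a generative stand-in: an additive Gaussian model on the m/s
scale with

* a per-participant random intercept (compound-symmetric within-participant
  correlation, matching the repeated-measures ANOVA's assumption),
* Direction and Distance main effects plus a Distance x Direction
  interaction, parameterized so the four Distance x Direction cell means hit
  the published values exactly,
* speed sensitivity present only on looming trials (the receding slope is
  zero, encoding the null speed effect for receding sounds),
* occasional "speed of sound" outlier participants whose every answer is a
  plausible value for the speed of sound itself (far above 600 mph), to
  exercise the exclusion filter,
* a mix of mph and km/h reporting units.

Estimates are truncated below at 1 m/s; the default calibration solves for
cell locations whose *truncated* means equal the target cell means, so the
truncation does not bias the calibrated cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .battery import ExperimentDesign, enumerate_trials
from .stats import MPH_PER_MPS, MPS_PER_MPH
from .trajectory import ConfigurationError

#: target Distance x Direction cell means (m/s), published for Experiment 1
EXP1_CELL_MEANS = {
    ("close", "looming"): 45.9,
    ("close", "receding"): 35.2,
    ("distant", "looming"): 32.4,
    ("distant", "receding"): 29.3,
}
#: published cell SDs for Experiment 1 (close/distant x looming/receding)
EXP1_CELL_SDS = {
    ("close", "looming"): 24.1,
    ("close", "receding"): 21.6,
    ("distant", "looming"): 18.6,
    ("distant", "receding"): 22.3,
}
#: Experiment 2 marginals: looming 36.3 / receding 27.6, close 36.9 /
#: distant 27.0, no Distance x Direction interaction reported
EXP2_CELL_MEANS = {
    ("close", "looming"): 41.25,
    ("close", "receding"): 32.55,
    ("distant", "looming"): 31.35,
    ("distant", "receding"): 22.65,
}

MIN_ESTIMATE_MPS = 1.0


@dataclass(frozen=True)
class ResponderParams:
    """Parameters of the additive response model (all speeds in m/s).

    ``baseline`` is the grand mean; ``direction_bias`` the looming minus
    receding gap (split symmetrically); ``distance_bias`` the close minus
    distant gap; ``close_direction_boost`` the extra looming-receding gap on
    close trials (the Distance x Direction interaction).  Speed slopes are
    estimate change per m/s of true speed, centered at 20 m/s.
    """

    baseline: float = 35.7
    direction_bias: float = 6.9
    distance_bias: float = 9.7
    looming_speed_slope: float = 0.32
    receding_speed_slope: float = 0.0
    close_direction_boost: float = 7.6
    participant_sd: float = 19.0
    residual_sd: float = 6.0
    outlier_rate: float = 0.0375
    outlier_floor: float = 600.0 * MPS_PER_MPH  # "speed of sound" answers sit above this
    unit_mix: float = 0.7  # probability a participant reports in mph (vs km/h)
    speed_level_sd: tuple = (0.0, 0.0, 0.0)  # extra per-speed noise (breaks sphericity)
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("participant_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        for name in ("outlier_rate", "unit_mix"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be a probability")
        if self.outlier_floor <= 0:
            raise ConfigurationError("outlier_floor must be positive")

    def cell_mean(self, distance: str, direction: str, speed: float = 20.0) -> float:
        """Model cell location (before truncation and noise)."""
        dir_sign = 1.0 if direction == "looming" else -1.0
        dist_sign = 1.0 if distance == "close" else -1.0
        slope = (self.looming_speed_slope if direction == "looming"
                 else self.receding_speed_slope)
        return (
            self.baseline
            + dir_sign * self.direction_bias / 2.0
            + dist_sign * self.distance_bias / 2.0
            + dir_sign * dist_sign * self.close_direction_boost / 4.0
            + slope * (speed - 20.0)
        )


def _truncated_mean(mu: float, sigma: float, floor: float = MIN_ESTIMATE_MPS) -> float:
    """E[max(floor, X)] for X ~ N(mu, sigma^2)."""
    if sigma == 0:
        return max(mu, floor)
    z = (floor - mu) / sigma
    return floor * norm.cdf(z) + mu * norm.sf(z) + sigma * norm.pdf(z)


def _location_for_target(target: float, sigma: float,
                         floor: float = MIN_ESTIMATE_MPS) -> float:
    """Cell location whose floor-truncated mean equals ``target``."""
    if sigma == 0:
        return target
    return brentq(lambda mu: _truncated_mean(mu, sigma, floor) - target,
                  target - 6 * sigma, target + 6 * sigma, xtol=1e-10)


def _params_from_cells(cell_means: dict, **kwargs) -> ResponderParams:
    """Invert the additive model onto four Distance x Direction cell targets.

    The inversion accounts for the 1 m/s response floor: it solves for cell
    locations whose truncated means equal the targets, then maps those
    locations onto (baseline, direction_bias, distance_bias, boost).
    """
    sds = dict(participant_sd=19.0, residual_sd=6.0)
    sds.update({k: kwargs[k] for k in ("participant_sd", "residual_sd") if k in kwargs})
    sigma = float(np.hypot(sds["participant_sd"], sds["residual_sd"]))
    loc = {
        cell: _location_for_target(m, sigma) for cell, m in cell_means.items()
    }
    cl, cr = loc[("close", "looming")], loc[("close", "receding")]
    dl, dr = loc[("distant", "looming")], loc[("distant", "receding")]
    return ResponderParams(
        baseline=(cl + cr + dl + dr) / 4.0,
        direction_bias=((cl - cr) + (dl - dr)) / 2.0,
        distance_bias=((cl + cr) - (dl + dr)) / 2.0,
        close_direction_boost=(cl - cr) - (dl - dr),
        **kwargs,
    )


def default_params(experiment: int) -> ResponderParams:
    """Calibrated parameters for one experiment.

    Cell locations reproduce the published Distance x Direction cell means;
    the looming speed slope reproduces the published speed-marginal ordering
    (receding slope zero in both experiments); SDs put cell SDs near 20 m/s,
    dominated by the stable per-participant scale rather than trial noise.
    """
    if experiment == 1:
        return _params_from_cells(
            EXP1_CELL_MEANS,
            looming_speed_slope=0.32,
            receding_speed_slope=0.0,
            participant_sd=19.0,
            residual_sd=6.0,
            outlier_rate=3.0 / 80.0,
        )
    if experiment == 2:
        return _params_from_cells(
            EXP2_CELL_MEANS,
            looming_speed_slope=0.28,
            receding_speed_slope=0.0,
            participant_sd=19.0,
            residual_sd=6.0,
            outlier_rate=11.0 / 211.0,
        )
    raise ConfigurationError(f"experiment must be 1 or 2, got {experiment}")


RESPONSE_COLUMNS = (
    "participant_id", "experiment", "distance", "direction", "speed_mps",
    "side", "unit", "estimate", "estimate_mps",
)


def _assign_exp2(i: int, design: ExperimentDesign):
    """Balanced deterministic assignment of participant i to cell and side."""
    cells = design.between_cells
    cell = cells[i % len(cells)]
    side = "left" if (i // len(cells)) % 2 == 0 else "right"
    return cell, side


def generate_responses(design: ExperimentDesign, params: ResponderParams,
                       n_participants: int, seed: int | None = None) -> pd.DataFrame:
    """Simulate a full response table for one experiment.

    Deterministic given the seed (``seed`` argument, falling back to
    ``params.seed``).  Experiment 2 participants are assigned to the four
    Distance x Direction cells and two sides in balanced rotation.
    """
    if n_participants < 2:
        raise ConfigurationError("need at least 2 participants")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    speed_extra = dict(zip(sorted(design.speeds), params.speed_level_sd))

    rows = []
    for i in range(n_participants):
        pid = f"p{i + 1:04d}"
        unit = "mph" if rng.random() < params.unit_mix else "kmh"
        is_outlier = rng.random() < params.outlier_rate
        intercept = rng.normal(0.0, params.participant_sd)
        if design.experiment == 1:
            trials = enumerate_trials(design)
        else:
            cell, side = _assign_exp2(i, design)
            trials = enumerate_trials(design, between_cell=cell, side=side)
        for spec in trials:
            if is_outlier:
                # a genuine "speed of sound" answer, always above the filter
                est = max(params.outlier_floor * 1.01,
                          rng.normal(343.0, 30.0))
            else:
                sd = float(np.hypot(params.residual_sd,
                                    speed_extra.get(spec.speed, 0.0)))
                mu = params.cell_mean(spec.distance_class, spec.direction,
                                      spec.speed)
                est = max(MIN_ESTIMATE_MPS, mu + intercept + rng.normal(0.0, sd))
            reported = est * MPH_PER_MPS if unit == "mph" else est * 3.6
            rows.append((pid, design.experiment, spec.distance_class,
                         spec.direction, spec.speed, spec.side, unit,
                         reported, est))
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def write_responses(table: pd.DataFrame, filename) -> None:
    table.to_csv(filename, index=False)


def read_responses(filename) -> pd.DataFrame:
    table = pd.read_csv(filename)
    missing = set(RESPONSE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    return table
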