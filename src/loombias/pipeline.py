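"""End-to-end replication runs and printed-statistics verification.

A run chains: stimulus battery synthesis (optional on disk) -> synthetic
response generation -> exclusion filter -> unit conversion -> per-condition
averaging -> factorial ANOVA with Greenhouse-Geisser correction ->
follow-up one-way ANOVAs and Tukey post hocs -> t tests and Cohen's d ->
structured report with a provenance record.

Response generation is driven by condition labels, not by the rendered
waveforms: no psychoacoustic transfer function from signal to verbal
estimate is available, so waveform synthesis is validated physically and the
responses statistically.  That decoupling is the deliberate boundary of the
artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .acoustics import SceneConfig
from .battery import ExperimentDesign, render_battery
from .responders import ResponderParams, default_params, generate_responses
from .stats import (
    average_cells,
    cohens_d,
    convert_to_mps,
    exclude_speed_of_sound,
    mixed_anova,
    paired_t,
    partial_eta_sq_from_f,
    rm_anova,
    tukey_hsd,
)
from .trajectory import ConfigurationError

log = logging.getLogger("loombias")

#: statistics printed for the two experiments: effect -> (F, df1, df2, eta_p^2)
PUBLISHED_F = {
    ("exp1", "direction"): (17.8, 1, 76, 0.19),
    ("exp1", "distance"): (76.6, 1, 76, 0.50),
    ("exp1", "speed_x_direction"): (4.6, 2, 152, 0.06),
    ("exp1", "distance_x_direction"): (13.3, 1, 76, 0.15),
    ("exp1", "looming_speed"): (3.1, 2, 68, 0.08),
    ("exp1", "receding_speed"): (0.81, 2, 68, 0.02),
    ("exp2", "direction"): (4.4, 1, 196, 0.02),
    ("exp2", "distance"): (5.7, 1, 196, 0.03),
    ("exp2", "speed"): (3.2, 1.9, 392, 0.02),
    ("exp2", "speed_x_direction"): (9.1, 2, 392, 0.05),
    ("exp2", "looming_speed"): (18.2, 2, 198, 0.16),
}
#: cell statistics printed for Experiment 1: (mean, sd) in m/s
PUBLISHED_CELLS = {
    ("close", "looming"): (45.9, 24.1),
    ("close", "receding"): (35.2, 21.6),
    ("distant", "looming"): (32.4, 18.6),
    ("distant", "receding"): (29.3, 22.3),
}
#: published Cohen's d for the close and distant looming-receding contrasts
PUBLISHED_D = {"close": 0.47, "distant": 0.15}
#: published mph equivalents of the stimulus speeds
PUBLISHED_MPH = {15.0: 33.6, 20.0: 44.7, 25.0: 55.9}


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one replication run."""

    experiment: int = 1
    n_participants: int | None = None
    seed: int = 0
    out_dir: str | None = None
    render_audio: bool = False
    scene: SceneConfig = field(default_factory=SceneConfig)
    responder_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ConfigurationError("experiment must be 1 or 2")
        n = self.resolved_n
        minimum = 4 if self.experiment == 1 else 8
        if n < minimum:
            raise ConfigurationError(
                f"experiment {self.experiment} needs at least {minimum} "
                f"participants, got {n}"
            )

    @property
    def resolved_n(self) -> int:
        if self.n_participants is not None:
            return self.n_participants
        return 80 if self.experiment == 1 else 200


@dataclass
class ReplicationReport:
    """All statistics one replication run produces."""

    experiment: int
    n_generated: int
    excluded: list
    n_analyzed: int
    cell_stats: pd.DataFrame
    anova: pd.DataFrame
    followups: dict
    tukey: dict
    t_tests: pd.DataFrame
    effect_sizes: pd.DataFrame
    provenance: dict

    def to_text(self) -> str:
        lines = [
            f"Replication report - Experiment {self.experiment}",
            f"participants generated: {self.n_generated}; "
            f"excluded (all estimates > 600 mph): {len(self.excluded)}; "
            f"analyzed: {self.n_analyzed}",
            "",
            "Condition cell statistics (m/s):",
            self.cell_stats.to_string(index=False, float_format="%.2f"),
            "",
            "ANOVA (Greenhouse-Geisser df/p alongside uncorrected):",
            self.anova.to_string(index=False, float_format="%.4f"),
        ]
        for name, table in self.followups.items():
            lines += ["", f"Follow-up one-way ANOVA ({name} trials, Speed):",
                      table.to_string(index=False, float_format="%.4f")]
        for name, table in self.tukey.items():
            lines += ["", f"Tukey HSD on Speed ({name} trials):",
                      table.to_string(index=False, float_format="%.4f")]
        if len(self.t_tests):
            lines += ["", "Pairwise t tests:",
                      self.t_tests.to_string(index=False, float_format="%.4f")]
        if len(self.effect_sizes):
            lines += ["", "Cohen's d (pooled SD):",
                      self.effect_sizes.to_string(index=False, float_format="%.3f")]
        lines += ["", f"provenance: {json.dumps(self.provenance)}"]
        return "\n".join(lines)


def _cell_stats(cells: pd.DataFrame) -> pd.DataFrame:
    out = (
        cells.groupby(["distance", "direction"], observed=True)["estimate_mps"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_mps", "std": "sd_mps", "count": "n"})
    )
    return out


def _speed_table(cells: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Per-participant speed means for one direction, distance collapsed."""
    sub = cells[cells["direction"] == direction]
    return (
        sub.groupby(["participant_id", "speed_mps"], observed=True, as_index=False)
        ["estimate_mps"].mean()
    )


def replicate(config: RunConfig) -> ReplicationReport:
    """Run the full pipeline for one experiment and return its report."""
    design = ExperimentDesign(experiment=config.experiment)
    n = config.resolved_n
    rng_seed = int(config.seed)

    if config.render_audio:
        if config.out_dir is None:
            raise ConfigurationError("render_audio requires an out_dir")
        manifest = render_battery(design, config.scene, config.out_dir,
                                  seed=rng_seed)
        log.info("rendered %d stimuli", len(manifest))

    params = default_params(config.experiment)
    if config.responder_overrides:
        params = replace(params, **config.responder_overrides)
    responses = generate_responses(design, params, n, seed=rng_seed)
    log.info("generated %d trials from %d participants", len(responses), n)

    # recompute m/s from the reported unit, then filter
    responses = responses.assign(
        estimate_mps=[
            convert_to_mps(v, u)
            for v, u in zip(responses["estimate"], responses["unit"])
        ]
    )
    kept, excluded = exclude_speed_of_sound(responses)
    log.info("excluded %d participants (all estimates > 600 mph)", len(excluded))

    cells = average_cells(kept)
    n_analyzed = kept["participant_id"].nunique()

    if config.experiment == 1:
        anova = rm_anova(cells)
    else:
        anova = mixed_anova(cells)

    followups, tukey = {}, {}
    for direction in ("looming", "receding"):
        spd = _speed_table(cells, direction)
        one_way = rm_anova(spd, within=("speed_mps",))
        followups[direction] = one_way
        row = one_way.iloc[0]
        level_means = spd.groupby("speed_mps")["estimate_mps"].mean()
        tukey[direction] = tukey_hsd(
            level_means.to_numpy(), row["ms_error"], row["df2"],
            spd["participant_id"].nunique(), labels=[str(s) for s in level_means.index],
        )

    t_rows, d_rows = [], []
    stats_by_cell = {
        (r.distance, r.direction): (r.mean_mps, r.sd_mps)
        for r in _cell_stats(cells).itertuples()
    }
    for dist in ("close", "distant"):
        piv = cells[cells["distance"] == dist].pivot_table(
            index="participant_id", columns="direction", values="estimate_mps",
            aggfunc="mean", observed=True,
        )
        if {"looming", "receding"} <= set(piv.columns):
            loom, reced = piv["looming"], piv["receding"]
            if config.experiment == 1:
                t, df, p = paired_t(loom.dropna(), reced.dropna())
                t_rows.append([f"{dist} looming vs receding (paired)", t, df, p])
            (m1, s1), (m2, s2) = stats_by_cell[(dist, "looming")], \
                stats_by_cell[(dist, "receding")]
            es = cohens_d(m1, s1, m2, s2)
            d_rows.append([f"{dist} looming vs receding", es.d, es.pooled_sd])

    provenance = {
        "package_version": __version__,
        "seed": rng_seed,
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "experiment": config.experiment,
                    "n_participants": n,
                    "seed": rng_seed,
                    "scene": asdict(config.scene),
                    "responder": asdict(params),
                },
                sort_keys=True, default=str,
            ).encode()
        ).hexdigest(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }

    return ReplicationReport(
        experiment=config.experiment,
        n_generated=n,
        excluded=excluded,
        n_analyzed=n_analyzed,
        cell_stats=_cell_stats(cells),
        anova=anova,
        followups=followups,
        tukey=tukey,
        t_tests=pd.DataFrame(t_rows, columns=["contrast", "t", "df", "p"]),
        effect_sizes=pd.DataFrame(d_rows, columns=["contrast", "d", "pooled_sd"]),
        provenance=provenance,
    )


def verify_paper_numbers() -> pd.DataFrame:
    """Recompute every statistic derivable from the printed tables alone.

    Covers the pooled-SD Cohen's d values from the printed cell means/SDs,
    the mph equivalents of the stimulus speeds, and the
    ``eta_p^2 = F df1 / (F df1 + df2)`` identity for each printed F whose
    degrees of freedom are internally consistent.  Returns a check table
    with computed vs published values (published precision: 2 decimals).
    """
    rows = []
    for dist, d_pub in PUBLISHED_D.items():
        (m1, s1) = PUBLISHED_CELLS[(dist, "looming")]
        (m2, s2) = PUBLISHED_CELLS[(dist, "receding")]
        d = cohens_d(m1, s1, m2, s2).d
        rows.append([f"cohens_d_{dist}", d, d_pub, abs(round(d, 2) - d_pub) < 1e-9])
    for mps, mph_pub in PUBLISHED_MPH.items():
        mph = mps / convert_to_mps(1.0, "mph")
        rows.append([f"mph_for_{mps:g}_mps", mph, mph_pub,
                     abs(round(mph, 1) - mph_pub) <= 0.1])
    for (exp, effect), (F, df1, df2, eta_pub) in PUBLISHED_F.items():
        eta = partial_eta_sq_from_f(F, df1, df2)
        # allow one unit in the last printed decimal (published at 2 dp)
        rows.append([f"eta_p_sq_{exp}_{effect}", eta, eta_pub,
                     abs(round(eta, 2) - eta_pub) <= 0.01 + 1e-9])
    return pd.DataFrame(rows, columns=["check", "computed", "published", "ok"])
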