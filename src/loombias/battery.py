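"""Stimulus-set enumeration and rendering for the two experiments.

Experiment 1 is fully within-subjects: every participant hears all
2 Distance x 2 Direction x 3 Speed conditions twice (once from each side),
24 trials.  Experiment 2 assigns each participant to a single
Distance x Direction cell and a single side, with Speed within-subjects:
3 trials per participant.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .acoustics import SceneConfig, synthesize, write_wav
from .trajectory import (
    CANONICAL_SPEEDS,
    DIRECTIONS,
    DISTANCE_CLASSES,
    SIDES,
    ConfigurationError,
    PathSpec,
    make_trajectory,
)

MANIFEST_COLUMNS = (
    "trial_id",
    "distance",
    "direction",
    "speed_mps",
    "side",
    "filename",
    "duration_s",
    "peak_level",
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial structure of one experiment.

    ``experiment=1``: all factors within-subjects, 24 trials/participant.
    ``experiment=2``: Distance and Direction between-subjects, Speed within,
    3 trials/participant.
    """

    experiment: int
    speeds: tuple = CANONICAL_SPEEDS

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ConfigurationError(
                f"experiment must be 1 or 2, got {self.experiment}"
            )

    @property
    def trials_per_participant(self) -> int:
        return 24 if self.experiment == 1 else 3

    @property
    def between_cells(self) -> list:
        return [(d, g) for d in DISTANCE_CLASSES for g in DIRECTIONS]


def enumerate_trials(design: ExperimentDesign, between_cell=None, side=None):
    """List the trial PathSpecs for one participant.

    For Experiment 1 this is the full 24-trial set (every condition from
    both sides).  For Experiment 2 the participant's assigned
    ``between_cell=(distance, direction)`` and ``side`` must be given and the
    set holds one trial per speed.
    """
    if design.experiment == 1:
        return [
            PathSpec(distance_class=d, direction=g, side=s, speed=v)
            for d in DISTANCE_CLASSES
            for g in DIRECTIONS
            for v in design.speeds
            for s in SIDES
        ]
    if between_cell is None or side is None:
        raise ConfigurationError(
            "Experiment 2 trials require the participant's between_cell "
            "(distance, direction) and side"
        )
    distance, direction = between_cell
    return [
        PathSpec(distance_class=distance, direction=direction, side=side, speed=v)
        for v in design.speeds
    ]


def full_stimulus_set(design: ExperimentDesign):
    """Every distinct waveform the experiment can present (24 for both:
    12 conditions x 2 sides; Experiment 2 participants each hear 3 of them)."""
    return [
        PathSpec(distance_class=d, direction=g, side=s, speed=v)
        for d in DISTANCE_CLASSES
        for g in DIRECTIONS
        for v in design.speeds
        for s in SIDES
    ]


def render_battery(design: ExperimentDesign, scene: SceneConfig | None = None,
                   out_dir=".", seed: int | None = None) -> list:
    """Render every stimulus in the design to WAV and write a manifest CSV.

    All stimuli share one normalization constant (peak 0.98 across the
    battery) so inter-stimulus level ratios are preserved.  If ``seed`` is
    given, the manifest rows are listed in a seeded random presentation
    order (analysis is order-blind); the rendering itself is deterministic.

    Returns the manifest as a list of dicts and writes ``manifest.csv``.
    """
    scene = scene or SceneConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    specs = full_stimulus_set(design)
    stimuli = [synthesize(make_trajectory(p), scene) for p in specs]
    global_peak = max(s.peak for s in stimuli)
    scale = 0.98 / global_peak

    order = np.arange(len(specs))
    if seed is not None:
        order = np.random.default_rng(seed).permutation(order)

    manifest = []
    for trial_id, idx in enumerate(order, start=1):
        spec, stim = specs[idx], stimuli[idx].scaled(scale)
        filename = f"{spec.label}.wav"
        try:
            write_wav(stim, out / filename)
        except OSError as exc:
            raise OSError(f"failed writing {out / filename}: {exc}") from exc
        manifest.append(
            {
                "trial_id": trial_id,
                "distance": spec.distance_class,
                "direction": spec.direction,
                "speed_mps": spec.speed,
                "side": spec.side,
                "filename": filename,
                "duration_s": round(stim.duration, 6),
                "peak_level": round(stim.peak, 6),
            }
        )

    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        writer.writerows(manifest)
    return manifest
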