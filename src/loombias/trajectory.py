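"""Deterministic source kinematics along the straight bypass path.

A virtual sound source travels on a straight line parallel to the listener's
interaural axis, offset laterally by a fixed miss distance.  The listener is
at the origin of a right-handed frame with

* ``x`` along the interaural axis (+x toward the right ear),
* ``y`` pointing from the listener toward the source path,
* ``z`` up.

"Close" paths run between 2 m and 47 m from the median plane (the y-z plane),
"distant" paths between 15 m and 60 m; both therefore cover 45 m of travel.
Looming trials end at the near bound, receding trials start there.  The
listener's ear height is taken equal to the source height (0.5 m), so the
lateral offset is the true miss distance at closest approach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CANONICAL_SPEEDS = (15.0, 20.0, 25.0)
PATH_LENGTH = 45.0
NEAR_BOUNDS = {"close": 2.0, "distant": 15.0}
FAR_BOUNDS = {"close": 47.0, "distant": 60.0}

DISTANCE_CLASSES = ("close", "distant")
DIRECTIONS = ("looming", "receding")
SIDES = ("left", "right")


class ConfigurationError(ValueError):
    """Raised when a path or scene field is outside its valid domain."""


@dataclass(frozen=True)
class PathSpec:
    """One experimental trajectory condition.

    Parameters
    ----------
    distance_class : {"close", "distant"}
        Close paths span 2-47 m from the median plane, distant paths 15-60 m.
    direction : {"looming", "receding"}
        Looming sources approach the near bound; receding sources leave it.
    side : {"left", "right"}
        Side of the head the source passes on; mirrors the x coordinate.
    speed : float
        Source speed in m/s (the experiments use 15, 20 or 25).
    lateral_offset : float
        Perpendicular miss distance from listener to path, m.
    source_height : float
        Height of the source above ground, m.
    """

    distance_class: str
    direction: str
    side: str
    speed: float
    lateral_offset: float = 2.0
    source_height: float = 0.5
    near_bound: float | None = None
    far_bound: float | None = None

    def __post_init__(self) -> None:
        if self.distance_class not in DISTANCE_CLASSES:
            raise ConfigurationError(
                f"distance_class must be one of {DISTANCE_CLASSES}, "
                f"got {self.distance_class!r}"
            )
        if self.direction not in DIRECTIONS:
            raise ConfigurationError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if self.side not in SIDES:
            raise ConfigurationError(
                f"side must be one of {SIDES}, got {self.side!r}"
            )
        if not self.speed > 0:
            raise ConfigurationError(f"speed must be positive, got {self.speed}")
        if not self.lateral_offset > 0:
            raise ConfigurationError(
                f"lateral_offset must be positive, got {self.lateral_offset}"
            )
        if self.source_height < 0:
            raise ConfigurationError(
                f"source_height must be nonnegative, got {self.source_height}"
            )
        if self.near_bound is None:
            object.__setattr__(self, "near_bound", NEAR_BOUNDS[self.distance_class])
        if self.far_bound is None:
            object.__setattr__(self, "far_bound", FAR_BOUNDS[self.distance_class])
        if not 0 <= self.near_bound < self.far_bound:
            raise ConfigurationError(
                f"bounds must satisfy 0 <= near_bound < far_bound, "
                f"got near_bound={self.near_bound}, far_bound={self.far_bound}"
            )

    @property
    def path_length(self) -> float:
        return self.far_bound - self.near_bound

    @property
    def label(self) -> str:
        return (
            f"{self.distance_class}_{self.direction}_"
            f"{self.speed:g}mps_{self.side}"
        )


@dataclass(frozen=True)
class Trajectory:
    """Continuous-time kinematics for one :class:`PathSpec`.

    ``duration = path_length / speed``; the along-path (|x|) coordinate runs
    from ``far_bound`` down to ``near_bound`` for looming trials and the
    reverse for receding trials.
    """

    path: PathSpec
    duration: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "duration", self.path.path_length / self.path.speed)

    def _along_path(self, t: np.ndarray) -> np.ndarray:
        p = self.path
        if p.direction == "looming":
            return p.far_bound - p.speed * t
        return p.near_bound + p.speed * t

    def position(self, t):
        """Source position at time(s) ``t``, shape (..., 3), listener frame."""
        t = np.asarray(t, dtype=float)
        u = self._along_path(t)
        sign = 1.0 if self.path.side == "right" else -1.0
        x = sign * u
        y = np.full_like(t, self.path.lateral_offset)
        z = np.full_like(t, self.path.source_height)
        return np.stack([x, y, z], axis=-1)

    def velocity(self, t):
        """Source velocity, shape (..., 3); constant along the path."""
        t = np.asarray(t, dtype=float)
        sign = 1.0 if self.path.side == "right" else -1.0
        rate = -self.path.speed if self.path.direction == "looming" else self.path.speed
        vx = np.full_like(t, sign * rate)
        zeros = np.zeros_like(t)
        return np.stack([vx, zeros, zeros], axis=-1)


@dataclass(frozen=True)
class StaticTrajectory:
    """A motionless source held at a fixed position for ``duration`` seconds.

    Not part of any experimental design; used to validate the renderer in its
    static limit (no Doppler, constant gain).
    """

    fixed_position: tuple[float, float, float]
    duration: float

    def position(self, t):
        t = np.asarray(t, dtype=float)
        out = np.empty(t.shape + (3,))
        out[...] = np.asarray(self.fixed_position, dtype=float)
        return out

    def velocity(self, t):
        t = np.asarray(t, dtype=float)
        return np.zeros(t.shape + (3,))


def make_trajectory(path: PathSpec) -> Trajectory:
    """Build the deterministic trajectory for one condition.

    Raises :class:`ConfigurationError` for invalid path fields (validation is
    performed by :class:`PathSpec` itself).
    """
    return Trajectory(path=path)


def radial_state(traj, t, reference_point):
    """Distance and radial velocity of the source relative to a point.

    Parameters
    ----------
    traj : Trajectory or StaticTrajectory
    t : float or array
        Time(s) within ``[0, duration]``.
    reference_point : length-3 sequence
        Point in the listener frame (e.g. an ear position), m.

    Returns
    -------
    (distance, radial_velocity)
        ``radial_velocity`` is d(distance)/dt, positive when receding.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < -1e-12) or np.any(t_arr > traj.duration + 1e-12):
        raise ValueError(
            f"t must lie in [0, {traj.duration}], got range "
            f"[{t_arr.min()}, {t_arr.max()}]"
        )
    ref = np.asarray(reference_point, dtype=float)
    rel = traj.position(t_arr) - ref
    dist = np.linalg.norm(rel, axis=-1)
    vel = traj.velocity(t_arr)
    # d|r|/dt = (r . v) / |r|
    vr = np.einsum("...i,...i->...", rel, vel) / dist
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(dist), float(vr)
    return dist, vr
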