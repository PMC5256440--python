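"""Binaural rendering of a moving harmonic source.

The source is a band-limited square wave (odd harmonics of a 400 Hz
fundamental).  Rendering is by additive synthesis: each harmonic's
instantaneous phase is the time integral of its Doppler-shifted received
frequency, and its instantaneous amplitude combines

* spherical spreading loss (1/r pressure law),
* atmospheric absorption in the ISO 9613-1 pure-tone form, evaluated at the
  harmonic's instantaneous received frequency,
* a single image source mirrored through the ground plane, scaled by a
  frequency-independent reflectivity,
* a parametric two-ear model: per-ear path lengths give natural interaural
  time and level differences, and the far ear gets a first-order low-pass
  head-shadow whose cutoff scales with head radius.

This is exact for a harmonic source (no resampling interpolation artifacts)
and makes per-harmonic absorption trivial.  The emission-time correction is
omitted; at source speeds <= 25 m/s the resulting frequency error is far
below the 1 % validation tolerance.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .trajectory import ConfigurationError, PathSpec, radial_state


class SynthesisError(RuntimeError):
    """Raised when a stimulus cannot be rendered (e.g. no harmonic fits)."""


@dataclass(frozen=True)
class SceneConfig:
    """Physical constants and rendering options for one synthesis run.

    Defaults: 44.1 kHz sampling, 400 Hz square-wave fundamental, 343 m/s
    speed of sound, 20 degC / 50 % RH air, ground reflectivity 0.95,
    spherical-head radius 8.75 cm, 10 ms raised-cosine ramps, unit gain at
    1 m.  Ear height matches the 0.5 m source height so the stated lateral
    offset is the true miss distance.
    """

    sample_rate: float = 44100.0
    f0: float = 400.0
    speed_of_sound: float = 343.0
    temperature: float = 20.0
    relative_humidity: float = 50.0
    ground_reflectivity: float = 0.95
    head_radius: float = 0.0875
    ear_height: float = 0.5
    ramp_ms: float = 10.0
    reference_distance: float = 1.0
    air_absorption: bool = True
    ground_reflection: bool = True
    head_shadow: bool = True
    nyquist_margin: float = 0.95

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ConfigurationError(f"sample_rate must be positive: {self.sample_rate}")
        if not self.f0 > 0:
            raise ConfigurationError(f"f0 must be positive: {self.f0}")
        if not 0.0 <= self.ground_reflectivity <= 1.0:
            raise ConfigurationError(
                f"ground_reflectivity must be in [0, 1]: {self.ground_reflectivity}"
            )
        if not self.speed_of_sound > 0:
            raise ConfigurationError(
                f"speed_of_sound must be positive: {self.speed_of_sound}"
            )
        if not self.reference_distance > 0:
            raise ConfigurationError(
                f"reference_distance must be positive: {self.reference_distance}"
            )

    def ear_positions(self) -> dict:
        a = self.head_radius
        return {
            "left": np.array([-a, 0.0, self.ear_height]),
            "right": np.array([a, 0.0, self.ear_height]),
        }


@dataclass(frozen=True)
class BinauralStimulus:
    """Two-channel sampled waveform plus its condition metadata."""

    left: np.ndarray
    right: np.ndarray
    sample_rate: float
    path: PathSpec | None = None

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ValueError("left and right channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.left)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def peak(self) -> float:
        return float(max(np.abs(self.left).max(), np.abs(self.right).max()))

    def scaled(self, scale: float) -> "BinauralStimulus":
        return replace(self, left=self.left * scale, right=self.right * scale)

    def normalized(self, peak: float = 0.98) -> "BinauralStimulus":
        return self.scaled(peak / self.peak)

    def stereo(self) -> np.ndarray:
        return np.stack([self.left, self.right], axis=1)


def doppler_frequency(f_emitted, radial_velocity, c):
    """Received frequency for a source with the given radial velocity.

    ``f_received = f_emitted / (1 + v_r / c)`` with ``v_r`` positive when the
    source recedes.  Raises for |v_r| >= c.
    """
    vr = np.asarray(radial_velocity, dtype=float)
    if np.any(np.abs(vr) >= c):
        raise ValueError(f"|radial_velocity| must be < c = {c}")
    return f_emitted / (1.0 + vr / c)


def spreading_gain(distance, reference_distance):
    """Inverse-distance pressure gain, unity at the reference distance."""
    dist = np.asarray(distance, dtype=float)
    if np.any(dist <= 0):
        raise ValueError("distance must be positive")
    if reference_distance <= 0:
        raise ValueError("reference_distance must be positive")
    return reference_distance / dist


def air_absorption_coefficient(frequency, temperature=20.0, relative_humidity=50.0,
                               pressure_atm=1.0):
    """Pure-tone atmospheric attenuation coefficient, dB per metre.

    ISO 9613-1 form: classical plus nitrogen/oxygen relaxation terms, as a
    function of frequency, air temperature (degC), relative humidity (%) and
    ambient pressure (atm).  Monotone nondecreasing in frequency.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    if not -20.0 <= temperature <= 50.0:
        raise ValueError(f"temperature {temperature} degC outside model range [-20, 50]")
    if not 0.0 < relative_humidity <= 100.0:
        raise ValueError(
            f"relative_humidity {relative_humidity} % outside model range (0, 100]"
        )
    T = temperature + 273.15
    T0 = 293.15
    T01 = 273.16
    pr = pressure_atm  # ratio p_a / p_ref
    # molar concentration of water vapour (%)
    C = -6.8346 * (T01 / T) ** 1.261 + 4.6151
    h = relative_humidity * 10.0 ** C / pr
    # relaxation frequencies of oxygen and nitrogen (Hz)
    fr_o = pr * (24.0 + 4.04e4 * h * (0.02 + h) / (0.391 + h))
    fr_n = pr * (T0 / T) ** 0.5 * (
        9.0 + 280.0 * h * np.exp(-4.17 * ((T0 / T) ** (1.0 / 3.0) - 1.0))
    )
    f2 = f * f
    alpha = 8.686 * f2 * (
        1.84e-11 / pr * (T / T0) ** 0.5
        + (T / T0) ** -2.5
        * (
            0.01275 * np.exp(-2239.1 / T) / (fr_o + f2 / fr_o)
            + 0.1068 * np.exp(-3352.0 / T) / (fr_n + f2 / fr_n)
        )
    )
    return alpha


def air_absorption_db(frequency, distance, temperature=20.0, relative_humidity=50.0):
    """Total atmospheric attenuation over a path, in dB (>= 0)."""
    dist = np.asarray(distance, dtype=float)
    if np.any(dist < 0):
        raise ValueError("distance must be nonnegative")
    return air_absorption_coefficient(frequency, temperature, relative_humidity) * dist


def ground_reflection_paths(traj, t, ear_position, source_height=None, ear_height=None):
    """Direct and ground-bounce path lengths from source to one ear.

    The bounce path is the distance to the image source mirrored through the
    ground plane (z -> -z); it is never shorter than the direct path.
    Heights default to those implied by the trajectory and ear position.
    """
    ear = np.asarray(ear_position, dtype=float)
    pos = traj.position(np.asarray(t, dtype=float))
    if source_height is not None:
        pos = pos.copy()
        pos[..., 2] = source_height
    if ear_height is not None:
        ear = ear.copy()
        ear[2] = ear_height
    if np.any(pos[..., 2] < 0) or ear[2] < 0:
        raise ValueError("heights must be nonnegative for a ground plane at z=0")
    direct = np.linalg.norm(pos - ear, axis=-1)
    image = pos.copy()
    image[..., 2] = -image[..., 2]
    bounced = np.linalg.norm(image - ear, axis=-1)
    if np.ndim(t) == 0:
        return float(direct), float(bounced)
    return direct, bounced


def _mirrored(traj):
    """View of a trajectory reflected through the ground plane."""

    class _Mirror:
        duration = traj.duration

        @staticmethod
        def position(t):
            p = traj.position(t).copy()
            p[..., 2] = -p[..., 2]
            return p

        @staticmethod
        def velocity(t):
            v = traj.velocity(t).copy()
            v[..., 2] = -v[..., 2]
            return v

    return _Mirror()


def _harmonic_orders(scene: SceneConfig, max_approach_speed: float) -> np.ndarray:
    """Odd harmonic orders kept for a whole stimulus.

    The cutoff uses the worst-case approach speed so the harmonic set is
    constant within one stimulus (no mid-stimulus timbre steps) and the
    maximum received frequency stays below the Nyquist margin.
    """
    c = scene.speed_of_sound
    worst = 1.0 / (1.0 - max_approach_speed / c)
    limit = scene.nyquist_margin * scene.sample_rate / 2.0
    n_max = int(np.floor(limit / (scene.f0 * worst)))
    orders = np.arange(1, n_max + 1, 2)
    if orders.size == 0:
        raise SynthesisError(
            f"no harmonic of f0={scene.f0} Hz fits below the Nyquist margin"
        )
    return orders


def _render_path(dist, vr, orders, scene: SceneConfig, shadowed: bool) -> np.ndarray:
    """Sum of odd harmonics for one propagation path to one ear."""
    c = scene.speed_of_sound
    dt = 1.0 / scene.sample_rate
    f_inst = doppler_frequency(scene.f0, vr, c)  # instantaneous fundamental
    phase0 = -2.0 * np.pi * scene.f0 * dist[0] / c  # absolute-delay offset -> ITD
    phase = 2.0 * np.pi * cumulative_trapezoid(f_inst, dx=dt, initial=0.0) + phase0
    gain = spreading_gain(dist, scene.reference_distance)
    out = np.zeros_like(dist)
    fc = c / (2.0 * np.pi * scene.head_radius)  # head-shadow corner frequency
    for n in orders:
        fn = n * f_inst
        amp = gain / n
        if scene.air_absorption:
            att_db = air_absorption_coefficient(
                fn, scene.temperature, scene.relative_humidity
            ) * dist
            amp = amp * 10.0 ** (-att_db / 20.0)
        if shadowed and scene.head_shadow:
            amp = amp / np.sqrt(1.0 + (fn / fc) ** 2)
        out += amp * np.sin(n * phase)
    return out


def synthesize(traj, scene: SceneConfig | None = None, path: PathSpec | None = None
               ) -> BinauralStimulus:
    """Render a trajectory into a two-channel stimulus.

    Returns the raw (unnormalized) waveform; battery rendering applies one
    shared normalization constant so inter-stimulus level ratios are
    preserved.  ``path`` metadata defaults to ``traj.path`` when present.
    """
    scene = scene or SceneConfig()
    if path is None:
        path = getattr(traj, "path", None)
    n_samples = int(round(traj.duration * scene.sample_rate))
    if n_samples < 2:
        raise SynthesisError("trajectory too short to render")
    t = np.arange(n_samples) / scene.sample_rate

    ears = scene.ear_positions()
    mirrored = _mirrored(traj) if scene.ground_reflection else None

    # Worst-case approach speed over both ears and both paths sets the
    # harmonic cutoff for the whole stimulus.
    v_app = 0.0
    states = {}
    for name, ear in ears.items():
        d, vr = radial_state(traj, t, ear)
        states[name] = (d, vr)
        v_app = max(v_app, float(np.max(-vr, initial=0.0)))
        if mirrored is not None:
            di, vri = radial_state(mirrored, t, ear)
            states[name + "_image"] = (di, vri)
            v_app = max(v_app, float(np.max(-vri, initial=0.0)))
    orders = _harmonic_orders(scene, v_app)

    shadow_side = None
    if path is not None:
        shadow_side = "left" if path.side == "right" else "right"

    channels = {}
    for name, ear in ears.items():
        shadowed = name == shadow_side
        d, vr = states[name]
        sig = _render_path(d, vr, orders, scene, shadowed)
        if mirrored is not None and scene.ground_reflectivity > 0:
            di, vri = states[name + "_image"]
            sig = sig + scene.ground_reflectivity * _render_path(
                di, vri, orders, scene, shadowed
            )
        channels[name] = sig

    ramp_n = int(round(scene.ramp_ms / 1000.0 * scene.sample_rate))
    if ramp_n > 0:
        ramp_n = min(ramp_n, n_samples // 2)
        win = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        for sig in channels.values():
            sig[:ramp_n] *= win
            sig[-ramp_n:] *= win[::-1]

    return BinauralStimulus(
        left=channels["left"],
        right=channels["right"],
        sample_rate=scene.sample_rate,
        path=path,
    )


def write_wav(stimulus: BinauralStimulus, filename) -> None:
    """Write a stimulus as 2-channel 16-bit PCM RIFF/WAVE."""
    data = stimulus.stereo()
    peak = np.abs(data).max()
    if peak > 1.0:
        raise ValueError(
            f"peak amplitude {peak:.3f} exceeds 1; normalize before writing"
        )
    pcm = np.round(data * 32767.0).astype("<i2")
    path = Path(filename)
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(2)
        fh.setsampwidth(2)
        fh.setframerate(int(round(stimulus.sample_rate)))
        fh.writeframes(pcm.tobytes())
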