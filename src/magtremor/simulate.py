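"""Ground-truth trajectory and tapping-signal generators.

These emulate the bench protocols used to validate the tracker: a robotic
arm carries the transmitter along a known path while a small servo adds a
tremor-like oscillation, and a fingertip-mounted transmitter performs
repeated tapping.  Three scenarios are covered:

* tremor test — a closed square/circle path with a superimposed small-angle
  servo oscillation (action tremor, up to 10 Hz);
* stop-movement test — linear locomotion with a 2 Hz oscillation for the
  first ~3 s, then a stationary hold with a 5 Hz oscillation until 8.5 s;
* finger tapping — near-periodic ~5 Hz taps for the healthy condition, and
  randomly slowed taps with short pauses for the simulated disease
  condition (bradykinesia-like: energy spread below 5 Hz).

All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coils import CoilArray, Pose, VoltageFrame, VOLUME_CENTER, simulate_frame
from .estimator import Trajectory
from .spectral import SampledSignal

__all__ = [
    "TremorSpec",
    "TapSpec",
    "square_trajectory",
    "circle_trajectory",
    "add_tremor",
    "sm_trajectory",
    "ft_signal",
    "trajectory_to_frames",
]

DEFAULT_RATE = 62.0
_UP = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class TremorSpec:
    """Servo-driven oscillation superimposed on a carrier trajectory.

    The servo sweeps ``servo_angle_deg`` peak rotation at ``frequency``; a
    lever arm of ``lever_mm`` converts rotation to fingertip displacement,
    giving a sinusoid of amplitude lever · sin(angle) on each selected axis.
    """

    frequency: float = 10.0
    servo_angle_deg: float = 10.0
    lever_mm: float = 30.0
    axes: tuple = ("x", "y")

    def __post_init__(self):
        if not (0.0 < self.frequency <= 31.0):
            raise ValueError("tremor frequency must be in (0, 31] Hz")
        if self.servo_angle_deg < 0:
            raise ValueError("servo angle must be non-negative")

    @property
    def amplitude_m(self) -> float:
        return self.lever_mm * 1e-3 * np.sin(np.radians(self.servo_angle_deg))


@dataclass(frozen=True)
class TapSpec:
    """Parameters of one synthetic finger-tapping take.

    Healthy takes tap at a near-constant ``base_rate`` (default 5 Hz) with
    small period/amplitude jitter.  Disease takes stretch each inter-tap
    interval by a random slowdown factor and insert short pauses, which
    spreads the spectrum below 5 Hz and breaks periodicity.
    """

    condition: str = "no-disease"
    duration: float | None = None
    base_rate: float = 5.0
    rate_jitter: float = 0.03
    pause_prob: float = 0.25
    pause_range: tuple = (0.3, 1.0)
    amplitude_jitter: float = 0.05
    slowdown_range: tuple = (1.2, 2.5)
    seed: int = 0

    def __post_init__(self):
        if self.condition not in ("no-disease", "disease"):
            raise ValueError("condition must be 'no-disease' or 'disease'")
        if self.condition == "no-disease":
            object.__setattr__(self, "pause_prob", 0.0)
        if self.duration is None:
            # defaults chosen to land in the 10-20 taps-per-take regime
            object.__setattr__(
                self, "duration", 3.0 if self.condition == "no-disease" else 7.0
            )


def _closed_path_trajectory(path_fn, duration_s: float, rate: float,
                            orientation=_UP) -> Trajectory:
    n = int(round(duration_s * rate))
    times = np.arange(n) / rate
    frac = np.linspace(0.0, 1.0, n)  # start == end point
    positions = path_fn(frac)
    poses = [Pose(position=positions[i], orientation=orientation) for i in range(n)]
    return Trajectory(times=times, poses=poses, rate=rate)


def square_trajectory(
    side_m: float = 0.10,
    duration_s: float = 15.0,
    rate: float = DEFAULT_RATE,
    center=None,
) -> Trajectory:
    """Closed square path traversed at constant speed, constant orientation
    (+z), constant height."""
    if side_m <= 0 or duration_s <= 0:
        raise ValueError("side and duration must be positive")
    c = VOLUME_CENTER if center is None else np.asarray(center, dtype=float)
    h = side_m / 2.0
    corners = np.array(
        [[-h, -h, 0], [h, -h, 0], [h, h, 0], [-h, h, 0], [-h, -h, 0]]
    ) + c

    def path(frac):
        s = frac * 4.0  # perimeter parameter, one unit per side
        leg = np.minimum(s.astype(int), 3)
        u = s - leg
        return corners[leg] + u[:, None] * (corners[leg + 1] - corners[leg])

    return _closed_path_trajectory(path, duration_s, rate)


def circle_trajectory(
    radius_m: float = 0.05,
    duration_s: float = 15.0,
    rate: float = DEFAULT_RATE,
    center=None,
) -> Trajectory:
    """Closed circular path at constant angular speed, constant orientation."""
    if radius_m <= 0 or duration_s <= 0:
        raise ValueError("radius and duration must be positive")
    c = VOLUME_CENTER if center is None else np.asarray(center, dtype=float)

    def path(frac):
        ang = 2.0 * np.pi * frac
        return c + radius_m * np.stack(
            [np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1
        )

    return _closed_path_trajectory(path, duration_s, rate)


def add_tremor(traj: Trajectory, spec: TremorSpec) -> Trajectory:
    """Superimpose the servo oscillation on the selected axes (phase 0 at t=0)."""
    if spec.frequency >= traj.rate / 2.0:
        raise ValueError("tremor frequency must be below Nyquist")
    disp = spec.amplitude_m * np.sin(2.0 * np.pi * spec.frequency * traj.times)
    offset = np.zeros((len(traj), 3))
    for ax in spec.axes:
        offset[:, {"x": 0, "y": 1, "z": 2}[ax]] = disp
    poses = [
        Pose(position=p.position + offset[i], orientation=p.orientation)
        for i, p in enumerate(traj.poses)
    ]
    return Trajectory(times=traj.times.copy(), poses=poses, rate=traj.rate)


def sm_trajectory(
    rate: float = DEFAULT_RATE,
    move_time: float = 3.0,
    total_time: float = 8.5,
    move_freq: float = 2.0,
    stop_freq: float = 5.0,
    osc_amp_mm: float = 5.0,
    speed: float = 0.03,
    start=None,
) -> Trajectory:
    """Two-phase stop-movement trajectory.

    Up to ``move_time`` the base point moves linearly (along the x-y diagonal
    at ``speed`` m/s) with a ``move_freq`` oscillation on x and y; afterwards
    the base holds still and the oscillation switches to ``stop_freq``, until
    ``total_time``.
    """
    n = int(round(total_time * rate))
    times = np.arange(n) / rate
    s0 = (
        np.array([-0.06, -0.06, VOLUME_CENTER[2]])
        if start is None
        else np.asarray(start, dtype=float)
    )
    direction = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)
    progress = np.minimum(times, move_time)
    base = s0 + progress[:, None] * speed * direction

    moving = times <= move_time
    freq = np.where(moving, move_freq, stop_freq)
    osc = osc_amp_mm * 1e-3 * np.sin(2.0 * np.pi * freq * times)
    positions = base.copy()
    positions[:, 0] += osc
    positions[:, 1] += osc
    poses = [Pose(position=positions[i], orientation=_UP) for i in range(n)]
    return Trajectory(times=times, poses=poses, rate=rate)


def _tap_waveform(n: int, amplitude: float) -> np.ndarray:
    """One open-close tap: squared raised cosine (sharper than a sinusoid, so
    a periodic train carries a visible first harmonic)."""
    u = np.arange(n) / n
    return amplitude * ((1.0 - np.cos(2.0 * np.pi * u)) / 2.0) ** 2


def ft_signal(spec: TapSpec, rate: float = DEFAULT_RATE) -> SampledSignal:
    """Synthesize the fingertip z-coordinate of one tapping take.

    Returns a dimensionless waveform in [0, 1]; downstream feature extraction
    rescales per take, so absolute amplitude carries no information.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = int(round(spec.duration * rate))
    z = np.zeros(n_total)
    t = 0.0
    while t < spec.duration:
        period = (1.0 / spec.base_rate) * (1.0 + rng.normal(0.0, spec.rate_jitter))
        if spec.condition == "disease":
            period *= rng.uniform(*spec.slowdown_range)
        period = max(period, 2.0 / rate)
        amp = max(1.0 + rng.normal(0.0, spec.amplitude_jitter), 0.1)
        i0 = int(round(t * rate))
        n_tap = int(round(period * rate))
        seg = _tap_waveform(n_tap, amp)[: max(0, n_total - i0)]
        z[i0 : i0 + len(seg)] = seg
        t += period
        if spec.condition == "disease" and rng.random() < spec.pause_prob:
            t += rng.uniform(*spec.pause_range)
    return SampledSignal(values=z, rate=rate, label="z")


def trajectory_to_frames(
    traj: Trajectory,
    array: CoilArray,
    snr_db=None,
    seed: int | None = None,
) -> list:
    """Run every trajectory sample through the coil forward model."""
    rng = np.random.default_rng(seed)
    return [
        simulate_frame(p, array, snr_db=snr_db, seed=rng, timestamp=t)
        for t, p in zip(traj.times, traj.poses)
    ]
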