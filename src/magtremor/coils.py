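"""Coil-array forward model.

A small transmitting coil (TX) driven at its resonant frequency behaves as an
oscillating magnetic dipole.  Each passive receiving coil (RX) of a fixed
array picks up an induced RMS voltage proportional to the component of the
dipole field along its axis.  Given the TX pose (position + orientation unit
vector) this module synthesizes the 24-channel voltage vector the tracker
would measure, optionally degraded by per-channel Gaussian noise at a chosen
signal-to-noise ratio, so that the inverse problem can be exercised without
hardware.

Conventions: right-handed frame, origin at the center of the horizontal
receiver grid, z up into the 30 x 30 x 30 cm tracking volume, SI units
(meters, volts, tesla) internally.  Because an RMS detector discards phase,
simulated frames carry |V|; the matching sign convention is applied by the
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np

__all__ = [
    "MU0_OVER_4PI",
    "TRACKING_VOLUME",
    "VOLUME_CENTER",
    "ReceiverCoil",
    "TransmitterSpec",
    "CoilArray",
    "Pose",
    "VoltageFrame",
    "default_array",
    "dipole_field",
    "induced_voltage",
    "forward_voltages",
    "voltage_design_matrix",
    "simulate_frame",
    "draw_channel_snrs",
]

MU0_OVER_4PI = 1e-7  # T·m/A, vacuum permeability / 4π

#: Axis-aligned tracking volume bounds, meters: ((xlo, xhi), (ylo, yhi), (zlo, zhi)).
TRACKING_VOLUME = ((-0.15, 0.15), (-0.15, 0.15), (0.0, 0.30))
VOLUME_CENTER = np.array([0.0, 0.0, 0.15])


def _as_vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class ReceiverCoil:
    """One passive pickup coil: position, axis and winding parameters."""

    position: np.ndarray
    normal: np.ndarray
    windings: int = 252
    radius: float = 0.0095  # meters

    def __post_init__(self):
        object.__setattr__(self, "position", _as_vec3(self.position, "position"))
        n = _as_vec3(self.normal, "normal")
        if abs(np.linalg.norm(n) - 1.0) > 1e-12:
            raise ValueError("receiver normal must be unit length (within 1e-12)")
        object.__setattr__(self, "normal", n)
        if self.windings <= 0:
            raise ValueError("windings must be positive")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def area(self) -> float:
        """Single-turn cross-section, m^2."""
        return np.pi * self.radius**2


@dataclass(frozen=True)
class TransmitterSpec:
    """Active coil parameters.

    The drive current only enters the model as a global amplitude scale, so
    its default (1 A RMS) is a convention rather than a physical calibration.
    """

    windings: int = 36
    radius: float = 0.005  # meters
    current: float = 1.0  # amperes RMS
    frequency: float = 182_000.0  # Hz, LC resonance

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")

    @property
    def area(self) -> float:
        return np.pi * self.radius**2

    @property
    def moment(self) -> float:
        """Magnetic dipole moment N·S·I, A·m^2."""
        return self.windings * self.area * self.current


@dataclass(frozen=True)
class Pose:
    """Transmitter position (m) and orientation unit vector."""

    position: np.ndarray
    orientation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", _as_vec3(self.position, "position"))
        n = _as_vec3(self.orientation, "orientation")
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("orientation must be unit length (within 1e-9)")
        object.__setattr__(self, "orientation", n)

    @property
    def theta(self) -> np.ndarray:
        """Concatenated [position, orientation] state vector."""
        return np.concatenate([self.position, self.orientation])


@dataclass(frozen=True)
class CoilArray:
    """Fixed receiver array plus the transmitter specification."""

    receivers: tuple
    transmitter: TransmitterSpec = field(default_factory=TransmitterSpec)

    def __post_init__(self):
        object.__setattr__(self, "receivers", tuple(self.receivers))
        pos = np.array([r.position for r in self.receivers])
        if len(pos) and len(np.unique(np.round(pos, 12), axis=0)) != len(pos):
            raise ValueError("receiver positions must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.receivers)

    @cached_property
    def positions(self) -> np.ndarray:
        """(N, 3) receiver centers, meters."""
        return np.array([r.position for r in self.receivers])

    @cached_property
    def normals(self) -> np.ndarray:
        """(N, 3) receiver axis unit vectors."""
        return np.array([r.normal for r in self.receivers])

    @cached_property
    def rx_gains(self) -> np.ndarray:
        """(N,) pickup gains 2π·f0·N_rx·S_rx, volts per tesla."""
        f0 = self.transmitter.frequency
        return np.array(
            [2.0 * np.pi * f0 * r.windings * r.area for r in self.receivers]
        )


def default_array(transmitter: TransmitterSpec | None = None) -> CoilArray:
    """Build the reference 24-receiver tri-planar array.

    Sixteen receivers sit on the horizontal X-Y plane on a regular 4x4 grid
    spanning a 24 cm square (axes +z).  Four more sit on each vertical plane
    (X-Z and Y-Z) at the vertices of an 8 cm square centered at mid-height of
    the tracking volume, axes pointing into the volume (+y and +x).
    """
    tx = transmitter or TransmitterSpec()
    rxs: list[ReceiverCoil] = []
    grid = np.linspace(-0.12, 0.12, 4)
    for x in grid:
        for y in grid:
            rxs.append(ReceiverCoil(position=[x, y, 0.0], normal=[0.0, 0.0, 1.0]))
    half = 0.04
    zc = VOLUME_CENTER[2]
    for sx in (-half, half):
        for sz in (-half, half):
            rxs.append(
                ReceiverCoil(position=[sx, -0.15, zc + sz], normal=[0.0, 1.0, 0.0])
            )
    for sy in (-half, half):
        for sz in (-half, half):
            rxs.append(
                ReceiverCoil(position=[-0.15, sy, zc + sz], normal=[1.0, 0.0, 0.0])
            )
    return CoilArray(receivers=tuple(rxs), transmitter=tx)


@dataclass(frozen=True)
class VoltageFrame:
    """One synchronous vector of RMS voltages from the whole array."""

    timestamp: float
    voltages: np.ndarray
    snr_db: float | None = None

    def __post_init__(self):
        v = np.asarray(self.voltages, dtype=float)
        if v.ndim != 1:
            raise ValueError("voltages must be a 1-D vector")
        if np.any(v < 0):
            raise ValueError("RMS voltages must be non-negative")
        object.__setattr__(self, "voltages", v)

    def __len__(self) -> int:
        return len(self.voltages)


def dipole_field(pose: Pose, tx: TransmitterSpec, point) -> np.ndarray:
    """RMS magnetic field of the TX dipole at ``point``, tesla.

    B = (mu0 / 4 pi) (m / d^3) [3 (n_tx . n_d) n_d - n_tx] with d the
    TX-to-point distance and n_d the unit vector from TX to the point.
    """
    point = _as_vec3(point, "point")
    d = point - pose.position
    dist = float(np.linalg.norm(d))
    if dist < 1e-12:
        raise ValueError("field point coincides with the transmitter (singular)")
    nd = d / dist
    n_tx = pose.orientation
    return (
        MU0_OVER_4PI
        * tx.moment
        / dist**3
        * (3.0 * np.dot(n_tx, nd) * nd - n_tx)
    )


def induced_voltage(field, rx: ReceiverCoil, tx: TransmitterSpec) -> float:
    """Signed RMS voltage induced on one receiver by a homogeneous field.

    Faraday pickup under the homogeneous-field approximation:
    V = 2π f0 N_rx S_rx (B · n_rx).  The hardware detector reports |V|;
    callers that emulate it take the magnitude.
    """
    field = _as_vec3(field, "field")
    return float(
        2.0 * np.pi * tx.frequency * rx.windings * rx.area * np.dot(field, rx.normal)
    )


def forward_voltages(position, orientation, array: CoilArray) -> np.ndarray:
    """|V| on every receiver for a TX at (position, orientation), vectorized.

    Raises ValueError if the TX coincides with a receiver center.
    """
    position = np.asarray(position, dtype=float)
    orientation = np.asarray(orientation, dtype=float)
    d = array.positions - position  # (N, 3), TX -> RX
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist < 1e-9):
        raise ValueError("pose coincides with a receiver position")
    nd = d / dist[:, None]
    proj = nd @ orientation  # (N,)
    b = (
        (MU0_OVER_4PI * array.transmitter.moment / dist**3)[:, None]
        * (3.0 * proj[:, None] * nd - orientation)
    )
    v = array.rx_gains * np.einsum("ij,ij->i", b, array.normals)
    return np.abs(v)


def voltage_design_matrix(positions, array: CoilArray) -> np.ndarray:
    """Matrix M(r) with signed voltages V = M @ n_tx, for one or many TX
    positions.

    The dipole field is linear in the TX orientation, so for a fixed position
    the full signed channel vector is a matrix product; this is the workhorse
    of coarse global scans in the estimator.  Shape (N, 3) for a single
    position, (G, N, 3) for a stack of G positions.
    """
    pos = np.asarray(positions, dtype=float)
    single = pos.ndim == 1
    pos = np.atleast_2d(pos)  # (G, 3)
    d = array.positions[None, :, :] - pos[:, None, :]  # (G, N, 3)
    dist = np.linalg.norm(d, axis=2)
    if np.any(dist < 1e-9):
        raise ValueError("position coincides with a receiver")
    nd = d / dist[..., None]
    c = MU0_OVER_4PI * array.transmitter.moment / dist**3  # (G, N)
    proj = np.einsum("gnj,nj->gn", nd, array.normals)  # n_rx . n_d
    m = (c * array.rx_gains)[..., None] * (
        3.0 * proj[..., None] * nd - array.normals[None, :, :]
    )
    return m[0] if single else m


def draw_channel_snrs(
    rng: np.random.Generator,
    n: int,
    mean_db: float = 20.0,
    sd_db: float = 13.0,
    floor_db: float = 1.0,
) -> np.ndarray:
    """Draw per-channel SNRs (dB) from a truncated normal, emulating the
    channel-to-channel SNR spread of a real array."""
    snrs = rng.normal(mean_db, sd_db, size=n)
    return np.maximum(snrs, floor_db)


def simulate_frame(
    pose: Pose,
    array: CoilArray,
    snr_db=None,
    seed: int | np.random.Generator | None = None,
    timestamp: float = 0.0,
) -> VoltageFrame:
    """Synthesize one measured frame at ``pose``.

    With ``snr_db`` unset the frame is the exact forward model |V|.  With a
    scalar (or per-channel vector) SNR in dB, independent zero-mean Gaussian
    noise with standard deviation = channel signal · 10^(−snr/20) is added to
    each channel, then clipped at zero since the detector reports magnitudes.
    Deterministic for a given seed.
    """
    clean = forward_voltages(pose.position, pose.orientation, array)
    if snr_db is None:
        return VoltageFrame(timestamp=timestamp, voltages=clean, snr_db=None)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    snr = np.broadcast_to(np.asarray(snr_db, dtype=float), clean.shape)
    sigma = clean * 10.0 ** (-snr / 20.0)
    noisy = np.clip(clean + rng.normal(0.0, 1.0, size=clean.shape) * sigma, 0.0, None)
    meta = float(snr[0]) if np.all(snr == snr[0]) else None
    return VoltageFrame(timestamp=timestamp, voltages=noisy, snr_db=meta)
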