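"""Inverse problem: recover the transmitter pose from one voltage frame.

The pose is found by least squares on the magnitude forward model,

    F(theta) = sum_i [ V_meas,i - |V_model,i(theta)| ]^2 ,

minimized with the Nelder-Mead simplex.  The optimizer works on five free
parameters — position (x, y, z) plus orientation azimuth/elevation — so the
unit-norm constraint on the orientation is structural rather than enforced.
Because the measurement is phase-free, theta and the orientation-flipped
theta produce identical frames; estimates are canonicalized to a
non-negative z component (ties broken toward non-negative x) and angular
errors should be read modulo that flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .coils import CoilArray, Pose, VoltageFrame, VOLUME_CENTER, forward_voltages

__all__ = [
    "EstimationResult",
    "Trajectory",
    "cost",
    "estimate_pose",
    "coarse_scan",
    "estimate_pose_multistart",
    "track",
    "angular_error_deg",
    "canonical_orientation",
]

#: Simplex size (m / rad) below which Nelder-Mead is considered converged.
XATOL = 1e-6
FATOL = 1e-12
MAXITER = 2000
#: Frames whose largest channel is below this are treated as signal-free.
DEGENERATE_VOLTAGE = 1e-12


@dataclass(frozen=True)
class EstimationResult:
    pose: Pose
    cost: float
    iterations: int
    converged: bool


@dataclass
class Trajectory:
    """Time-ordered pose sequence at a fixed nominal rate."""

    times: np.ndarray
    poses: list
    rate: float = 62.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.poses):
            raise ValueError("times and poses must have equal length")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) positions in meters."""
        return np.array([p.position for p in self.poses])

    @property
    def orientations(self) -> np.ndarray:
        return np.array([p.orientation for p in self.poses])

    def coordinate(self, axis: str) -> np.ndarray:
        """One cartesian coordinate series in millimeters."""
        idx = {"x": 0, "y": 1, "z": 2}[axis]
        return self.positions[:, idx] * 1e3


def _angles_from_unit(n: np.ndarray) -> tuple[float, float]:
    az = float(np.arctan2(n[1], n[0]))
    el = float(np.arcsin(np.clip(n[2], -1.0, 1.0)))
    return az, el


def _unit_from_angles(az: float, el: float) -> np.ndarray:
    ce = np.cos(el)
    return np.array([ce * np.cos(az), ce * np.sin(az), np.sin(el)])


def _pack(pose: Pose) -> np.ndarray:
    az, el = _angles_from_unit(pose.orientation)
    return np.array([*pose.position, az, el])


def _unpack(p: np.ndarray) -> Pose:
    return Pose(position=p[:3].copy(), orientation=_unit_from_angles(p[3], p[4]))


def canonical_orientation(n: np.ndarray) -> np.ndarray:
    """Resolve the sign ambiguity: non-negative z, tie toward non-negative x."""
    n = np.asarray(n, dtype=float)
    if n[2] < 0 or (n[2] == 0 and n[0] < 0):
        return -n
    return n.copy()


def angular_error_deg(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Angle (degrees) between orientation axes, modulo the sign flip."""
    c = abs(float(np.dot(estimated, truth)))
    c /= float(np.linalg.norm(estimated) * np.linalg.norm(truth))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def cost(pose: Pose, frame: VoltageFrame, array: CoilArray) -> float:
    """Sum of squared residuals between measured and modeled |V|, volts^2."""
    if len(frame) != len(array):
        raise ValueError(
            f"frame has {len(frame)} channels but array has {len(array)} receivers"
        )
    model = forward_voltages(pose.position, pose.orientation, array)
    r = frame.voltages - model
    return float(r @ r)


def _objective(frame: VoltageFrame, array: CoilArray, solve_scale: bool):
    meas = frame.voltages

    def fun(p: np.ndarray) -> float:
        try:
            model = forward_voltages(p[:3], _unit_from_angles(p[3], p[4]), array)
        except ValueError:
            return np.inf
        if solve_scale:
            denom = model @ model
            if denom > 0:
                model = model * ((model @ meas) / denom)
        r = meas - model
        return float(r @ r)

    return fun


def estimate_pose(
    frame: VoltageFrame,
    array: CoilArray,
    init: Pose,
    solve_scale: bool = False,
    xatol: float = XATOL,
    fatol: float = FATOL,
    maxiter: int = MAXITER,
) -> EstimationResult:
    """Minimize the least-squares cost from ``init`` with Nelder-Mead.

    ``solve_scale=True`` enables a split solver: the global amplitude (the
    dipole-moment scale) is eliminated in closed form by linear least squares
    at every cost evaluation, leaving the simplex to search geometry only.
    Both modes agree on noiseless data; the default is the plain 5-parameter
    search.

    Frames with no usable signal are returned unchanged and flagged
    ``converged=False``.
    """
    if len(frame) != len(array):
        raise ValueError("frame/array channel count mismatch")
    if np.max(frame.voltages) < DEGENERATE_VOLTAGE:
        return EstimationResult(pose=init, cost=cost(init, frame, array),
                                iterations=0, converged=False)
    fun = _objective(frame, array, solve_scale)
    res = minimize(
        fun,
        _pack(init),
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter, "maxfev": 10 * maxiter},
    )
    pose = _unpack(res.x)
    pose = Pose(position=pose.position,
                orientation=canonical_orientation(pose.orientation))
    return EstimationResult(
        pose=pose,
        cost=float(res.fun),
        iterations=int(res.nit),
        converged=bool(res.success),
    )


def _hemisphere_directions(n: int) -> np.ndarray:
    """n roughly uniform unit vectors on the upper half-sphere (Fibonacci
    lattice); the magnitude model makes the lower half redundant."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def coarse_scan(
    frame: VoltageFrame,
    array: CoilArray,
    n_grid: int = 8,
    n_orientations: int = 26,
    n_candidates: int = 5,
    min_separation: float = 0.05,
) -> list[Pose]:
    """Global scan of the cost on a position grid x orientation lattice.

    Because the signed channel vector is linear in the orientation for fixed
    position, the cost over all (position, orientation) pairs reduces to one
    matrix product per grid slab.  Returns up to ``n_candidates`` low-cost
    poses that are mutually at least ``min_separation`` apart, to seed local
    refinement in distinct basins.
    """
    from .coils import voltage_design_matrix

    (xlo, xhi), (ylo, yhi), (zlo, zhi) = (
        (-0.11, 0.11), (-0.11, 0.11), (0.04, 0.26)
    )
    xs = np.linspace(xlo, xhi, n_grid)
    ys = np.linspace(ylo, yhi, n_grid)
    zs = np.linspace(zlo, zhi, n_grid)
    grid = np.array(np.meshgrid(xs, ys, zs, indexing="ij")).reshape(3, -1).T
    dirs = _hemisphere_directions(n_orientations)  # (K, 3)
    m = voltage_design_matrix(grid, array)  # (G, N, 3)
    model = np.abs(m @ dirs.T)  # (G, N, K)
    resid = model - frame.voltages[None, :, None]
    costs = np.einsum("gnk,gnk->gk", resid, resid)  # (G, K)
    best_k = np.argmin(costs, axis=1)
    best_cost = costs[np.arange(len(grid)), best_k]
    order = np.argsort(best_cost)
    out: list[Pose] = []
    for g in order:
        pos = grid[g]
        if all(np.linalg.norm(pos - p.position) > min_separation for p in out):
            out.append(Pose(position=pos, orientation=dirs[best_k[g]]))
        if len(out) >= n_candidates:
            break
    return out


_DENSE_DIRS = _hemisphere_directions(200)
_FINE_OFFSETS: np.ndarray | None = None


def _scan_cost(frame: VoltageFrame, array: CoilArray, positions: np.ndarray,
               dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Lowest-cost (position, orientation) over a stack of candidate
    positions x orientation lattice, fully vectorized."""
    from .coils import voltage_design_matrix

    m = voltage_design_matrix(positions, array)
    model = np.abs(m @ dirs.T)
    resid = model - frame.voltages[None, :, None]
    costs = np.einsum("gnk,gnk->gk", resid, resid)
    g, k = np.unravel_index(int(np.argmin(costs)), costs.shape)
    return positions[g], dirs[k], float(costs[g, k])


def estimate_pose_multistart(
    frame: VoltageFrame,
    array: CoilArray,
    n_candidates: int = 5,
    n_hops: int = 6,
    **kwargs,
) -> EstimationResult:
    """Cold-start estimate via global scan + multi-basin refinement.

    The magnitude model's cost surface carries several well-separated local
    minima at realistic noise levels, so a single descent is unreliable.
    Strategy: (1) coarse global scan over the tracking volume; (2) around
    each surviving candidate, a fine vectorized position x orientation scan
    (covering one coarse-grid cell at ~5 mm pitch); (3) Nelder-Mead descent
    from each fine-scan winner; (4) a few deterministic perturbed restarts
    ("basin hops", +-8 mm and ~17 deg) around the overall best.  All stages
    are deterministic for a given frame.
    """
    global _FINE_OFFSETS
    if _FINE_OFFSETS is None:
        ax = np.linspace(-0.02, 0.02, 9)
        _FINE_OFFSETS = np.array(np.meshgrid(ax, ax, ax, indexing="ij")).reshape(3, -1).T
    if np.max(frame.voltages) < DEGENERATE_VOLTAGE:
        init = Pose(position=VOLUME_CENTER, orientation=np.array([0.0, 0.0, 1.0]))
        return estimate_pose(frame, array, init, **kwargs)
    best: EstimationResult | None = None
    for cand in coarse_scan(frame, array, n_candidates=n_candidates):
        pos = cand.position + _FINE_OFFSETS
        pos = pos[pos[:, 2] > 0.005]
        p0, d0, _ = _scan_cost(frame, array, pos, _DENSE_DIRS)
        res = estimate_pose(frame, array, Pose(position=p0, orientation=d0), **kwargs)
        if best is None or res.cost < best.cost:
            best = res
    hop_rng = np.random.default_rng(0)  # fixed: hops are part of the algorithm
    for _ in range(n_hops):
        dp = hop_rng.uniform(-0.008, 0.008, 3)
        v = best.pose.orientation + hop_rng.normal(0.0, 0.3, 3)
        v /= np.linalg.norm(v)
        try:
            res = estimate_pose(
                frame, array, Pose(position=best.pose.position + dp, orientation=v),
                **kwargs,
            )
        except ValueError:
            continue
        if res.cost < best.cost:
            best = res
    return best


def track(
    frames,
    array: CoilArray,
    init: Pose | None = None,
    rate: float = 62.0,
    **kwargs,
) -> Trajectory:
    """Estimate a frame sequence with warm starts.

    Frame 0 is solved from ``init`` if given, otherwise by multi-start from
    the volume center; every later frame starts from the previous estimate,
    emulating a real-time tracking loop.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame sequence")
    poses: list[Pose] = []
    times = np.array([f.timestamp for f in frames])
    for k, frame in enumerate(frames):
        if k == 0:
            if init is not None:
                res = estimate_pose(frame, array, init, **kwargs)
            else:
                res = estimate_pose_multistart(frame, array, **kwargs)
        else:
            res = estimate_pose(frame, array, poses[-1], **kwargs)
        poses.append(res.pose)
    return Trajectory(times=times, poses=poses, rate=rate)
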