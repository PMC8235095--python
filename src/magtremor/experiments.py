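"""End-to-end experiment runners on synthetic data.

Each function reproduces one bench protocol — action-tremor tracking,
stop-movement detection, static accuracy, finger tapping — by generating the
ground truth, pushing it through the coil forward model and the pose
estimator, and applying the corresponding analysis.  They return plain dicts
so the CLI ``demo`` subcommand and reproduction scripts can serialize them
directly.
"""

from __future__ import annotations

import numpy as np

from .classify import FeatureDataset, knn_cv
from .coils import Pose, default_array
from .estimator import angular_error_deg, estimate_pose_multistart, track
from .simulate import (
    TapSpec,
    TremorSpec,
    add_tremor,
    ft_signal,
    sm_trajectory,
    square_trajectory,
    trajectory_to_frames,
)
from .spectral import (
    SampledSignal,
    dft_spectrum,
    dominant_frequency,
    frequency_change_time,
    highpass,
    spectrogram,
)
from .tapping import TapTake, extract_features

__all__ = [
    "run_tremor_experiment",
    "run_sm_experiment",
    "run_static_accuracy",
    "make_tap_population",
    "run_tapping_experiment",
    "run_demo",
]

SM_MOVE_BAND = (1.5, 3.5)  # Hz, locomotion-phase oscillation
SM_STOP_BAND = (4.0, 6.0)  # Hz, stop-phase oscillation


def _estimated_coordinate(traj_true, array, snr_db, seed, axis="x"):
    frames = trajectory_to_frames(traj_true, array, snr_db=snr_db, seed=seed)
    est = track(frames, array, init=traj_true.poses[0])
    return est, SampledSignal(values=est.coordinate(axis), rate=est.rate, label=axis)


def run_tremor_experiment(
    seed: int = 0,
    tremor_hz: float = 10.0,
    snr_db: float = 20.0,
    duration_s: float = 15.0,
    cutoff_hz: float = 2.5,
) -> dict:
    """Square-path action-tremor run: simulate, invert, filter, locate the
    tremor line in the spectrum of each horizontal coordinate."""
    truth = add_tremor(
        square_trajectory(duration_s=duration_s),
        TremorSpec(frequency=tremor_hz),
    )
    array = default_array()
    frames = trajectory_to_frames(truth, array, snr_db=snr_db, seed=seed)
    est = track(frames, array, init=truth.poses[0])
    out = {"tremor_hz_injected": tremor_hz, "snr_db": snr_db}
    for axis in ("x", "y"):
        sig = SampledSignal(values=est.coordinate(axis), rate=est.rate, label=axis)
        spec = dft_spectrum(highpass(sig, cutoff_hz))
        out[f"dominant_hz_{axis}"] = dominant_frequency(spec, (cutoff_hz, 31.0))
    return out


def run_sm_experiment(
    seed: int = 0,
    snr_db: float = 20.0,
    cutoff_hz: float = 1.0,
    move_time: float = 3.0,
) -> dict:
    """Stop-movement run: per-phase dominant frequencies on the filtered x
    coordinate and the spectrogram change time."""
    truth = sm_trajectory(move_time=move_time)
    array = default_array()
    _, sig = _estimated_coordinate(truth, array, snr_db, seed, "x")
    filt = highpass(sig, cutoff_hz)
    loco = dft_spectrum(filt.slice(0.0, move_time))
    stop = dft_spectrum(filt.slice(move_time, np.inf))
    spg = spectrogram(filt)
    return {
        "snr_db": snr_db,
        "locomotion_dominant_hz": dominant_frequency(loco, (cutoff_hz, 31.0)),
        "stop_dominant_hz": dominant_frequency(stop, (cutoff_hz, 31.0)),
        "change_time_s": frequency_change_time(spg, SM_MOVE_BAND, SM_STOP_BAND),
        "hop_s": float(np.diff(spg.window_times)[0]) if len(spg.window_times) > 1 else None,
    }


def random_central_poses(rng: np.random.Generator, n: int) -> list:
    """Uniform poses in the central 20 cm cube with isotropic orientations."""
    poses = []
    for _ in range(n):
        pos = np.array(
            [rng.uniform(-0.10, 0.10), rng.uniform(-0.10, 0.10), rng.uniform(0.05, 0.25)]
        )
        v = rng.normal(size=3)
        poses.append(Pose(position=pos, orientation=v / np.linalg.norm(v)))
    return poses


def run_static_accuracy(
    seed: int = 0,
    n_poses: int = 200,
    snr_db: float = 20.0,
) -> dict:
    """Monte-Carlo static accuracy: mean position / orientation error over
    random central-volume poses, cold-started from the volume center."""
    rng = np.random.default_rng(seed)
    array = default_array()
    pos_err_mm, ang_err_deg = [], []
    from .coils import simulate_frame  # local import to keep module top light

    for pose in random_central_poses(rng, n_poses):
        frame = simulate_frame(pose, array, snr_db=snr_db, seed=rng)
        res = estimate_pose_multistart(frame, array)
        pos_err_mm.append(
            float(np.linalg.norm(res.pose.position - pose.position)) * 1e3
        )
        ang_err_deg.append(angular_error_deg(res.pose.orientation, pose.orientation))
    return {
        "n_poses": n_poses,
        "snr_db": snr_db,
        "mean_position_error_mm": float(np.mean(pos_err_mm)),
        "std_position_error_mm": float(np.std(pos_err_mm)),
        "mean_angle_error_deg": float(np.mean(ang_err_deg)),
        "std_angle_error_deg": float(np.std(ang_err_deg)),
    }


def make_tap_population(
    seed: int = 0,
    n_nodisease: int = 17,
    n_disease: int = 20,
) -> list:
    """Synthetic tapping cohort (one TapTake per take), sized like a small
    two-condition bench study."""
    takes = []
    for i in range(n_nodisease):
        sig = ft_signal(TapSpec(condition="no-disease", seed=seed * 10007 + i))
        takes.append(TapTake(z_raw=sig.values, rate=sig.rate, label="no-disease"))
    for i in range(n_disease):
        sig = ft_signal(TapSpec(condition="disease", seed=seed * 10007 + 1000 + i))
        takes.append(TapTake(z_raw=sig.values, rate=sig.rate, label="disease"))
    return takes


def run_tapping_experiment(seed: int = 0, k: int = 10, folds: int = 5) -> dict:
    """Feature extraction + k-NN cross-validation on the synthetic cohort,
    for each feature subset of interest."""
    takes = make_tap_population(seed)
    feats = [extract_features(t) for t in takes]
    out = {
        "n_nodisease": sum(f.label == "no-disease" for f in feats),
        "n_disease": sum(f.label == "disease" for f in feats),
    }
    subsets = {
        "acc_int14_int412": ("int1_4", "int4_12"),
        "acc_int14_ftts": ("int1_4", "ftts"),
        "acc_int412_ftts": ("int4_12", "ftts"),
        "acc_all3": ("int1_4", "int4_12", "ftts"),
    }
    for key, subset in subsets.items():
        ds = FeatureDataset.from_features(feats, subset=subset)
        out[key] = knn_cv(ds, k=k, folds=folds, seed=seed)
    out["mean_pm_nodisease"] = float(
        np.mean([f.pm for f in feats if f.label == "no-disease"])
    )
    out["mean_pm_disease"] = float(
        np.mean([f.pm for f in feats if f.label == "disease"])
    )
    return out


def run_demo(seed: int = 0, n_poses: int = 200) -> dict:
    """Run all experiments at default settings and consolidate the report."""
    return {
        "seed": seed,
        "tremor": run_tremor_experiment(seed=seed),
        "stop_movement": run_sm_experiment(seed=seed),
        "static_accuracy": run_static_accuracy(seed=seed, n_poses=n_poses),
        "tapping": run_tapping_experiment(seed=seed),
    }
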