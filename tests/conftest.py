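"""Shared fixtures: cached synthetic recordings and small builders."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitval import (
    DropoutModel,
    ExerciseProfile,
    Foot,
    GroundTruthTrajectory,
    ImuRecording,
    NoiseModel,
    SegmenterConfig,
    generate_trajectory,
    trajectory_to_imu,
    trajectory_to_mocap,
)

GRAVITY = 9.81


@pytest.fixture(scope="session")
def normal_walk():
    """(trajectory, truths) for a seeded normal walk."""
    profile = ExerciseProfile.for_kind("normal_walk")
    return generate_trajectory(profile, Foot.LEFT, 7)


@pytest.fixture(scope="session")
def noiseless_imu(normal_walk):
    traj, _ = normal_walk
    return trajectory_to_imu(traj, NoiseModel.noiseless())


@pytest.fixture(scope="session")
def noisy_imu(normal_walk):
    traj, _ = normal_walk
    return trajectory_to_imu(traj, NoiseModel(seed=7, clock_offset=0.0))


@pytest.fixture(scope="session")
def pristine_mocap(normal_walk):
    traj, _ = normal_walk
    return trajectory_to_mocap(traj, DropoutModel.pristine())


@pytest.fixture
def seg_config():
    return SegmenterConfig()


def constant_velocity_trajectory(speed: float, duration: float = 60.0,
                                 rate: float = 600.0) -> GroundTruthTrajectory:
    """Straight-line trajectory at constant horizontal speed (no stance)."""
    time = np.arange(0.0, duration, 1.0 / rate)
    n = len(time)
    velocity = np.zeros((n, 3))
    velocity[:, 0] = speed
    position = np.zeros((n, 3))
    position[:, 0] = speed * time
    return GroundTruthTrajectory(
        time=time, position=position, velocity=velocity,
        orientation=Rotation.identity(n), stance_mask=np.zeros(n, dtype=bool))


def stationary_imu(duration: float = 12.0, rate: float = 100.0) -> ImuRecording:
    """Level, motionless device: accel (0, 0, +g), gyro 0."""
    time = np.arange(0.0, duration, 1.0 / rate)
    accel = np.zeros((len(time), 3))
    accel[:, 2] = GRAVITY
    gyro = np.zeros((len(time), 3))
    return ImuRecording(time, accel, gyro)
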