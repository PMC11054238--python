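"""Stride feature definitions shared by the inertial and mocap pipelines.

Both pipelines call this single implementation, so any wearable-vs-mocap
disagreement reflects the signals, never a difference in feature definitions.
"""

from __future__ import annotations

import numpy as np


def stride_features(positions: np.ndarray, duration: float,
                    path_length_mode: bool = False) -> tuple[float, float]:
    """Stride length (m) and mean horizontal velocity (m/s).

    Parameters
    ----------
    positions
        (m, 3) trajectory samples spanning the stride interval, first and last
        samples at the stride boundaries.
    duration
        Stride interval duration in seconds.
    path_length_mode
        If true, report the horizontal path length instead of the default
        straight-line horizontal displacement between the boundaries.
    """
    xy = positions[:, :2]
    if path_length_mode:
        length = float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))
    else:
        length = float(np.linalg.norm(xy[-1] - xy[0]))
    return length, length / duration
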