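"""Uniformly sampled marker displacement time series (mm, default 120 Hz).

Axis convention follows the motion-capture setup: X mediolateral,
Y vertical, Z anteroposterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    """Displacement history of one marker.

    ``times`` are strictly increasing with constant step ``1/sample_rate``;
    ``displacement`` is (n_frames, 3) in mm.
    """

    times: np.ndarray
    displacement: np.ndarray
    sample_rate: float = 120.0
    marker: str = "clavicle"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.times.ndim != 1 or self.displacement.shape != (self.times.size, 3):
            raise ValueError("times (n,) and displacement (n, 3) required")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.displacement)):
            raise ValueError("trajectory contains non-finite values")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if dt.min() <= 0 or not np.allclose(dt, 1.0 / self.sample_rate, rtol=1e-6, atol=1e-9):
                raise ValueError("times must increase with constant step 1/sample_rate")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def axis(self, name: str) -> np.ndarray:
        """Return one displacement component ('x' | 'y' | 'z' or 0..2)."""
        idx = {"x": 0, "y": 1, "z": 2}.get(name, name) if isinstance(name, str) else name
        return self.displacement[:, idx]

    def resample(self, t: np.ndarray, kind: str = "linear") -> np.ndarray:
        """Interpolated displacement at arbitrary times (n, 3).

        ``kind="cubic"`` uses a clamped cubic spline (twice differentiable,
        suitable for prescribing motion to a dynamic solver)."""
        t = np.asarray(t, dtype=float)
        if kind == "cubic" and self.times.size >= 4:
            from scipy.interpolate import CubicSpline
            return CubicSpline(self.times, self.displacement, axis=0)(
                np.clip(t, self.times[0], self.times[-1]))
        return np.column_stack([
            np.interp(t, self.times, self.displacement[:, k]) for k in range(3)
        ])


def save_trajectories_csv(path, trajectories) -> None:
    """Write one or more trajectories to CSV with the header
    ``time_s,marker,dx_mm,dy_mm,dz_mm``."""
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    frames = []
    for tr in trajectories:
        frames.append(pd.DataFrame({
            "time_s": tr.times, "marker": tr.marker,
            "dx_mm": tr.displacement[:, 0],
            "dy_mm": tr.displacement[:, 1],
            "dz_mm": tr.displacement[:, 2],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_trajectories_csv(path) -> dict:
    """Read a marker CSV back into ``{marker: Trajectory}``."""
    df = pd.read_csv(path)
    out = {}
    for marker, grp in df.groupby("marker", sort=False):
        t = grp["time_s"].to_numpy()
        rate = 1.0 / np.mean(np.diff(t)) if t.size > 1 else 120.0
        out[marker] = Trajectory(
            times=t,
            displacement=grp[["dx_mm", "dy_mm", "dz_mm"]].to_numpy(),
            sample_rate=float(round(rate, 6)),
            marker=str(marker),
        )
    return out
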