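"""Shared time-series container for detector pressure traces."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PressureTrace"]


@dataclass
class PressureTrace:
    """Pressure time series at one or more point detectors.

    times
        Seconds, uniform step; t = 0 is the incident beam-pulse peak.
    pressure
        mPa per proton, shape (n_detectors, n_times).
    detector_positions_mm
        (n_detectors, 3) array of (x, y, z) positions, mm.
    """

    times: np.ndarray
    pressure: np.ndarray
    detector_positions_mm: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressure = np.atleast_2d(np.asarray(self.pressure, dtype=float))
        self.detector_positions_mm = np.atleast_2d(
            np.asarray(self.detector_positions_mm, dtype=float)
        )
        if self.pressure.shape != (len(self.detector_positions_mm), len(self.times)):
            raise ValueError(
                f"pressure shape {self.pressure.shape} inconsistent with "
                f"{len(self.detector_positions_mm)} detectors × {len(self.times)} samples"
            )
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
            raise ValueError("time axis must be uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_detectors(self) -> int:
        return self.pressure.shape[0]

    def single(self, index: int = 0) -> "PressureTrace":
        """One-detector view of this trace."""
        return PressureTrace(
            self.times,
            self.pressure[index : index + 1],
            self.detector_positions_mm[index : index + 1],
        )

    def same_axes(self, other: "PressureTrace") -> bool:
        return (
            self.pressure.shape == other.pressure.shape
            and np.allclose(self.times, other.times)
            and np.allclose(self.detector_positions_mm, other.detector_positions_mm)
        )

    def save_txt(self, path) -> None:
        """Write a delimited text container: header + one column per detector."""
        header_lines = ["ionomark pressure trace", "units: t s, p mPa/proton"]
        for i, pos in enumerate(self.detector_positions_mm):
            header_lines.append(
                f"detector {i}: x={pos[0]:.4f} y={pos[1]:.4f} z={pos[2]:.4f} mm"
            )
        data = np.column_stack([self.times, self.pressure.T])
        np.savetxt(path, data, header="\n".join(header_lines))

    @classmethod
    def load_txt(cls, path) -> "PressureTrace":
        positions = []
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "detector" in line:
                    parts = dict(
                        kv.split("=") for kv in line.split(":")[1].split() if "=" in kv
                    )
                    positions.append(
                        [float(parts["x"]), float(parts["y"]), float(parts["z"].rstrip())]
                    )
        data = np.loadtxt(path)
        return cls(data[:, 0], data[:, 1:].T, np.asarray(positions))
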