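"""Named per-frame scalar series with units and provenance."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class DescriptorSeries:
    """One scalar descriptor sampled along a trajectory."""

    name: str
    units: str
    values: np.ndarray
    times_ps: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times_ps is None:
            self.times_ps = np.arange(len(self.values), dtype=np.float64)
        self.times_ps = np.asarray(self.times_ps, dtype=np.float64)
        if len(self.times_ps) != len(self.values):
            raise ValueError("times and values length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.values)),
                "time_ps": self.times_ps,
                "value": self.values,
                "units": self.units,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def read_csv(path: str | Path, name: str | None = None) -> "DescriptorSeries":
        df = pd.read_csv(path)
        units = str(df["units"].iloc[0]) if "units" in df else ""
        return DescriptorSeries(
            name=name or Path(path).stem,
            units=units,
            values=df["value"].to_numpy(),
            times_ps=df["time_ps"].to_numpy() if "time_ps" in df else None,
        )
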