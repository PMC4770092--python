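"""Censoring-aware dwell-time container.

A dwell is one uninterrupted visit to the open or closed conformation.
The first and last dwells of any finite recording are censored (their
true duration is unknown) and are excluded from rate estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OPEN = 0
CLOSED = 1
STATE_NAMES = {OPEN: "open", CLOSED: "closed"}


@dataclass
class DwellSet:
    """Alternating sequence of dwells with per-dwell mean force.

    Attributes are parallel arrays; ``meta`` carries the originating
    condition (ligand, concentration, trap separation, seed, ...).
    """

    state: np.ndarray  # int, OPEN/CLOSED
    duration: np.ndarray  # s
    mean_force: np.ndarray  # pN (nan when no force channel)
    censored: np.ndarray  # bool
    t_start: np.ndarray | None = None  # s
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=int)
        self.duration = np.asarray(self.duration, dtype=float)
        self.mean_force = np.asarray(self.mean_force, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        n = self.state.size
        for name in ("duration", "mean_force", "censored"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.duration <= 0):
            raise ValueError("dwell durations must be > 0")

    def __len__(self) -> int:
        return self.state.size

    def usable(self, state: int) -> "DwellSet":
        """Uncensored dwells of one state."""
        keep = (self.state == state) & ~self.censored
        return DwellSet(
            state=self.state[keep],
            duration=self.duration[keep],
            mean_force=self.mean_force[keep],
            censored=self.censored[keep],
            t_start=None if self.t_start is None else np.asarray(self.t_start)[keep],
            meta=dict(self.meta),
        )

    def n_usable(self, state: int) -> int:
        return int(np.sum((self.state == state) & ~self.censored))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "state": [STATE_NAMES[s] for s in self.state],
                "duration_s": self.duration,
                "mean_force_pN": self.mean_force,
                "censored": self.censored,
            }
        )
        if self.t_start is not None:
            df.insert(1, "t_start_s", np.asarray(self.t_start, dtype=float))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "DwellSet":
        name_to_state = {v: k for k, v in STATE_NAMES.items()}
        return cls(
            state=np.array([name_to_state[s] for s in df["state"]]),
            duration=df["duration_s"].to_numpy(),
            mean_force=df["mean_force_pN"].to_numpy(),
            censored=df["censored"].to_numpy(dtype=bool),
            t_start=df["t_start_s"].to_numpy() if "t_start_s" in df else None,
            meta=meta or {},
        )
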