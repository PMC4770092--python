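"""In-memory container for a passive-mode trap trace."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Metadata keys every stored trace must carry.
REQUIRED_META_KEYS = (
    "ligand",
    "concentration",
    "concentration_unit",
    "trap_k1_pN_per_nm",
    "trap_k2_pN_per_nm",
    "trap_separation_nm",
    "sampling_rate_hz",
)


@dataclass
class Trace:
    """Time-stamped bead deflection (or corrected extension) signal.

    Attributes
    ----------
    time : array, s — strictly increasing sample times.
    signal : array, nm — difference/deflection signal, or protein
        extension after the constant-force transform.
    force : array, pN, optional — per-sample tether tension.
    meta : dict — ligand identity, concentration (+unit), trap
        stiffnesses, trap separation, sampling rate, seed, and an
        append-only ``history`` list of processing steps.
    """

    time: np.ndarray
    signal: np.ndarray
    force: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.force is not None:
            self.force = np.asarray(self.force, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if self.force is not None and self.force.shape != self.time.shape:
            raise ValueError("force channel must match time length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            bad = int(np.argmax(np.diff(self.time) <= 0)) + 1
            raise ValueError(f"time must be strictly increasing (violated at sample {bad})")
        self.meta.setdefault("history", [])

    def __len__(self) -> int:
        return self.time.size

    @property
    def sampling_rate(self) -> float:
        if "sampling_rate_hz" in self.meta:
            return float(self.meta["sampling_rate_hz"])
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def history(self) -> list[str]:
        return list(self.meta.get("history", []))

    def history_contains(self, step: str) -> bool:
        return any(h.split("(")[0] == step for h in self.meta.get("history", []))

    def with_signal(self, signal: np.ndarray, history_entry: str | None = None) -> "Trace":
        """Copy with a new signal array and an appended history entry."""
        meta = dict(self.meta)
        meta["history"] = list(self.meta.get("history", []))
        if history_entry is not None:
            meta["history"].append(history_entry)
        force = None if self.force is None else self.force.copy()
        return Trace(time=self.time.copy(), signal=np.asarray(signal, dtype=float),
                     force=force, meta=meta)
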