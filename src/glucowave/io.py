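"""Serialization of beat-signal records and scalogram tensor batches.

Beat records travel as long-format CSV — one row per complex sample with
the header ``antenna_id,sample_index,I,Q,concentration,power_cycle_id`` —
which keeps the on-disk format human-inspectable and diff-friendly.
Tensor batches are stored as a compressed npz with shape/label metadata in
a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from glucowave.simulate import BeatSignal

CSV_COLUMNS = [
    "antenna_id",
    "sample_index",
    "I",
    "Q",
    "concentration",
    "power_cycle_id",
]


def signals_to_frame(signals: list[BeatSignal]) -> pd.DataFrame:
    """Long-format DataFrame of a list of beat records."""
    frames = []
    for rec_id, sig in enumerate(signals):
        n = sig.n_samples
        frames.append(
            pd.DataFrame(
                {
                    "record_id": rec_id,
                    "antenna_id": sig.antenna_id,
                    "sample_index": np.arange(n),
                    "I": sig.samples.real,
                    "Q": sig.samples.imag,
                    "concentration": sig.concentration,
                    "power_cycle_id": sig.power_cycle_id,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_signals_csv(signals: list[BeatSignal], path: str | Path) -> None:
    signals_to_frame(signals).to_csv(path, index=False)


def read_signals_csv(path: str | Path) -> list[BeatSignal]:
    """Read beat records back; strict about the expected columns."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"signal CSV {path} is missing columns {missing}")
    if "record_id" not in df.columns:
        # fall back to grouping by (antenna, concentration, power cycle)
        df = df.assign(
            record_id=(df["sample_index"] == 0).cumsum() - 1
        )
    signals = []
    for _, grp in df.groupby("record_id", sort=True):
        grp = grp.sort_values("sample_index")
        signals.append(
            BeatSignal(
                samples=grp["I"].to_numpy() + 1j * grp["Q"].to_numpy(),
                antenna_id=int(grp["antenna_id"].iloc[0]),
                concentration=float(grp["concentration"].iloc[0]),
                power_cycle_id=int(grp["power_cycle_id"].iloc[0]),
            )
        )
    return signals


def write_tensors(
    path: str | Path,
    tensors: np.ndarray,
    concentrations: np.ndarray,
    scales: np.ndarray | None = None,
) -> None:
    """Store a tensor batch with a JSON sidecar describing it."""
    path = Path(path)
    np.savez_compressed(path, tensors=tensors, concentrations=concentrations)
    sidecar = {
        "shape": list(np.asarray(tensors).shape),
        "concentrations": [float(c) for c in concentrations],
    }
    if scales is not None:
        sidecar["scales"] = [float(s) for s in scales]
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_tensors(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.load(Path(path))
    return data["tensors"], data["concentrations"]
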