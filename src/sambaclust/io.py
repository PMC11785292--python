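"""Plain-text I/O for curves, sequences, matrices and partitions.

Cohort curves travel as delimited text: one row per curve, first column
the subject id, second column the three-symbol string label, remaining
columns the samples; the header row carries the grid times.  Stimulus
sequences are one character per symbol; partitions and configurations
are JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .dissimilarity import TestConfig
from .functional import FunctionalSet, TimeGrid
from .stimulus import StimulusSequence

__all__ = [
    "write_sequence",
    "read_sequence",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_test_config",
    "read_test_config",
]


def write_sequence(seq: StimulusSequence, path) -> None:
    with open(path, "w") as fh:
        fh.write(str(seq) + "\n")


def read_sequence(path) -> StimulusSequence:
    with open(path) as fh:
        return StimulusSequence.from_string(fh.read().strip())


def write_cohort_csv(cohort: dict[str, dict[str, FunctionalSet]], path) -> None:
    """Write a cohort (subject -> string -> FunctionalSet) to one CSV."""
    frames = []
    for sid in sorted(cohort):
        for label in sorted(cohort[sid]):
            fs = cohort[sid][label]
            df = pd.DataFrame(fs.values, columns=[f"{t:.6f}" for t in fs.grid.times])
            df.insert(0, "label", label)
            df.insert(0, "subject", sid)
            frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_cohort_csv(path) -> dict[str, dict[str, FunctionalSet]]:
    df = pd.read_csv(path, dtype={"subject": str, "label": str})
    times = np.array([float(c) for c in df.columns[2:]])
    n = times.size
    grid = TimeGrid(t0=float(times[0]), t1=float(times[-1]), n_points=n)
    if not np.allclose(np.diff(times), grid.dt, atol=1e-9):
        raise ValueError("grid times in header are not uniformly spaced")
    cohort: dict[str, dict[str, FunctionalSet]] = {}
    for (sid, label), grp in df.groupby(["subject", "label"], sort=True):
        vals = grp.iloc[:, 2:].to_numpy(dtype=float)
        cohort.setdefault(sid, {})[label] = FunctionalSet(
            grid, vals, label=label, subject=sid
        )
    return cohort


def write_test_config(cfg: TestConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(cfg), fh, indent=1)


def read_test_config(path) -> TestConfig:
    with open(path) as fh:
        return TestConfig(**json.load(fh))
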