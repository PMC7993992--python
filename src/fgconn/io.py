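"""Array-container and table I/O.

Per-subject time series live in an HDF5 container with datasets
``/timeseries`` (vertices × timepoints) and ``/run_boundaries`` and a
``subject_id`` attribute; per-region transforms are stored under
``/transforms/region_<id>``. Cohort-level tables (subject, family, trait and
test scores) are TSV; configs are echoed as JSON with the resolved seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cohort import CohortConfig, FamilyStructure, SubjectTimeSeries, TraitScores
from .hyperalign import Transform

__all__ = [
    "save_subject",
    "load_subject",
    "save_transforms",
    "load_transforms",
    "save_cohort_table",
    "load_cohort_table",
    "save_config_echo",
]


def save_subject(
    path: str | Path,
    ts: SubjectTimeSeries,
    subject_id: int,
    transforms: dict[int, Transform] | None = None,
) -> None:
    """Write one subject's container (optionally with per-region transforms)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("timeseries", data=ts.values)
        f.create_dataset("run_boundaries", data=np.asarray(ts.run_boundaries))
        f.attrs["subject_id"] = subject_id
        if transforms:
            grp = f.create_group("transforms")
            for region_id, t in transforms.items():
                grp.create_dataset(f"region_{region_id}", data=t.matrix)


def load_subject(path: str | Path) -> tuple[SubjectTimeSeries, int]:
    with h5py.File(path, "r") as f:
        ts = SubjectTimeSeries(
            values=f["timeseries"][()],
            run_boundaries=tuple(int(b) for b in f["run_boundaries"][()]),
        )
        return ts, int(f.attrs["subject_id"])


def save_transforms(
    path: str | Path, transforms: dict[tuple[int, int], Transform]
) -> None:
    with h5py.File(path, "w") as f:
        for (subject_id, region_id), t in transforms.items():
            f.create_dataset(f"subject_{subject_id}/region_{region_id}",
                             data=t.matrix)


def load_transforms(path: str | Path) -> dict[tuple[int, int], Transform]:
    out: dict[tuple[int, int], Transform] = {}
    with h5py.File(path, "r") as f:
        for skey in f:
            sid = int(skey.split("_")[1])
            for rkey in f[skey]:
                rid = int(rkey.split("_")[1])
                out[(sid, rid)] = Transform(
                    matrix=f[skey][rkey][()], subject_id=sid, region_id=rid
                )
    return out


def save_cohort_table(
    path: str | Path, traits: TraitScores, families: FamilyStructure
) -> None:
    traits.to_frame(families).to_csv(path, sep="\t", index=False)


def load_cohort_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_config_echo(path: str | Path, config: CohortConfig, **extra) -> None:
    """JSON echo of a cohort config (with the resolved seed) plus extras."""
    payload = dataclasses.asdict(config)
    payload["family_histogram"] = {
        str(k): int(v) for k, v in config.family_histogram.items()
    }
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
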