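"""Plain-text interchange: TSV matrices, JSON designs and manifests.

Conventions
-----------
* ROI time series: tab-delimited, one row per volume, header = ROI labels;
  TR carried in a ``# tr=<seconds>`` comment on the first line.
* Connectomes: square tab-delimited matrices with ROI labels as header and
  index column.
* Task designs: JSON ``{tr, n_time, conditions: [{label, trials:
  [[onset, duration], ...]}]}``.
* ROI→network partitions: two-column TSV (roi_label, network_label).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import RoiTimeSeries, StructuralConnectome, TaskDesign
from .exceptions import ValidationError

_TR_PREFIX = "# tr="


def write_timeseries(data: RoiTimeSeries, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_TR_PREFIX}{data.tr!r}\n")
        fh.write("\t".join(data.roi_labels) + "\n")
        np.savetxt(fh, data.values, delimiter="\t", fmt="%.10g")


def read_timeseries(path: str | Path) -> RoiTimeSeries:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith(_TR_PREFIX):
            raise ValidationError(
                f"{path}: expected leading '{_TR_PREFIX}<seconds>' comment")
        tr = float(first[len(_TR_PREFIX):])
        labels = fh.readline().strip().split("\t")
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return RoiTimeSeries(values=values, tr=tr, roi_labels=labels)


def write_connectome(connectome: StructuralConnectome, path: str | Path) -> None:
    df = pd.DataFrame(connectome.weights, index=connectome.roi_labels,
                      columns=connectome.roi_labels)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_connectome(path: str | Path) -> StructuralConnectome:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column labels differ")
    return StructuralConnectome(weights=df.to_numpy(dtype=float),
                                roi_labels=[str(c) for c in df.columns])


def write_task_design(design: TaskDesign, path: str | Path) -> None:
    Path(path).write_text(json.dumps(design.to_dict(), indent=2) + "\n")


def read_task_design(path: str | Path) -> TaskDesign:
    return TaskDesign.from_dict(json.loads(Path(path).read_text()))


def write_partition(partition: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("roi_label\tnetwork_label\n")
        for roi, net in partition.items():
            fh.write(f"{roi}\t{net}\n")


def read_partition(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["roi_label", "network_label"]:
        raise ValidationError(
            f"{path}: expected columns roi_label, network_label")
    return dict(zip(df["roi_label"], df["network_label"]))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_matrix_tsv(matrix: np.ndarray, path: str | Path,
                     columns: Sequence[str] | None = None) -> None:
    """Generic labelled matrix writer (e.g. null statistics, sign vectors)."""
    df = pd.DataFrame(np.asarray(matrix), columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
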