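"""Reading and writing recordings and cohort manifests.

The canonical on-disk format is a wide CSV (``time,ch01,...,chNN``): it is
inspectable and diff-able, which matters for small human cohorts.  SNIRF
(the community HDF5 interchange format for fNIRS) is supported read-only
for processed-hemoglobin continuous-wave files.

Channel ids are 1-based, matching the NIRSIT Lite montage numbering used
throughout the analysis ("channel 1", "channel 15"); array columns are
0-based with an explicit id <-> column mapping on :class:`Recording`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

GROUPS = ("pianist", "non_pianist")
TASKS = ("score", "improv")

#: HbO/HbR concentration data carries SNIRF dataType 99999 ("processed").
_SNIRF_LABELS = {"HbO", "HbR"}


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


class ManifestError(ValueError):
    """A cohort manifest is malformed or inconsistent."""


class UnsupportedContentError(ValueError):
    """A file is well-formed but lacks the requested content."""


@dataclass
class Recording:
    """One subject x task multichannel hemodynamic time series.

    ``data`` has shape (time, channel); values are hemoglobin concentration
    change in arbitrary concentration units.  ``channel_ids`` gives the
    1-based montage id of each data column, in column order.
    """

    subject_id: str
    group: str
    task: str
    rate_hz: float
    data: np.ndarray
    channel_ids: Sequence[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (time x channel), got {self.data.ndim}-D")
        if self.channel_ids is None:
            self.channel_ids = list(range(1, self.data.shape[1] + 1))
        else:
            self.channel_ids = [int(c) for c in self.channel_ids]
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if len(self.channel_ids) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {self.data.shape[1]} data columns"
            )
        if self.group not in GROUPS:
            raise ManifestError(f"unknown group {self.group!r}; allowed: {GROUPS}")
        if self.task not in TASKS:
            raise ManifestError(f"unknown task {self.task!r}; allowed: {TASKS}")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.data.size and not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise FormatError(
                f"non-finite value at sample {bad[0]}, channel {self.channel_ids[bad[1]]}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def channel_index(self, channel_id: int) -> int:
        """Column index of a 1-based montage channel id."""
        try:
            return self.channel_ids.index(int(channel_id))
        except ValueError:
            raise KeyError(f"channel {channel_id} not in montage {self.channel_ids}") from None

    def with_data(self, data: np.ndarray, rate_hz: float | None = None) -> "Recording":
        return replace(self, data=data, rate_hz=self.rate_hz if rate_hz is None else rate_hz)


@dataclass
class CohortManifest:
    """Validated (subject_id, group, task, file, seed) table for a cohort."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "task"}
        missing = required - set(self.table.columns)
        if missing:
            raise ManifestError(f"manifest missing columns: {sorted(missing)}")
        bad_group = set(self.table["group"]) - set(GROUPS)
        if bad_group:
            raise ManifestError(
                f"unknown group value(s) {sorted(bad_group)}; allowed values: {list(GROUPS)}"
            )
        bad_task = set(self.table["task"]) - set(TASKS)
        if bad_task:
            raise ManifestError(
                f"unknown task value(s) {sorted(bad_task)}; allowed values: {list(TASKS)}"
            )
        dup = self.table.duplicated(subset=["subject_id", "task"])
        if dup.any():
            row = self.table[dup].iloc[0]
            raise ManifestError(
                f"duplicate (subject, task) entry: ({row['subject_id']}, {row['task']})"
            )

    def __len__(self) -> int:
        return len(self.table)

    def group_of(self, subject_id: str) -> str:
        rows = self.table[self.table["subject_id"] == subject_id]
        if rows.empty:
            raise KeyError(subject_id)
        return str(rows["group"].iloc[0])

    def subjects(self, group: str | None = None) -> list[str]:
        t = self.table if group is None else self.table[self.table["group"] == group]
        return list(dict.fromkeys(t["subject_id"]))


_HEADER_RE = re.compile(r"^ch(\d+)$")


def write_wide_csv(recording: Recording, path: str | Path) -> Path:
    """Write a recording as ``time,ch01,...,chNN`` with >=9 significant digits.

    Time starts at 0 with step 1/rate_hz; serialization is canonical, so
    rewriting a loaded file reproduces the header byte-for-byte.
    """
    path = Path(path)
    header = "time," + ",".join(f"ch{c:02d}" for c in recording.channel_ids)
    t = np.arange(recording.n_samples) / recording.rate_hz
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i in range(recording.n_samples):
            row = [f"{t[i]:.12g}"] + [f"{v:.12g}" for v in recording.data[i]]
            fh.write(",".join(row) + "\n")
    return path


def read_wide_csv(
    path: str | Path,
    subject_id: str = "unknown",
    group: str = "pianist",
    task: str = "score",
    rate_hz: float | None = None,
) -> Recording:
    """Read a wide-CSV recording; metadata comes from the arguments.

    The time column must be uniformly spaced (relative tolerance 1e-6);
    rate is inferred from the spacing when not given.  Any malformed cell
    is an error naming the first offending data row — never a silent fill.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc
    cols = list(frame.columns)
    if not cols or cols[0] != "time":
        raise FormatError(f"{path.name}: first column must be 'time', got {cols[:1]}")
    channel_ids = []
    for c in cols[1:]:
        m = _HEADER_RE.match(c)
        if not m:
            raise FormatError(f"{path.name}: bad channel column name {c!r}")
        channel_ids.append(int(m.group(1)))
    values = frame.to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise FormatError(f"{path.name}: non-finite value in row {r + 1}, column {cols[c]}")
    tcol = values[:, 0]
    if len(tcol) >= 3:
        steps = np.diff(tcol)
        step = steps.mean()
        if step <= 0 or np.any(np.abs(steps - step) > 1e-6 * max(abs(step), 1e-30)):
            first_bad = int(np.argmax(np.abs(steps - step) > 1e-6 * abs(step))) + 2
            raise FormatError(f"{path.name}: non-uniform time spacing at row {first_bad}")
        inferred = 1.0 / step
    elif len(tcol) == 2:
        inferred = 1.0 / (tcol[1] - tcol[0])
    else:
        inferred = rate_hz or 1.0
    return Recording(
        subject_id=subject_id,
        group=group,
        task=task,
        rate_hz=float(rate_hz if rate_hz is not None else inferred),
        data=values[:, 1:],
        channel_ids=channel_ids,
    )


def read_snirf_hbo(path: str | Path, chromophore: str = "HbO") -> Recording:
    """Read one chromophore's time series from a processed-hemoglobin SNIRF file.

    Only continuous-wave processed concentration data is supported; channels
    are mapped, in file order, to montage ids 1..n (n <= 15).
    """
    if chromophore not in _SNIRF_LABELS:
        raise ValueError(f"chromophore must be one of {sorted(_SNIRF_LABELS)}")
    path = Path(path)
    with h5py.File(path, "r") as fh:
        try:
            data_group = fh["/nirs/data1"]
            series = np.asarray(data_group["dataTimeSeries"], dtype=float)
            time = np.asarray(data_group["time"], dtype=float).ravel()
        except KeyError as exc:
            raise FormatError(f"{path.name}: not a SNIRF data file ({exc})") from exc
        labels = []
        for i in range(series.shape[1]):
            ml = data_group.get(f"measurementList{i + 1}")
            if ml is None:
                raise FormatError(f"{path.name}: missing measurementList{i + 1}")
            raw = ml["dataTypeLabel"][()]
            labels.append(raw.decode() if isinstance(raw, bytes) else str(raw))
        keep = [i for i, lab in enumerate(labels) if lab == chromophore]
        if not keep:
            raise UnsupportedContentError(
                f"{path.name}: no {chromophore} measurements (found {sorted(set(labels))})"
            )
        if len(keep) > 15:
            raise FormatError(
                f"{path.name}: {len(keep)} {chromophore} channels exceed the supported 15-channel montage"
            )
        if len(time) >= 2:
            rate = 1.0 / float(np.mean(np.diff(time)))
        else:
            rate = 1.0
    return Recording(
        subject_id=path.stem,
        group="pianist",
        task="score",
        rate_hz=rate,
        data=series[:, keep],
        channel_ids=list(range(1, len(keep) + 1)),
    )


def load_manifest(path: str | Path, check_files: bool = True) -> CohortManifest:
    """Load and validate a cohort manifest CSV."""
    path = Path(path)
    table = pd.read_csv(path, dtype={"subject_id": str})
    manifest = CohortManifest(table)
    if check_files and "file" in table.columns:
        for _, row in table.iterrows():
            f = row["file"]
            if isinstance(f, str) and f:
                candidate = Path(f)
                if not candidate.is_absolute():
                    candidate = path.parent / candidate
                if not candidate.exists():
                    raise ManifestError(f"manifest references missing file: {f}")
    return manifest


def save_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    manifest.table.to_csv(path, index=False)
    return path
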