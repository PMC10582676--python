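"""Reading, validation and preparation of camera-trap tables.

Two input tables drive a camera-trap distance sampling (CTDS) analysis:

``detections.csv``
    one row per snapshot observation — ``camera_id, species, timestamp,
    distance_m, group_size`` (group_size optional, default 1).
``deployments.csv``
    one row per camera — ``camera_id, theta_fov_deg, start, end, stratum``.

This module validates both, derives each camera's operational time
(trimmed by one hour at either end of the deployment to let animals
habituate and to exclude servicing disturbance), truncates and bins
radial distances for detection-function fitting, and applies the
30-minute temporal independence filter used for activity-time data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DETECTION_COLUMNS = ("camera_id", "species", "timestamp", "distance_m")
DEPLOYMENT_COLUMNS = ("camera_id", "theta_fov_deg", "start", "end", "stratum")

#: seconds trimmed from a deployment (1 h after set-up + 1 h before retrieval)
EFFORT_TRIM_S = 7200.0


class SchemaError(ValueError):
    """An input table is missing a required column or has an invalid value."""


class ReferentialError(ValueError):
    """A detection refers to a camera_id absent from the deployment table."""


@dataclass
class IngestReport:
    """Row-level outcome of reading a detection table."""

    n_read: int = 0
    n_kept: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def compute_operational_time(start, end) -> float:
    """Operational seconds of a deployment: max(0, (end - start) - 2 h).

    One hour after set-up and one hour before retrieval are excluded
    from effort.  Raises :class:`SchemaError` if ``end <= start``.
    """
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    if end <= start:
        raise SchemaError(f"deployment end {end} is not after start {start}")
    return max(0.0, (end - start).total_seconds() - EFFORT_TRIM_S)


def read_deployments(path) -> pd.DataFrame:
    """Read and validate a deployment table.

    Returns a DataFrame indexed by ``camera_id`` with parsed timestamps,
    ``theta_fov`` in radians and operational time ``T_k`` in seconds.
    """
    df = pd.read_csv(path)
    missing = [c for c in DEPLOYMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"deployment table missing column(s): {missing}")
    if df["camera_id"].duplicated().any():
        dupes = df.loc[df["camera_id"].duplicated(), "camera_id"].tolist()
        raise SchemaError(f"duplicate camera_id(s) in deployments: {dupes}")
    df = df.copy()
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    theta = np.deg2rad(df["theta_fov_deg"].astype(float))
    if ((theta <= 0) | (theta > 2 * np.pi)).any():
        raise SchemaError("theta_fov_deg must lie in (0, 360]")
    df["theta_fov"] = theta
    df["T_k"] = [
        compute_operational_time(s, e) for s, e in zip(df["start"], df["end"])
    ]
    return df.set_index("camera_id")


def read_detections(path, deployments: pd.DataFrame | None = None):
    """Read a detection table, validating row by row.

    Rows with a missing/negative distance, unparseable timestamp, or
    non-positive group size are rejected and listed in the returned
    :class:`IngestReport`; a timestamp outside its camera's deployment
    window is likewise rejected when ``deployments`` is given.  A
    ``camera_id`` absent from ``deployments`` altogether raises
    :class:`ReferentialError` (that is a join error, not a bad row).

    Returns ``(detections, report)`` where ``detections`` is a DataFrame
    with parsed timestamps and a ``group_size`` column defaulting to 1.
    """
    df = pd.read_csv(path)
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"detection table missing column(s): {missing}")
    df = df.copy()
    if "group_size" not in df.columns:
        df["group_size"] = 1

    if deployments is not None:
        unknown = set(df["camera_id"]) - set(deployments.index)
        if unknown:
            raise ReferentialError(
                f"camera_id(s) absent from deployment table: {sorted(unknown)}"
            )

    report = IngestReport(n_read=len(df))
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    dist = pd.to_numeric(df["distance_m"], errors="coerce")
    gs = pd.to_numeric(df["group_size"], errors="coerce")

    bad = {}
    for i in df.index[ts.isna()]:
        bad[i] = "unparseable timestamp"
    for i in df.index[dist.isna()]:
        bad.setdefault(i, "missing or non-numeric distance_m")
    for i in df.index[dist < 0]:
        bad.setdefault(i, "negative distance_m")
    for i in df.index[gs.isna() | (gs < 1)]:
        bad.setdefault(i, "group_size < 1 or non-numeric")
    if deployments is not None:
        dep_start = deployments["start"].reindex(df["camera_id"]).to_numpy()
        dep_end = deployments["end"].reindex(df["camera_id"]).to_numpy()
        outside = (ts.to_numpy() < dep_start) | (ts.to_numpy() > dep_end)
        for i in df.index[np.asarray(outside) & ts.notna().to_numpy()]:
            bad.setdefault(i, "timestamp outside deployment window")

    keep = df.index.difference(list(bad))
    out = df.loc[keep].copy()
    out["timestamp"] = ts.loc[keep]
    out["distance_m"] = dist.loc[keep]
    out["group_size"] = gs.loc[keep].astype(int)
    report.rejected = sorted(bad.items())
    report.n_kept = len(out)
    return out.reset_index(drop=True), report


@dataclass(frozen=True)
class BinningScheme:
    """Distance bins for a binned point-transect analysis.

    ``cutpoints`` are strictly increasing distances in metres; the first
    cutpoint is the left-truncation distance and the last the
    right-truncation distance ``w``.  Bins are half-open ``[c_{j-1}, c_j)``
    and observations outside ``[left, w)`` are discarded.
    """

    cutpoints: tuple[float, ...]

    def __post_init__(self):
        cp = tuple(float(c) for c in self.cutpoints)
        if len(cp) < 2:
            raise ValueError("need at least two cutpoints (one bin)")
        if any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError("cutpoints must be strictly increasing")
        if cp[0] < 0:
            raise ValueError("left truncation must be >= 0")
        object.__setattr__(self, "cutpoints", cp)

    @classmethod
    def regular(cls, width: float = 1.0, left: float = 0.0, right: float = 10.0):
        """Equal-width bins, e.g. the study's 1-m intervals on [0, 10)."""
        n = int(round((right - left) / width))
        edges = left + width * np.arange(n + 1)
        edges[-1] = right
        return cls(tuple(edges))

    @property
    def left_truncation(self) -> float:
        return self.cutpoints[0]

    @property
    def w(self) -> float:
        """Right-truncation distance (metres)."""
        return self.cutpoints[-1]

    @property
    def n_bins(self) -> int:
        return len(self.cutpoints) - 1

    def bin_index(self, distances) -> np.ndarray:
        """Half-open bin index per distance; -1 where outside [left, w)."""
        d = np.asarray(distances, dtype=float)
        idx = np.digitize(d, self.cutpoints, right=False) - 1
        idx[(d < self.left_truncation) | (d >= self.w)] = -1
        return idx


@dataclass
class BinnedCounts:
    """Per-camera binned distance counts after truncation.

    ``counts`` is a DataFrame (rows: camera_id, columns: bin index).
    """

    scheme: BinningScheme
    counts: pd.DataFrame
    n_discarded_left: int = 0
    n_discarded_right: int = 0

    @property
    def pooled(self) -> np.ndarray:
        """Counts pooled over cameras (the multinomial data for fitting)."""
        return self.counts.to_numpy().sum(axis=0)

    @property
    def n_by_camera(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def n_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def subset(self, camera_ids) -> "BinnedCounts":
        sub = self.counts.loc[self.counts.index.intersection(camera_ids)]
        return BinnedCounts(self.scheme, sub)


def truncate_and_bin(
    detections: pd.DataFrame,
    scheme: BinningScheme,
    camera_ids=None,
) -> BinnedCounts:
    """Truncate distances to [left, w) and count them into bins per camera.

    ``camera_ids`` optionally fixes the camera universe (so cameras with
    zero detections still appear with zero counts — they contribute
    effort and must enter the encounter-rate variance).
    """
    idx = scheme.bin_index(detections["distance_m"].to_numpy())
    kept = idx >= 0
    d = detections["distance_m"].to_numpy()
    n_left = int(np.sum(d < scheme.left_truncation))
    n_right = int(np.sum(d >= scheme.w))

    cams = (
        pd.Index(camera_ids, name="camera_id")
        if camera_ids is not None
        else pd.Index(sorted(detections["camera_id"].unique()), name="camera_id")
    )
    table = pd.DataFrame(
        0, index=cams, columns=pd.RangeIndex(scheme.n_bins), dtype=int
    )
    sub = pd.DataFrame(
        {"camera_id": detections["camera_id"].to_numpy()[kept], "bin": idx[kept]}
    )
    for (cam, b), cnt in sub.groupby(["camera_id", "bin"]).size().items():
        if cam in table.index:
            table.loc[cam, b] += int(cnt)
    return BinnedCounts(scheme, table, n_left, n_right)


def independence_filter(
    detections: pd.DataFrame, window_minutes: float = 30.0
) -> pd.DataFrame:
    """Thin events to temporal independence within each (camera, species).

    An event is retained iff at least ``window_minutes`` have elapsed
    since the last *retained* event at the same camera for the same
    species.  Used only to build the activity-time sample; distance data
    for detection-function fitting are never filtered this way.
    """
    window = pd.Timedelta(minutes=window_minutes)
    keep_rows = []
    df = detections.sort_values("timestamp", kind="mergesort")
    for _, grp in df.groupby(["camera_id", "species"], sort=False):
        last = None
        for row_idx, ts in zip(grp.index, grp["timestamp"]):
            if last is None or ts - last >= window:
                keep_rows.append(row_idx)
                last = ts
    return detections.loc[sorted(keep_rows)]
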