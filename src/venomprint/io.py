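"""Readers and writers for every on-disk artifact.

All formats are plain text with a single documented dialect:

* trace CSV — two numeric columns ``time_s, fluorescence_FU``; lines
  starting ``#`` carry ``key=value`` metadata;
* manifest CSV — ``sample_id, individual_id, replicate_id, group,
  trace_path``;
* ladder CSV — ``time_s, kda``;
* binary matrix TSV — first column individual ids, header of marker
  labels, cells strictly 0/1;
* bin set TSV — ``label, center_s, lo_s, hi_s, half_width_s, sd_s,
  support``;
* QC report JSON.

Readers and writers are mutually inverse on valid artifacts and never
reorder rows or columns. Vendor binary exports (.xad) are out of scope; a
converter hook upstream of :func:`read_trace` is the supported path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import BinSet, MarkerBin
from .exceptions import (
    CalibrationError,
    DegenerateTraceError,
    ManifestError,
    MatrixFormatError,
    TraceFormatError,
)
from .matrix import BinaryMatrix
from .qc import QCReport
from .trace import LadderTable, Trace

MIN_TRACE_ROWS = 10


@dataclass(frozen=True)
class SampleManifestEntry:
    """One row of the sample manifest."""

    sample_id: str
    individual_id: str
    replicate_id: int
    group: str
    trace_path: str


# ---------------------------------------------------------------------------
# traces


def read_trace(path: str | Path, sample_id: str | None = None) -> Trace:
    """Read a trace CSV (see module docstring for the dialect).

    Raises :class:`TraceFormatError` for a non-monotone time column and
    :class:`DegenerateTraceError` for traces shorter than 10 rows.
    """
    path = Path(path)
    metadata: dict[str, str] = {}
    times: list[float] = []
    fluor: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    metadata[key.strip()] = value.strip()
                continue
            parts = line.split(",")
            if parts[0].replace("_", "").isalpha():
                continue  # header row
            try:
                t, f = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise TraceFormatError(f"{path}:{lineno}: not two numeric columns") from exc
            times.append(t)
            fluor.append(f)
    if len(times) < MIN_TRACE_ROWS:
        raise DegenerateTraceError(f"{path}: only {len(times)} rows (< {MIN_TRACE_ROWS})")
    t_arr = np.array(times)
    if not np.all(np.diff(t_arr) > 0):
        raise TraceFormatError(f"{path}: time column is not strictly increasing")
    sid = sample_id or metadata.get("sample_id", path.stem)
    return Trace(sample_id=sid, times=t_arr, fluorescence=np.array(fluor), metadata=metadata)


def write_trace(trace: Trace, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sample_id={trace.sample_id}\n")
        for key, value in trace.metadata.items():
            if key == "sample_id":
                continue
            fh.write(f"# {key}={value}\n")
        fh.write("time_s,fluorescence_FU\n")
        for t, f in zip(trace.times, trace.fluorescence):
            fh.write(f"{float(t)!r},{float(f)!r}\n")


# ---------------------------------------------------------------------------
# manifest


def read_manifest(path: str | Path) -> list[SampleManifestEntry]:
    """Read and validate the sample manifest.

    Enforced invariants: unique sample ids; every individual has >= 1
    replicate with replicate ids consecutive from 1.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "individual_id": str, "group": str})
    required = {"sample_id", "individual_id", "replicate_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    if "trace_path" not in df.columns:
        df["trace_path"] = ""
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ManifestError(f"duplicate sample_id {dup!r}")
    for individual, group in df.groupby("individual_id", sort=False):
        reps = sorted(int(r) for r in group["replicate_id"])
        if reps != list(range(1, len(reps) + 1)):
            raise ManifestError(
                f"individual {individual!r}: replicate ids {reps} not consecutive from 1"
            )
    return [
        SampleManifestEntry(
            sample_id=row.sample_id,
            individual_id=row.individual_id,
            replicate_id=int(row.replicate_id),
            group=row.group,
            trace_path=str(row.trace_path),
        )
        for row in df.itertuples()
    ]


def write_manifest(entries: list[SampleManifestEntry], path: str | Path) -> None:
    pd.DataFrame([e.__dict__ for e in entries]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ladder


def read_ladder(path: str | Path) -> LadderTable:
    df = pd.read_csv(path)
    if not {"time_s", "kda"} <= set(df.columns):
        raise CalibrationError(f"{path}: ladder needs columns time_s, kda")
    return LadderTable(points=tuple(zip(df["time_s"], df["kda"])))


def write_ladder(ladder: LadderTable, path: str | Path) -> None:
    pd.DataFrame(ladder.points, columns=["time_s", "kda"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# binary matrix


def read_matrix(path: str | Path) -> BinaryMatrix:
    """Read a binary matrix TSV; any cell outside {0, 1} is a format error."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    bad = ~df.isin([0, 1])
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise MatrixFormatError(
            f"{path}: cell ({df.index[r]}, {df.columns[c]}) = {df.iat[r, c]!r} not in {{0,1}}"
        )
    return BinaryMatrix(data=df)


def write_matrix(matrix: BinaryMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = df.index.name or "individual_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# bin sets


def read_binset(path: str | Path) -> BinSet:
    df = pd.read_csv(path, sep="\t")
    bins = tuple(
        MarkerBin(
            label=str(r.label),
            center=float(r.center_s),
            lo=float(r.lo_s),
            hi=float(r.hi_s),
            sd=float(r.sd_s),
            support=int(r.support),
        )
        for r in df.itertuples()
    )
    return BinSet(bins=bins)


def write_binset(bins: BinSet, path: str | Path) -> None:
    pd.DataFrame(
        [
            dict(
                label=b.label,
                center_s=b.center,
                lo_s=b.lo,
                hi_s=b.hi,
                half_width_s=b.half_width,
                sd_s=b.sd,
                support=b.support,
            )
            for b in bins
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC report


def write_qc_report(report: QCReport, path: str | Path) -> None:
    Path(path).write_text(report.to_json() + "\n")


def read_qc_report(path: str | Path) -> QCReport:
    return QCReport.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# analysis results


def write_distance_matrix(dm, path: str | Path) -> None:
    """Square Bray-Curtis matrix as TSV with ids on both margins."""
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(path, sep="\t")


def write_series(series: pd.Series, path: str | Path, value_name: str) -> None:
    series.rename(value_name).to_csv(path, sep="\t")


def write_frame(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
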