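"""File I/O: CSV sample streams, label sidecars, reports, WFDB records.

The interchange format is deliberately minimal: one numeric sample per line
(optional single header line), with the sampling rate supplied separately.
WFDB reading is optional and only available when the ``wfdb`` package is
installed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .evaluation import ConfusionCounts
from .screening import ScreenResult

__all__ = [
    "read_samples",
    "write_samples",
    "read_labels",
    "write_labels",
    "write_report",
]


def _read_csv_samples(path: Path) -> np.ndarray:
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty input file")
    try:
        float(first.strip().split(",")[0])
        skip = 0
    except ValueError:
        skip = 1  # header line
    try:
        data = np.loadtxt(path, skiprows=skip, ndmin=1)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric sample row ({exc})") from exc
    if data.ndim > 1:
        data = data[:, 0]
    if data.size == 0:
        raise ValueError(f"{path}: no samples")
    return data.astype(float)


def read_samples(
    path, fmt: str = "csv", channel: int = 0
) -> Tuple[np.ndarray, Optional[float]]:
    """Read a sample stream.

    Returns ``(samples, sampling_rate)``; the rate is ``None`` for CSV input
    (it comes from configuration) and is taken from the record header for
    WFDB input, where ``channel`` selects the signal.
    """
    path = Path(path)
    if fmt == "csv":
        return _read_csv_samples(path), None
    if fmt == "wfdb":
        try:
            import wfdb
        except ImportError as exc:
            raise ImportError(
                "WFDB input requires the optional 'wfdb' package "
                "(pip install pulsescreen[wfdb])"
            ) from exc
        record = wfdb.rdrecord(str(path))
        if channel >= record.n_sig:
            raise ValueError(
                f"channel {channel} not present; record has {record.n_sig} signals"
            )
        return record.p_signal[:, channel].astype(float), float(record.fs)
    raise ValueError(f"unknown input format {fmt!r}")


def write_samples(path, samples) -> None:
    np.savetxt(path, np.asarray(samples, dtype=float), fmt="%.8g")


def write_labels(path, labels: Sequence[str]) -> None:
    """Truth/label sidecar: CSV with columns segment_index (1-based), label."""
    pd.DataFrame(
        {"segment_index": np.arange(1, len(labels) + 1), "label": list(labels)}
    ).to_csv(path, index=False)


def read_labels(path) -> Tuple[str, ...]:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: expected a 'label' column")
    if "segment_index" in df.columns:
        df = df.sort_values("segment_index")
    return tuple(str(v) for v in df["label"])


def write_report(
    path,
    result: ScreenResult,
    counts: Optional[ConfusionCounts] = None,
) -> None:
    """Write the screening report as JSON.

    Segment numbers are 1-based in the report.  Includes the adaptive
    thresholds and per-group statistics so a run can be audited end to end.
    """
    calls = result.calls
    report = {
        "sampling_rate": result.segments.sampling_rate,
        "segment_seconds": result.segments.segment_seconds,
        "n_segments": result.segments.m,
        "samples_per_segment": result.segments.n,
        "coefficient_method": result.thresholds.method,
        "spike_coefficient": result.thresholds.spike_coefficient,
        "groups": None,
        "spike_segments": sorted(i + 1 for i in calls.spike_segments),
        "poor_contact_segments": sorted(i + 1 for i in calls.poor_contact_segments),
        "removed_segments": sorted(i + 1 for i in calls.removed),
        "retained_count": result.clean.m,
        "segment_labels": calls.labels(),
    }
    if result.groups is not None:
        report["groups"] = [
            {
                "group": g + 1,
                "members": int(result.groups.member_counts[g]),
                "mean_of_stds": float(result.groups.mean_of_stds[g]),
                "std_of_stds": float(result.groups.std_of_stds[g]),
                "coefficient": float(result.thresholds.poor_contact_coefficients[g]),
                "threshold": float(result.thresholds.poor_contact_thresholds[g]),
            }
            for g in range(result.groups.group_count)
        ]
    if counts is not None:
        report["confusion"] = {
            "tp": counts.tp,
            "tn": counts.tn,
            "fp": counts.fp,
            "fn": counts.fn,
        }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
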