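"""The TraceSet container and tidy-CSV I/O.

A :class:`TraceSet` is the unit every pipeline stage consumes: time x
community matrices of the dEGFP reporter and the constitutive mCherry
growth marker, on a uniform sampling grid, with provenance metadata.  It is
the post-ROI representation of a microfluidics recording (image analysis
happens upstream) and is serialized as a tidy CSV with columns
``time_min, community, channel, value``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd

__all__ = ["TraceSet", "TraceError", "read_traces", "write_traces"]

CHANNELS = ("dEGFP", "mCherry")
REQUIRED_COLUMNS = ("time_min", "community", "channel", "value")


class TraceError(ValueError):
    """Invalid trace data."""


@dataclass
class TraceSet:
    time_min: np.ndarray
    degfp: np.ndarray  # (n_times, n_communities)
    mcherry: np.ndarray
    community_ids: List[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.degfp = np.atleast_2d(np.asarray(self.degfp, dtype=float))
        self.mcherry = np.atleast_2d(np.asarray(self.mcherry, dtype=float))
        self.community_ids = [str(c) for c in self.community_ids]
        nt, nc = len(self.time_min), len(self.community_ids)
        if self.degfp.shape != (nt, nc) or self.mcherry.shape != (nt, nc):
            raise TraceError(
                f"matrix shapes {self.degfp.shape}/{self.mcherry.shape} do not "
                f"match {nt} times x {nc} communities"
            )
        if nt < 2:
            raise TraceError("need at least two time points")
        dt = np.diff(self.time_min)
        if np.any(dt <= 0):
            raise TraceError("time must be strictly increasing")
        if np.any(self.degfp < 0) or np.any(self.mcherry < 0):
            raise TraceError("fluorescence values must be non-negative")

    @property
    def n_times(self) -> int:
        return len(self.time_min)

    @property
    def n_communities(self) -> int:
        return len(self.community_ids)

    @property
    def dt_min(self) -> float:
        return float(self.time_min[1] - self.time_min[0])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, mat in (("dEGFP", self.degfp), ("mCherry", self.mcherry)):
            df = pd.DataFrame(mat, columns=self.community_ids)
            df["time_min"] = self.time_min
            long = df.melt(id_vars="time_min", var_name="community", value_name="value")
            long["channel"] = name
            rows.append(long)
        out = pd.concat(rows, ignore_index=True)
        return out[["time_min", "community", "channel", "value"]]


def write_traces(traceset: TraceSet, path) -> None:
    """Write a TraceSet as tidy CSV (UTF-8, header row, '.' decimals).

    A JSON sidecar line of metadata is embedded as '#'-prefixed header
    comment so a round trip preserves provenance.
    """
    df = traceset.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if traceset.meta:
            fh.write("# meta: " + json.dumps(traceset.meta, sort_keys=True) + "\n")
        df.to_csv(fh, index=False)


def read_traces(path) -> TraceSet:
    """Read and validate a tidy trace CSV into a TraceSet.

    Enforces a uniform time grid and the presence of both channels for every
    community; each violation raises :class:`TraceError` with a distinct
    diagnostic.
    """
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# meta:"):
            meta = json.loads(first[len("# meta:"):])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TraceError(f"missing required column(s): {', '.join(missing)}")
    if df["value"].lt(0).any():
        bad = int(df.index[df["value"] < 0][0])
        raise TraceError(f"negative fluorescence value at row {bad}")
    times = np.sort(df["time_min"].unique())
    if len(times) < 2:
        raise TraceError("need at least two time points")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-6 * dt[0]):
        bad = int(np.argmax(~np.isclose(dt, dt[0], rtol=0, atol=1e-6 * dt[0]))) + 1
        raise TraceError(
            f"non-uniform time grid: spacing changes at time index {bad} "
            f"(t={times[bad]} min)"
        )
    communities = list(df["community"].astype(str).unique())
    nt = len(times)
    mats = {}
    for channel in CHANNELS:
        sub = df[df["channel"] == channel]
        mat = np.full((nt, len(communities)), np.nan)
        for j, comm in enumerate(communities):
            s = sub[sub["community"].astype(str) == comm]
            if len(s) == 0:
                raise TraceError(f"channel {channel} missing for community {comm}")
            if len(s) != nt:
                raise TraceError(
                    f"community {comm} channel {channel} has {len(s)} samples, "
                    f"expected {nt} (ragged grid)"
                )
            order = np.argsort(s["time_min"].to_numpy())
            mat[:, j] = s["value"].to_numpy()[order]
        mats[channel] = mat
    return TraceSet(
        time_min=times,
        degfp=mats["dEGFP"],
        mcherry=mats["mCherry"],
        community_ids=communities,
        meta=meta,
    )
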