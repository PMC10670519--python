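"""Delimited-text readers and writers for recordings, markers and tables.

A recording is stored as a wide TSV of samples x channels (header = channel
labels) together with a marker sidecar (onset_s, duration_s, scene, region,
subject) and a small JSON manifest holding the sampling rate and montage.
Feature tables and questionnaires are plain CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Marker, Recording


def write_recording(rec: Recording, stem: str | Path) -> None:
    """Write ``<stem>.tsv`` (data), ``<stem>.markers.tsv``, ``<stem>.json``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rec.data.T, columns=list(rec.channel_labels)).to_csv(
        stem.with_suffix(".tsv"), sep="\t", index=False,
        float_format="%.4f")
    pd.DataFrame(
        [{"onset_s": m.onset, "duration_s": m.duration, "scene": m.scene,
          "region": m.region, "subject": m.subject} for m in rec.markers]
    ).to_csv(stem.with_suffix(".markers.tsv"), sep="\t", index=False)
    manifest = {
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "reference_labels": list(rec.reference_labels),
        "montage": {k: list(v) for k, v in rec.montage.items()},
    }
    stem.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def read_recording(stem: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    stem = Path(stem)
    manifest = json.loads(stem.with_suffix(".json").read_text())
    data = pd.read_csv(stem.with_suffix(".tsv"), sep="\t")
    markers_df = pd.read_csv(stem.with_suffix(".markers.tsv"), sep="\t")
    markers = [Marker(onset=r.onset_s, duration=r.duration_s, scene=r.scene,
                      region=r.region, subject=int(r.subject))
               for r in markers_df.itertuples()]
    return Recording(
        data=data.to_numpy(dtype=float).T,
        fs=float(manifest["fs"]),
        channel_labels=tuple(manifest["channel_labels"]),
        markers=markers,
        montage={k: tuple(v) for k, v in manifest["montage"].items()},
        reference_labels=tuple(manifest["reference_labels"]),
    )


def write_feature_table(table: pd.DataFrame, path: str | Path,
                        manifest: dict | None = None) -> None:
    """Feature table as CSV plus an optional JSON manifest alongside."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    if manifest is not None:
        path.with_suffix(".manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
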