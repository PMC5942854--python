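"""Focus counting and transcription-site/focus colocalization scoring.

Operates on tidy nucleus scenes (``nucleus_id, stage, kind, x, y, z``
with ``kind`` in {"focus", "ts"}; coordinates in μm). A transcription
site is colocalized when its Euclidean distance to the nearest focus in
the same nucleus is at most the threshold radius; scenes without foci
contribute all their sites as non-colocalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["FociSummary", "count_foci", "coloc_fraction"]


@dataclass
class FociSummary:
    per_nucleus: pd.Series
    range: tuple[int, int]
    per_stage_mean: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "per_nucleus": self.per_nucleus.astype(int).to_dict(),
            "range": list(self.range),
            "per_stage_mean": self.per_stage_mean,
        }


def _check_scenes(scenes: pd.DataFrame) -> None:
    for col in ("nucleus_id", "kind", "x", "y", "z"):
        if col not in scenes.columns:
            raise ValueError(f"scene table missing column {col!r}")
    coords = scenes[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("scene coordinates must be finite")


def count_foci(scenes: pd.DataFrame) -> FociSummary:
    """Per-nucleus focus counts with range and per-stage means."""
    _check_scenes(scenes)
    foci = scenes[scenes["kind"] == "focus"]
    all_nuclei = scenes["nucleus_id"].unique()
    counts = (
        foci.groupby("nucleus_id").size().reindex(all_nuclei, fill_value=0).sort_index()
    )
    rng = (int(counts.min()), int(counts.max())) if len(counts) else (0, 0)
    per_stage: dict[str, float] = {}
    if "stage" in scenes.columns:
        stage_of = scenes.drop_duplicates("nucleus_id").set_index("nucleus_id")["stage"]
        per_stage = {
            str(stage): float(counts.loc[ids.index].mean())
            for stage, ids in stage_of.groupby(stage_of)
        }
    return FociSummary(counts, rng, per_stage)


def coloc_fraction(scenes: pd.DataFrame, radius: float) -> tuple[float, pd.DataFrame]:
    """Pooled fraction of transcription sites within ``radius`` of a focus.

    Returns ``(fraction, per_nucleus)`` where ``per_nucleus`` has columns
    ``nucleus_id, stage, n_ts, n_coloc``. Nuclei without transcription
    sites do not enter the pooled denominator; nuclei without foci count
    all their sites as non-colocalized.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    _check_scenes(scenes)
    rows = []
    for nid, sub in scenes.groupby("nucleus_id", sort=False):
        ts = sub[sub["kind"] == "ts"][["x", "y", "z"]].to_numpy(dtype=float)
        if ts.shape[0] == 0:
            continue
        foci = sub[sub["kind"] == "focus"][["x", "y", "z"]].to_numpy(dtype=float)
        if foci.shape[0] == 0:
            n_coloc = 0
        else:
            d = cdist(ts, foci).min(axis=1)
            n_coloc = int(np.sum(d <= radius))
        stage = str(sub["stage"].iloc[0]) if "stage" in sub.columns else ""
        rows.append((nid, stage, int(ts.shape[0]), n_coloc))
    per_nucleus = pd.DataFrame(rows, columns=["nucleus_id", "stage", "n_ts", "n_coloc"])
    total_ts = int(per_nucleus["n_ts"].sum()) if len(per_nucleus) else 0
    if total_ts == 0:
        raise ValueError("no transcription sites in any scene")
    frac = float(per_nucleus["n_coloc"].sum() / total_ts)
    return frac, per_nucleus
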