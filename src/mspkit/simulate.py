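"""Synthetic-data generators for every input the pipeline consumes.

Each generator emulates one class of measurement with the statistical
structure the downstream analyses assume:

* :func:`gen_ts_counts` — per-nucleus transcription-site counts as the sum
  of ``K`` independent Bernoulli(p) cluster states (the binomial burst
  model snapshot).
* :func:`gen_gene_map` — point gene positions on a chromosome with a
  category-labelled subset, optionally concentrated in cluster windows.
* :func:`gen_expression_table` — per-gene log2 fold-changes with a
  designated misregulated subset shifted by a fixed effect.
* :func:`gen_frap_trace` — single-exponential fluorescence recovery with
  Gaussian measurement noise.
* :func:`gen_nucleus_scenes` — 3D focus and transcription-site coordinates
  in spherical nuclei with a controlled colocalization rate.

All generators are deterministic for a fixed integer seed.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "gen_ts_counts",
    "gen_gene_map",
    "gen_expression_table",
    "gen_frap_trace",
    "gen_frap_traces",
    "gen_nucleus_scenes",
    "SceneSizingError",
]


class SceneSizingError(ValueError):
    """Nucleus too crowded to place a non-colocalized transcription site."""


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_ts_counts(
    p: float,
    K: int = 4,
    n: int = 141,
    seed: int | np.random.Generator | None = 0,
    genotype: str = "wild_type",
) -> pd.DataFrame:
    """Simulate per-nucleus transcription-site counts.

    Each nucleus holds ``K`` transcribable cluster states, each ON
    independently with probability ``p``; the observed count is the number
    of ON states, i.e. Binomial(K, p).

    Returns a table with columns ``nucleus_id``, ``genotype``, ``ts_count``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p!r} must lie in [0, 1]")
    if K < 1 or n < 1:
        raise ValueError("K and n must be >= 1")
    rng = _rng(seed)
    counts = rng.binomial(K, p, size=n)
    return pd.DataFrame(
        {
            "nucleus_id": [f"{genotype}_{i:04d}" for i in range(n)],
            "genotype": genotype,
            "ts_count": counts.astype(int),
        }
    )


def gen_gene_map(
    chrom_length: int,
    n_genes: int,
    n_category: int,
    cluster_spec: Sequence[tuple[int, int, int]] = (),
    seed: int | np.random.Generator | None = 0,
    chrom: str = "chrV",
) -> pd.DataFrame:
    """Place genes on a chromosome, concentrating category genes in windows.

    ``cluster_spec`` is a list of ``(start, end, n_in_cluster)`` windows;
    each window receives exactly ``n_in_cluster`` category genes placed
    uniformly inside it. Remaining category genes are placed uniformly
    outside all cluster windows (so each window holds exactly its assigned
    category count); non-category genes are placed uniformly over the whole
    chromosome. Positions are 0-based bp; genes are points (end = start+1).

    Returns a BED-like table: ``chrom, start, end, gene_id, category``.
    """
    if n_category > n_genes:
        raise ValueError("n_category cannot exceed n_genes")
    windows = sorted((int(s), int(e), int(k)) for s, e, k in cluster_spec)
    total_in_clusters = sum(k for _, _, k in windows)
    if total_in_clusters > n_category:
        raise ValueError("cluster windows assign more category genes than exist")
    for (s, e, _), (s2, e2, _) in zip(windows, windows[1:]):
        if s2 < e:
            raise ValueError(f"overlapping cluster windows: [{s},{e}) and [{s2},{e2})")
    for s, e, _ in windows:
        if not (0 <= s < e <= chrom_length):
            raise ValueError(f"cluster window [{s},{e}) outside chromosome of "
                             f"length {chrom_length}")

    rng = _rng(seed)
    positions: list[np.ndarray] = []
    flags: list[np.ndarray] = []
    for s, e, k in windows:
        positions.append(rng.uniform(s, e, size=k))
        flags.append(np.ones(k, dtype=bool))

    def _uniform_outside(n: int) -> np.ndarray:
        out: list[float] = []
        while len(out) < n:
            draw = rng.uniform(0, chrom_length, size=max(n - len(out), 8))
            for s, e, _ in windows:
                draw = draw[(draw < s) | (draw >= e)]
            out.extend(draw.tolist())
        return np.asarray(out[:n])

    n_cat_rest = n_category - total_in_clusters
    positions.append(_uniform_outside(n_cat_rest))
    flags.append(np.ones(n_cat_rest, dtype=bool))
    n_non = n_genes - n_category
    positions.append(rng.uniform(0, chrom_length, size=n_non))
    flags.append(np.zeros(n_non, dtype=bool))

    pos = np.floor(np.concatenate(positions)).astype(np.int64)
    cat = np.concatenate(flags)
    order = np.argsort(pos, kind="stable")
    pos, cat = pos[order], cat[order]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": pos,
            "end": pos + 1,
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "category": cat,
        }
    )


def gen_expression_table(
    n_genes: int,
    misregulated_ids: Iterable[str],
    effect_log2fc: float = -1.0,
    noise_sd: float = 0.2,
    seed: int | np.random.Generator | None = 0,
    genotype: str = "mutant",
) -> pd.DataFrame:
    """Simulate a differential-expression table.

    Misregulated genes draw log2FC ~ Normal(effect_log2fc, noise_sd); all
    other genes ~ Normal(0, noise_sd). The significance flag is set exactly
    on the misregulated set. Gene ids are ``gene00000``.. unless
    ``misregulated_ids`` names others, which must be a subset of those ids.

    Returns columns ``gene_id, log2fc_<genotype>, logcpm, significant``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    mis = set(misregulated_ids)
    unknown = mis - set(gene_ids)
    if unknown:
        raise ValueError(f"misregulated ids not in table: {sorted(unknown)[:5]}")
    flag = np.array([g in mis for g in gene_ids])
    lfc = rng.normal(0.0, noise_sd, size=n_genes) if noise_sd > 0 else np.zeros(n_genes)
    lfc = lfc + np.where(flag, effect_log2fc, 0.0)
    logcpm = rng.normal(5.0, 2.0, size=n_genes)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            f"log2fc_{genotype}": lfc,
            "logcpm": logcpm,
            "significant": flag,
        }
    )


def gen_frap_trace(
    t_half: float,
    plateau: float = 1.0,
    bleach_floor: float = 0.0,
    dt: float = 2.0,
    duration: float = 300.0,
    noise_sd: float = 0.02,
    seed: int | np.random.Generator | None = 0,
    trace_id: str = "trace0",
    compartment: str = "focus",
) -> pd.DataFrame:
    """Simulate a normalized FRAP recovery trace.

    The pre-bleach point at t=0 is exactly 1. For t>0 the bleached region
    recovers as ``I(t) = plateau - (plateau - floor) * exp(-ln2 * t / t_half)``
    plus Gaussian measurement noise.
    """
    if t_half <= 0:
        raise ValueError("t_half must be strictly positive")
    if not 0.0 <= bleach_floor < plateau <= 1.0:
        raise ValueError("require 0 <= bleach_floor < plateau <= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = _rng(seed)
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    k = math.log(2.0) / t_half
    intensity = plateau - (plateau - bleach_floor) * np.exp(-k * t)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=t.size)
    intensity[0] = 1.0  # pre-bleach anchor
    return pd.DataFrame(
        {
            "trace_id": trace_id,
            "compartment": compartment,
            "time_s": t,
            "intensity": intensity,
        }
    )


def gen_frap_traces(
    n_traces: int,
    t_half: float,
    seed: int | np.random.Generator | None = 0,
    compartment: str = "focus",
    **kwargs,
) -> pd.DataFrame:
    """Simulate ``n_traces`` independent recovery traces (long format)."""
    rng = _rng(seed)
    frames = [
        gen_frap_trace(
            t_half,
            seed=rng,
            trace_id=f"{compartment}_{i:02d}",
            compartment=compartment,
            **kwargs,
        )
        for i in range(n_traces)
    ]
    return pd.concat(frames, ignore_index=True)


def _uniform_in_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return v * r


def gen_nucleus_scenes(
    n_nuclei: int = 100,
    foci_range: tuple[int, int] = (4, 14),
    K: int = 4,
    p: float = 1.75 / 4,
    coloc_prob: float = 0.90,
    radius: float = 0.3,
    nucleus_radius: float = 2.0,
    seed: int | np.random.Generator | None = 0,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Simulate 3D nucleus scenes of foci and transcription sites.

    Each nucleus (a sphere of radius ``nucleus_radius`` μm) receives a
    uniform focus count in ``foci_range`` and a transcription-site count
    drawn from the Binomial(K, p) burst model. Each TS is placed within
    ``radius`` of a randomly chosen focus with probability ``coloc_prob``,
    otherwise uniformly in the nucleus at distance > ``radius`` from every
    focus (rejection sampling; a :class:`SceneSizingError` is raised if the
    nucleus is too crowded to fit a non-colocalized site).

    Stages are assigned from the focus count (terciles of ``foci_range``:
    early/mid/late), mirroring the observation that focus number grows
    with spermatocyte maturation.

    Returns a tidy table ``nucleus_id, stage, kind, x, y, z`` with
    ``kind`` in {"focus", "ts"}.
    """
    if not 0.0 <= coloc_prob <= 1.0:
        raise ValueError("coloc_prob must lie in [0, 1]")
    if radius <= 0 or nucleus_radius <= 0:
        raise ValueError("radii must be > 0")
    lo, hi = int(foci_range[0]), int(foci_range[1])
    rng = _rng(seed)
    rows: list[tuple] = []
    span = max(hi - lo, 1)
    for i in range(n_nuclei):
        nid = f"nuc{i:04d}"
        n_foci = int(rng.integers(lo, hi + 1))
        tercile = (n_foci - lo) / span
        stage = "early" if tercile < 1 / 3 else ("mid" if tercile < 2 / 3 else "late")
        foci = _uniform_in_sphere(rng, n_foci, nucleus_radius)
        for x, y, z in foci:
            rows.append((nid, stage, "focus", x, y, z))
        n_ts = int(rng.binomial(K, p))
        for _ in range(n_ts):
            if n_foci > 0 and rng.uniform() < coloc_prob:
                centre = foci[rng.integers(n_foci)]
                pt = centre + _uniform_in_sphere(rng, 1, radius)[0]
            else:
                for _try in range(max_tries):
                    cand = _uniform_in_sphere(rng, 1, nucleus_radius)[0]
                    if n_foci == 0 or np.min(
                        np.linalg.norm(foci - cand, axis=1)
                    ) > radius:
                        pt = cand
                        break
                else:
                    raise SceneSizingError(
                        f"nucleus {nid}: no room for a non-colocalized TS "
                        f"(radius {radius} μm, {n_foci} foci in a "
                        f"{nucleus_radius} μm nucleus)"
                    )
            rows.append((nid, stage, "ts", *pt))
    return pd.DataFrame(rows, columns=["nucleus_id", "stage", "kind", "x", "y", "z"])
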