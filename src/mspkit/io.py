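"""File formats and run configuration.

All tabular artifacts are tab-separated UTF-8 with a header row and '.'
decimal separators. Gene maps travel as BED (0-based half-open: chrom,
start, end, name[, score, strand]) with gene categories in a separate
two-column TSV (gene_id, category). Every written artifact gets a JSON
sidecar (``<file>.meta.json``) recording the tool version, the
configuration hash and the seed, so outputs stay plain TSV/BED while
remaining traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .params import ParamRegistry

__all__ = [
    "read_bed",
    "write_bed",
    "read_categories",
    "read_tsv",
    "write_tsv",
    "write_meta",
    "RunConfig",
]


class BedFormatError(ValueError):
    pass


def read_bed(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Read a BED gene map (>= 4 columns: chrom, start, end, gene_id).

    Coordinates are kept 0-based half-open; pass ``one_based=True`` for
    1-based inclusive input (starts are shifted by -1). Malformed lines
    are reported with their line numbers.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise BedFormatError(
                    f"{path}:{lineno}: expected >= 4 tab-separated columns, "
                    f"got {len(parts)}"
                )
            chrom, start_s, end_s, name = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            rows.append((chrom, start, end, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write intervals as 4-column BED (chrom, start, end, name)."""
    name_col = "gene_id" if "gene_id" in df.columns else "name"
    out = df[["chrom", "start", "end", name_col]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_categories(path: str | Path) -> dict[str, str]:
    """Read a gene_id -> category TSV (with header row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "category"} <= set(df.columns):
        raise ValueError(f"{path}: category TSV needs columns gene_id, category")
    return dict(zip(df["gene_id"], df["category"]))


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_meta(path: str | Path, config_hash: str, seed: int | None, **extra: Any) -> None:
    """Write the provenance sidecar for an artifact."""
    meta = {"tool": "mspkit", "version": __version__, "config_hash": config_hash,
            "seed": seed, **extra}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


@dataclass
class RunConfig:
    """Configuration of an end-to-end synthetic run.

    Unknown keys in a config file are rejected; registry overrides are
    validated against :class:`~mspkit.params.ParamRegistry`.
    """

    seed: int = 0
    out_dir: str = "mspkit_out"
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "ts-fit", "scan", "expr", "frap", "coloc"]
    )
    registry: ParamRegistry = field(default_factory=ParamRegistry)
    log_level: str = "INFO"

    KNOWN_STAGES = ("simulate", "ts-fit", "scan", "expr", "frap", "coloc")

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(self.KNOWN_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"seed", "out_dir", "stages", "registry", "log_level"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        reg = ParamRegistry.from_dict(raw.pop("registry", {}) or {})
        return cls(registry=reg, **raw)

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "stages": list(self.stages),
            "registry": self.registry.to_dict(),
            "log_level": self.log_level,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
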