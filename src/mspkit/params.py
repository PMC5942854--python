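"""Default parameter registry for the synthetic study conditions.

The registry collects every quantitative setting the synthetic-data
generators and the downstream estimators share: the binomial burst-model
parameters for wild-type and *set-17* mutant spermatocytes, FRAP recovery
half-times for spermatocyte foci and hypodermal nuclei, the transcription
site/focus colocalization rate, the differential-expression effect size,
and the genomic binning width used by the cluster scan.

Defaults encode the study conditions:

* ``K = 4`` transcribable cluster states per nucleus; mean transcription
  sites per nucleus 1.75 (wild type, n=141) and 0.82 (mutant, n=153),
  hence per-cluster ON probabilities ``p_wt = 1.75/4`` and
  ``p_mut = 0.82/4``.
* FRAP half-maximal recovery 61 s in spermatocyte foci; ten-fold faster
  (6.1 s) in hypodermal nuclei.
* 90% of transcription sites colocalize with SET-17 foci; 4-14 foci per
  primary spermatocyte.
* 123 misregulated transcripts, down two-fold on average
  (log2FC = -1); 28-member msp gene family.
* 50-kb bins for the spermatogenic gene-cluster scan.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ParamRegistry"]


@dataclass
class ParamRegistry:
    """Registry of the synthetic study conditions.

    All probabilities are in [0, 1], counts are positive integers and
    half-times are strictly positive seconds. ``validate`` (called on
    construction) enforces these invariants and the mutual consistency
    ``K * p_wt = 1.75`` and ``K * p_mut = 0.82`` is preserved by the
    defaults.
    """

    K: int = 4
    p_wt: float = 1.75 / 4
    p_mut: float = 0.82 / 4
    n_wt: int = 141
    n_mut: int = 153
    t_half_foci: float = 61.0
    t_half_hyp: float = 6.1
    coloc_prob: float = 0.90
    effect_log2fc: float = -1.0
    n_misregulated: int = 123
    n_msp: int = 28
    bin_width: int = 50_000
    foci_range: tuple[int, int] = (4, 14)
    # noise / geometry settings for the generators
    log2fc_sd: float = 0.2
    frap_noise_sd: float = 0.02
    nucleus_radius: float = 2.0
    coloc_radius: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.foci_range = tuple(int(v) for v in self.foci_range)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        for name in ("p_wt", "p_mut", "coloc_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} must lie in [0, 1]")
        for name in ("K", "n_wt", "n_mut", "n_misregulated", "n_msp", "bin_width"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name}={v!r} must be a positive integer")
        for name in ("t_half_foci", "t_half_hyp", "nucleus_radius", "coloc_radius"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name}={v!r} must be strictly positive")
        for name in ("log2fc_sd", "frap_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.foci_range
        if not (0 <= lo <= hi):
            raise ValueError(f"foci_range={self.foci_range!r} must be a non-empty "
                             "non-negative integer interval")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["foci_range"] = list(self.foci_range)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ParamRegistry":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown registry keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParamRegistry":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def replace(self, **overrides: Any) -> "ParamRegistry":
        return dataclasses.replace(self, **overrides)
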