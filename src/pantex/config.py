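"""Run configuration: every knob of the pipeline in one serializable object.

Defaults mirror the reference analysis workflow: 1-HU histogram and GLCM
bins, the full 13-direction 3D offset set, natural-log entropies, the
pooled-variance Student t test, a univariate screen at α = 0.05, backward
elimination by likelihood-ratio test with removal threshold 0.10, and the
Youden index as ROC cutoff criterion.  The configuration is embedded in
every output artifact so a run is reproducible from its reports alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

__all__ = ["RunConfig", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class RunConfig:
    bin_width_first_order: float = 1.0   # HU
    bin_width_glcm: float = 1.0          # HU
    glcm_offsets: str = "3d13"           # "3d13" or "inplane"
    log_base: str = "ln"                 # "ln", "log2", "log10"
    glcm_moment_order: int = 1
    skewness_convention: str = "adjusted"
    kurtosis_convention: str = "pearson"
    t_test_variant: str = "student"      # "student" (pooled) or "welch"
    alpha: float = 0.05                  # univariate screen threshold
    p_remove: float = 0.10               # backward-elimination removal threshold
    elimination_criterion: str = "lr"    # "lr" or "wald"
    cutoff_criterion: str = "youden"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; allowed: {sorted(known)}"
            )
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


DEFAULT_CONFIG = RunConfig()
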