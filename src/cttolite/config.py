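"""Pipeline configuration: one structured file, full defaulting.

All randomness flows from the single root ``seed`` through named substreams
(design, cohort, fitting) so stages can be re-run independently yet
reproducibly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml


def substream_seed(root_seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from the root seed and a label."""
    ss = np.random.SeedSequence([int(root_seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    seed: int = 0
    n_respondents: int = 500
    n_interviewers: int = 6
    inconsistency_rate: float = 0.077
    compliance_violation_rate: float = 0.02
    sigma_base: float = 0.15
    sigma_slope: float = 0.08
    noise_mode: str = "multiplicative"
    tau: float = 0.05
    truth_sample: str = "analytic"  # which published decrement column seeds truth
    truth_scale: float = 1.0
    models: list[str] = field(
        default_factory=lambda: [
            "model1",
            "model2",
            "model3_constrained",
            "model4_constrained",
            "model5",
            "model6",
        ]
    )
    cross_validation: str = "none"  # none | state | block | both
    include_flagged: bool = False
    leave_out_interviewers: bool = False
    outdir: str = "cttolite_run"

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("model list must be non-empty")
        if self.cross_validation not in ("none", "state", "block", "both"):
            raise ValueError(f"unknown cross_validation {self.cross_validation!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
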