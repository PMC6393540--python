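"""Run configuration shared by the CLI stages.

Unknown keys are rejected by name so typos never silently change a run;
the canonical JSON hash of the active config is echoed into every output's
metadata for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    log_level: str = "WARNING"
    # solver tolerances
    root_xtol: float = 1e-30
    optimizer_tol: float = 1e-14
    # SAXS stage
    guinier_qrg_limit: float = 1.3
    kratky_smooth_window: int = 7
    kratky_x_threshold: float = 1.9
    kratky_y_threshold: float = 1.17
    multistate_exact_bound: int = 25000
    multistate_beam_width: int = 100
    # structure stage
    sasa_probe: float = 1.4
    sasa_points: int = 960
    alpha3_ranges: dict = field(default_factory=dict)
    # per-stage free-form overrides (validated by their consumers)
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        from coopfold import __version__

        return {"tool_version": __version__, "config_hash": self.hash(),
                "seed": self.seed}
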