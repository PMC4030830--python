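"""Runtime configuration (tolerances, paths, policies) with YAML loading."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Tuple

import yaml

__all__ = ["Config", "load_config"]


@dataclass(frozen=True)
class Config:
    tol_gu_amide: float = 0.2
    tol_gu_c30: float = 0.2
    tol_mass: float = 1.0
    map_path: Optional[str] = None  # None -> bundled map
    enzyme_table: Optional[str] = None  # None -> bundled rules
    exclusion_labels: Tuple[str, ...] = ("melibiose",)
    # 'report-all' keeps every within-tolerance candidate with a flag;
    # it is the only policy implemented (silent selection is a non-goal).
    ambiguity_policy: str = "report-all"

    def __post_init__(self) -> None:
        if min(self.tol_gu_amide, self.tol_gu_c30, self.tol_mass) <= 0:
            raise ValueError("all tolerances must be positive")
        for attr in ("map_path", "enzyme_table"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise ValueError(f"{attr} does not resolve: {value}")


def load_config(path=None) -> Config:
    if path is None:
        return Config()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "exclusion_labels" in raw:
        raw["exclusion_labels"] = tuple(raw["exclusion_labels"])
    return Config(**raw)
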