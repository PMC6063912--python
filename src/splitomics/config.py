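"""Run configuration: a YAML file mirroring the CLI flags.

The file maps subcommand names to flag defaults, e.g.::

    deg:
      p_threshold: 0.05
      fc_threshold: 1.5
    opls:
      n_orth: 1
      folds: 8
      permutations: 1000
      seed: 0

Values given on the command line override the file.  ``RunConfig``
validates the ranges once at load time and round-trips losslessly
through its file representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]

_RANGE_CHECKS = {
    ("deg", "p_threshold"): lambda v: 0.0 < v < 1.0,
    ("deg", "fc_threshold"): lambda v: v >= 1.0,
    ("opls", "alpha"): lambda v: 0.0 < v < 1.0,
    ("opls", "n_orth"): lambda v: v >= 0,
    ("opls", "folds"): lambda v: v >= 2,
    ("opls", "permutations"): lambda v: v >= 1,
    ("opls", "seed"): lambda v: v >= 0,
    ("simulate", "seed"): lambda v: v >= 0,
}


@dataclass
class RunConfig:
    """Per-subcommand flag defaults, validated against the CLI's ranges."""

    sections: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for section, params in self.sections.items():
            if not isinstance(params, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            for key, value in params.items():
                check = _RANGE_CHECKS.get((section, key))
                if check is not None and not check(value):
                    raise ValueError(
                        f"config value {section}.{key} = {value!r} out of range"
                    )

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config root must be a mapping")
        return cls(sections=data)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.sections, fh, sort_keys=True)

    def default_map(self) -> dict:
        """The click ``default_map`` structure (subcommand -> params)."""
        return {k: dict(v) for k, v in self.sections.items()}
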