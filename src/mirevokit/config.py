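"""Run configuration: TOML loading, defaults, aggregated validation."""

from __future__ import annotations

import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

__all__ = ["RunConfig", "load_config", "ConfigError", "DEFAULTS", "setup_logging"]

logger = logging.getLogger("mirevokit")


class ConfigError(ValueError):
    """All validation problems of one config, reported together."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  " + "\n  ".join(problems))


DEFAULTS: dict[str, dict[str, Any]] = {
    "run": {"out_dir": "mirevo_out", "seed": 1, "log_level": "INFO"},
    "simulate": {
        "genome_length": 10_000,
        "gc_content": 0.5,
        "transition_rate": 0.10,
        "transversion_rate": 0.05,
        "indel_rate": 0.0,
        "n_precursors": 6,
        "stem_len": 30,
        "loop_len": 8,
        "mature_len": 22,
        "library_depth": 2_000,
        "base_arm_rate": 0.02,
        "n_diff": 2,
        "fold_change": 4.0,
        "read_len": 36,
        "adapter": "TCGTATGCCGTCTTCTGCTTG",
        "contam_rate": 0.05,
        "n_db_seqs": 4,
        "species": ["melsim", "pseudo"],
    },
    "preprocess": {
        "min_overlap": 6,
        "min_len": 18,
        "max_mismatch_frac": 0.1,
        "keep_untrimmed": True,
    },
    "filter": {"max_mismatch_db": 2},
    "profile": {"max_mismatch_mirna": 1},
    "homolog": {"min_identity": 0.95},
    "distance": {"all_pairs": False},
    "diffexp": {"alpha": 0.05, "correction": "bh"},
    "inputs": {},  # optional external files; the simulate stage fills the gap
}

_RANGES: dict[tuple[str, str], tuple[float, float]] = {
    ("filter", "max_mismatch_db"): (0, 3),
    ("profile", "max_mismatch_mirna"): (0, 3),
    ("preprocess", "min_overlap"): (4, 50),
    ("preprocess", "max_mismatch_frac"): (0.0, 0.5),
    ("diffexp", "alpha"): (1e-12, 1.0),
    ("simulate", "gc_content"): (0.0, 1.0),
    ("simulate", "transition_rate"): (0.0, 0.49),
    ("simulate", "transversion_rate"): (0.0, 0.49),
    ("simulate", "indel_rate"): (0.0, 0.2),
    ("homolog", "min_identity"): (0.5, 1.0),
}


@dataclass
class RunConfig:
    sections: dict[str, dict[str, Any]] = field(default_factory=dict)
    source: Path | None = None

    def __getitem__(self, section: str) -> dict[str, Any]:
        return self.sections[section]

    @property
    def out_dir(self) -> Path:
        return Path(self.sections["run"]["out_dir"])

    @property
    def seed(self) -> int:
        return int(self.sections["run"]["seed"])


def _merged(user: dict[str, Any]) -> tuple[dict[str, dict[str, Any]], list[str]]:
    problems: list[str] = []
    merged = {sec: dict(vals) for sec, vals in DEFAULTS.items()}
    for sec, vals in user.items():
        if sec not in DEFAULTS:
            problems.append(f"unknown section [{sec}]")
            continue
        if not isinstance(vals, dict):
            problems.append(f"section [{sec}] must be a table")
            continue
        for key, value in vals.items():
            if sec != "inputs" and key not in DEFAULTS[sec]:
                problems.append(f"unknown key {sec}.{key}")
                continue
            merged[sec][key] = value
    return merged, problems


def load_config(path: str | Path) -> RunConfig:
    """Load a TOML run config, fill defaults, and validate everything.

    All problems (unknown sections/keys, out-of-range values, missing
    input files) are aggregated into one ConfigError.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    merged, problems = _merged(user)
    for (sec, key), (lo, hi) in _RANGES.items():
        v = merged[sec][key]
        if not isinstance(v, (int, float)) or not lo <= v <= hi:
            problems.append(f"{sec}.{key}={v!r} outside [{lo}, {hi}]")
    if merged["diffexp"]["correction"] not in ("bh", "none"):
        problems.append("diffexp.correction must be 'bh' or 'none'")
    if not isinstance(merged["run"]["seed"], int) or merged["run"]["seed"] < 0:
        problems.append("run.seed must be a non-negative integer")
    species = merged["simulate"]["species"]
    if not isinstance(species, (list, tuple)) or len(species) < 2:
        problems.append("simulate.species must list at least two species")
    for key, value in merged["inputs"].items():
        if not Path(value).exists():
            problems.append(f"inputs.{key}: path {value!r} does not exist")
    if problems:
        raise ConfigError(problems)
    return RunConfig(merged, source=path)


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
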