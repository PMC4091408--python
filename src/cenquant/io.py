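"""Format readers/writers, run configuration and structured run logging.

Interchange conventions: genomic coordinates are 0-based half-open
(bedGraph); pixel coordinates are 0-based; CSV (with header row) is the
interchange format between pipeline stages so each module is independently
testable from files.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .occupancy import ReadProfile

__all__ = ["read_profile", "write_profile", "read_pairs", "write_pairs",
           "RunConfig", "RunLog"]


# ---------------------------------------------------------------------------
# read-count profiles
# ---------------------------------------------------------------------------

def _profile_from_intervals(df: pd.DataFrame) -> ReadProfile:
    df = df.sort_values("start").reset_index(drop=True)
    if (df["end"] <= df["start"]).any():
        raise ValueError("intervals must have end > start")
    if (df["start"].values[1:] < df["end"].values[:-1]).any():
        raise ValueError("overlapping intervals in profile")
    if (df["count"] < 0).any():
        raise ValueError("counts must be >= 0")
    start = int(df["start"].min())
    end = int(df["end"].max())
    counts = np.zeros(end - start)
    for s, e, c in zip(df["start"], df["end"], df["count"]):
        counts[int(s) - start:int(e) - start] = c
    chrom = str(df["chrom"].iloc[0]) if "chrom" in df else "locus"
    return ReadProfile(start=start, counts=counts, chrom=chrom)


def read_profile(path: str) -> ReadProfile:
    """Read a bedGraph (chrom, start, end, count; 0-based half-open) or CSV.

    CSV dialects are auto-detected from the header: either interval columns
    (``start, end, count``) or per-position columns (``position, count``,
    unit-width intervals). Unsorted input is canonicalized; overlapping
    intervals are an error.
    """
    with open(path) as fh:
        first = fh.readline()
    if "," in first and any(c.isalpha() for c in first.split(",")[0]):
        df = pd.read_csv(path)
        cols = {c.lower().strip(): c for c in df.columns}
        if "start" in cols and "end" in cols:
            df = df.rename(columns={cols["start"]: "start", cols["end"]: "end",
                                    cols.get("count", "count"): "count"})
        elif "position" in cols:
            df = df.rename(columns={cols["position"]: "start",
                                    cols.get("count", "count"): "count"})
            df["end"] = df["start"] + 1
        else:
            raise ValueError("CSV profile needs start/end or position columns")
        if "chrom" not in df:
            df["chrom"] = "locus"
    else:
        df = pd.read_csv(path, sep=r"\s+", header=None,
                         names=["chrom", "start", "end", "count"],
                         comment="#")
    return _profile_from_intervals(df[["chrom", "start", "end", "count"]])


def write_profile(profile: ReadProfile, path: str) -> None:
    """Write a profile as bedGraph (run-length encoded, zero runs omitted)."""
    profile.to_intervals().to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# sister-pair tables
# ---------------------------------------------------------------------------

PAIR_COLUMNS = ["experiment_id", "cell_id", "pair_id", "i1", "i2"]


def read_pairs(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("i1", "i2") if c not in df.columns]
    if missing:
        raise ValueError(f"pair table missing columns: {missing}")
    for col, default in (("experiment_id", "exp1"), ("cell_id", 0)):
        if col not in df.columns:
            df[col] = default
    if "pair_id" not in df.columns:
        df["pair_id"] = np.arange(len(df))
    return df[PAIR_COLUMNS]


def write_pairs(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration and logging
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = {
    "seed", "output_dir", "log_level",
    "cell", "pairs", "blot", "profile", "spots", "risk", "budget",
    "occupancy", "fluctuation", "combine", "standard_bound",
}


@dataclass
class RunConfig:
    """Schema-checked pipeline configuration (unknown top-level keys rejected)."""

    seed: int = 0
    output_dir: str | None = None
    log_level: str = "info"
    sections: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=raw.get("output_dir"),
            log_level=str(raw.get("log_level", "info")),
            sections={k: v for k, v in raw.items()
                      if k not in ("seed", "output_dir", "log_level")},
        )

    def section(self, name: str) -> dict:
        return dict(self.sections.get(name, {}))

    def hash(self) -> str:
        payload = json.dumps(
            {"seed": self.seed, "sections": self.sections}, sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunLog:
    """Structured events plus named counters for every warning path."""

    events: list = field(default_factory=list)
    counters: dict = field(default_factory=dict)
    config_hash: str = ""

    def event(self, stage: str, message: str) -> None:
        self.events.append({"t": time.time(), "stage": stage, "message": message})

    def count(self, name: str, increment: int = 1) -> None:
        self.counters[name] = self.counters.get(name, 0) + increment

    def to_json(self) -> str:
        from . import __version__
        return json.dumps(
            {"version": __version__, "config_hash": self.config_hash,
             "counters": self.counters, "events": self.events},
            indent=2,
        )
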