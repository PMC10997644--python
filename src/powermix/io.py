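"""Readers, writers, packaged fixtures and run manifests."""

from __future__ import annotations

import datetime
import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .elicitation import PredictiveInterval
from .types import CensoredSummary, IPHyper

_SUMMARY_KEYS = ("n", "log_inv_t", "u1", "u2", "u3", "S1", "S2", "S3")
_HYPER_KEYS = ("a1", "b1", "a2", "b2", "a3", "b3", "a", "b", "c")


def _parse_keyvalue(text: str, path: str = "<string>") -> dict[str, float]:
    out: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        try:
            out[key.strip()] = float(value)
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: bad number {value.strip()!r}") from err
    return out


def read_summary(path) -> CensoredSummary:
    """Read a key-value summary file (keys n, log_inv_t, u1..u3, S1..S3)."""
    text = Path(path).read_text()
    kv = _parse_keyvalue(text, str(path))
    missing = [k for k in _SUMMARY_KEYS if k not in kv]
    if missing:
        raise ValueError(f"{path}: missing keys {missing}")
    return CensoredSummary(n=int(kv["n"]), log_inv_t=kv["log_inv_t"],
                           u1=int(kv["u1"]), u2=int(kv["u2"]), u3=int(kv["u3"]),
                           S1=kv["S1"], S2=kv["S2"], S3=kv["S3"])


def write_summary(summary: CensoredSummary, path) -> None:
    lines = [f"{key} = {getattr(summary, key)!r}" for key in _SUMMARY_KEYS]
    Path(path).write_text("\n".join(lines) + "\n")


def read_hyperparameters(path) -> IPHyper:
    """Read informative-prior hyperparameters from a key-value file."""
    kv = _parse_keyvalue(Path(path).read_text(), str(path))
    missing = [k for k in _HYPER_KEYS if k not in kv]
    if missing:
        raise ValueError(f"{path}: missing keys {missing}")
    return IPHyper(**{k: kv[k] for k in _HYPER_KEYS})


def read_labeled_data(path) -> pd.DataFrame:
    """Read delimited labeled lifetimes with header ``component,value``."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep)
    frame.columns = [c.strip().lower() for c in frame.columns]
    for col in ("component", "value"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    bad = frame[~frame["component"].isin((1, 2, 3))]
    if len(bad):
        raise ValueError(
            f"{path}: invalid component label at data line {bad.index[0] + 2}")
    return frame[["component", "value"]]


def read_intervals(path) -> list[PredictiveInterval]:
    """Read an elicitation spec: whitespace-delimited ``z1 z2 target`` rows."""
    intervals = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'z1 z2 target'")
        z1, z2, target = map(float, parts)
        intervals.append(PredictiveInterval(z1, z2, target))
    if not intervals:
        raise ValueError(f"{path}: no intervals found")
    return intervals


# -- packaged fixtures -------------------------------------------------------

def _fixture_path(name: str) -> Path:
    return Path(resources.files("powermix") / "data" / name)


def kevlar_summary() -> CensoredSummary:
    """Packaged real-data fixture: the censored Kevlar lifetime summary."""
    return read_summary(_fixture_path("kevlar_summary.txt"))


def reference_hyper() -> IPHyper:
    """Packaged informative-prior hyperparameters from the elicitation study."""
    return read_hyperparameters(_fixture_path("reference_hyperparameters.txt"))


def packaged_intervals() -> list[PredictiveInterval]:
    """Packaged nine-interval elicitation spec."""
    return read_intervals(_fixture_path("elicitation_intervals.txt"))


# -- manifests ---------------------------------------------------------------

def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(out_dir, command: str, config: dict,
                   inputs: list[str] | None = None) -> Path:
    """Write a JSON run manifest sufficient to re-execute the run."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "input_digests": {str(p): _digest(p) for p in (inputs or [])},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
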