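"""Persistence: JSONL trial logs, manifests, and campaign output layout.

A campaign output directory has subdirectories ``images/``, ``logs/``,
``checkpoints/`` and ``reports/``; every run writes a manifest (config hash,
master seed, package version) sufficient for bit-exact replay.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Iterable

from .config import CampaignConfig
from .errors import DataError
from .trials import TIMING_MS, TrialRecord

__all__ = [
    "config_hash",
    "write_trial_log",
    "read_trial_log",
    "write_manifest",
    "prepare_output_dir",
]

SUBDIRS = ("images", "logs", "checkpoints", "reports")


def config_hash(config: CampaignConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode("utf8")).hexdigest()[:16]


def prepare_output_dir(path) -> dict[str, str]:
    os.makedirs(path, exist_ok=True)
    out = {}
    for sub in SUBDIRS:
        p = os.path.join(path, sub)
        os.makedirs(p, exist_ok=True)
        out[sub] = p
    return out


def write_trial_log(
    records: Iterable[TrialRecord], path, config: CampaignConfig | None = None
) -> None:
    """One JSON record per line, preceded by a session metadata header."""
    header = {
        "_header": True,
        "timing_ms": TIMING_MS,
        "config_hash": None if config is None else config_hash(config),
        "master_seed": None if config is None else config.master_seed,
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for r in records:
            fh.write(json.dumps(r.to_dict()) + "\n")


def read_trial_log(path) -> tuple[list[TrialRecord], dict]:
    records: list[TrialRecord] = []
    header: dict = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            if d.get("_header"):
                header = d
                continue
            try:
                records.append(TrialRecord.from_dict(d))
            except TypeError as exc:
                raise DataError(f"malformed trial record on line {i + 1}: {exc}") from None
    return records, header


def write_manifest(path, config: CampaignConfig, extra: dict | None = None) -> None:
    from . import __version__

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "master_seed": config.master_seed,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
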