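"""Bundled data files: expert partitions for the calibration regimes.

The partitions match the bundled minimal model's trajectories only; users
running a different model must supply their own partition files.
"""

from __future__ import annotations

from importlib import resources

import json

from tempocode.clustering import Partition

_EXPERT_DIR = "expert"


def load_expert_partitions() -> dict[str, Partition]:
    """Expert partitions keyed by regime id, from the package data."""
    out: dict[str, Partition] = {}
    root = resources.files(__package__) / _EXPERT_DIR
    for entry in root.iterdir():
        if entry.name.endswith(".json"):
            d = json.loads(entry.read_text(encoding="utf-8"))
            out[entry.name[: -len(".json")]] = Partition.from_json_dict(d)
    return out
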