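"""Flat JSON rate-set configuration and tabular result output.

A rate config is a JSON object with the eight canonical rate keys and an
optional ``potencies`` sub-object::

    {"k_sx": 10.0, "k_xs": 1.35, ..., "potencies": {"r_s": 0, "r_x": 0,
     "r_p": 1, "r_xp": 1}}

Result writers embed the full parameterization (rates, potencies, seeds,
grids, budget, package version) alongside the numbers so every output file is
regenerable on its own.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .graph_model import EDGE_NAMES, Potencies, RateSet

__all__ = [
    "load_rate_config",
    "save_rate_config",
    "write_table",
    "write_json_summary",
]


def load_rate_config(path) -> tuple:
    """Read ``(RateSet, Potencies)`` from a flat JSON config file."""
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: rate config must be a JSON object")
    unknown = set(raw) - set(EDGE_NAMES) - {"potencies"}
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    rates = RateSet.from_dict(raw)
    pot = Potencies(**raw.get("potencies", {}))
    return rates, pot


def save_rate_config(path, rates: RateSet, potencies: Potencies | None = None) -> None:
    doc = rates.to_dict()
    doc["potencies"] = (potencies or Potencies()).to_dict()
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_table(df: pd.DataFrame, path) -> None:
    """Write a tidy CSV (no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_json_summary(doc: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        try:
            return o.item()  # numpy scalars
        except AttributeError:
            return str(o)

    Path(path).write_text(json.dumps(doc, indent=2, default=default) + "\n")
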