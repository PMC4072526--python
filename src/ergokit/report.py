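"""JSON report rendering shared by the CLI subcommands."""

from __future__ import annotations

import json
import math

import numpy as np

SCHEMA_VERSION = "1.0"


def _round_sig(x: float, sig: int = 12) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.{sig}g}")


def _clean(obj):
    """Round floats to 12 significant digits and de-numpy containers."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_clean(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return None if not math.isfinite(x) else _round_sig(x)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def render(payload: dict, kind: str) -> dict:
    return {"schema_version": SCHEMA_VERSION, "kind": kind, **_clean(payload)}


def dump_json(payload: dict, kind: str, path=None) -> str:
    doc = json.dumps(render(payload, kind), indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(doc + "\n")
    return doc
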