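"""Configuration files and result serialization.

The config dialect is YAML with the keys::

    n: 50            # codons
    r: 12            # ribosome footprint
    alpha: 1.0       # initiation rate
    beta: 0.5        # termination rate
    gamma: 1.0       # scalar, or list of length n - r (hops r..n-1)
    slow_codons:     # optional rate edits
      - {position: 25, rate: 0.2}
    premature_stop:  # optional
      position: 25
      mu: 0.5
    feedback:        # optional
      alpha_I: 1.0
      k_I: 1.0
      d_I: 1.0
      rho_m: 1.0

Unknown keys are rejected.  Results embed the fully resolved configuration
and the package version; floats are written with 6 significant digits so
identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .lattice import ConfigurationError, LatticeConfig
from .regulation import FeedbackSpec, PrematureStopSpec, make_slow_profile

__all__ = ["RunSpec", "load_config", "save_config", "config_dict",
           "write_json", "write_csv", "format_float"]

_TOP_KEYS = {"n", "r", "alpha", "beta", "gamma", "slow_codons",
             "premature_stop", "feedback"}


@dataclass(frozen=True)
class RunSpec:
    """A fully resolved model: lattice rates plus optional regulation blocks."""

    config: LatticeConfig
    stop: PrematureStopSpec | None = None
    feedback: FeedbackSpec | None = None


def _require(mapping: dict, keys: set[str], context: str) -> None:
    unknown = set(mapping) - keys
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {context}; allowed: {sorted(keys)}")


def from_dict(raw: dict) -> RunSpec:
    """Validate a raw mapping into a :class:`RunSpec`."""
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config must be a mapping, got {type(raw).__name__}")
    _require(raw, _TOP_KEYS, "config")
    for key in ("n", "r", "alpha", "beta"):
        if key not in raw:
            raise ConfigurationError(f"missing required key {key!r}")
    config = LatticeConfig(raw["n"], raw["r"], raw["alpha"], raw["beta"],
                           raw.get("gamma", 1.0))
    for item in raw.get("slow_codons") or []:
        _require(item, {"position", "rate"}, "slow_codons entry")
        config = make_slow_profile(config, [item["position"]], item["rate"])
    stop = None
    if raw.get("premature_stop") is not None:
        block = raw["premature_stop"]
        _require(block, {"position", "mu"}, "premature_stop")
        stop = PrematureStopSpec(block["position"], block["mu"])
        config.gamma_at(stop.position)  # validates position range
    feedback = None
    if raw.get("feedback") is not None:
        block = raw["feedback"]
        _require(block, {"alpha_I", "k_I", "d_I", "rho_m"}, "feedback")
        feedback = FeedbackSpec(block["alpha_I"], block["k_I"], block["d_I"],
                                block.get("rho_m", 1.0))
    return RunSpec(config=config, stop=stop, feedback=feedback)


def config_dict(spec: RunSpec) -> dict:
    """Round-trippable plain mapping of a :class:`RunSpec`."""
    cfg = spec.config
    out: dict = {"n": cfg.n, "r": cfg.r, "alpha": cfg.alpha, "beta": cfg.beta,
                 "gamma": list(cfg.gamma)}
    if spec.stop is not None:
        out["premature_stop"] = {"position": spec.stop.position, "mu": spec.stop.mu}
    if spec.feedback is not None:
        fb = spec.feedback
        out["feedback"] = {"alpha_I": fb.alpha_I, "k_I": fb.k_I, "d_I": fb.d_I,
                           "rho_m": fb.rho_m}
    return out


def load_config(path: str | Path) -> RunSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return from_dict(raw)


def save_config(spec: RunSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict(spec), fh, sort_keys=True)


def format_float(x: float, sig: int = 6) -> float:
    """Round to ``sig`` significant digits for byte-stable outputs."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{sig}g}")


def _jsonable(obj, sig: int = 6):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v, sig) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return format_float(float(obj), sig)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def write_json(payload: dict, path: str | Path, spec: RunSpec | None = None) -> None:
    """Write a result JSON embedding the resolved config and version."""
    doc = {"package": "ribolattice", "version": __version__}
    if spec is not None:
        doc["config"] = config_dict(spec)
    doc.update(payload)
    with open(path, "w") as fh:
        json.dump(_jsonable(doc), fh, indent=2, sort_keys=False)
        fh.write("\n")


def write_csv(rows: list[dict], path: str | Path) -> None:
    """Comma-separated, header row, 6-significant-digit floats."""
    if not rows:
        raise ValueError("no rows to write")
    cols = list(rows[0])
    lines = [",".join(cols)]
    for row in rows:
        lines.append(",".join(
            f"{format_float(v):.6g}" if isinstance(v, (float, np.floating))
            else str(v) for v in (row[c] for c in cols)))
    Path(path).write_text("\n".join(lines) + "\n")
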