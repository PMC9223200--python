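"""Readers and writers for the CSV/JSON formats used across the package.

Chronicles travel as plain CSV with header ``time,X,N,S,E,CO2,dCO2dt`` (any
subset of the variable columns; comma-separated, dot decimal).  Parameter
sets travel as JSON documents with three sections (growth, yield,
second_step) and an optional meta section; the yield "family" tag selects
the concrete yield type.  Units are fixed package-wide: g/L and hours.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import (
    GrowthParams,
    SecondStepParams,
    YieldConstant,
    YieldFunction,
    YieldLinearSmoothed,
    YieldQuadExp,
)
from .simulator import Chronicle

__all__ = [
    "ParameterSet",
    "read_chronicle",
    "write_chronicle",
    "read_params",
    "write_params",
    "yield_from_dict",
    "load_preset",
    "available_presets",
]

_CHRONICLE_COLS = ("X", "N", "S", "E", "CO2", "dCO2dt")


@dataclass(frozen=True)
class ParameterSet:
    """Full model parameterization: growth + yield family + second step."""

    growth: GrowthParams
    yield_fn: YieldFunction
    second_step: SecondStepParams
    meta: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.meta.get("name", "unnamed")


# ---------------------------------------------------------------------------
# chronicles
# ---------------------------------------------------------------------------

def read_chronicle(path: str | Path, meta: dict | None = None) -> Chronicle:
    """Read a chronicle CSV; partial column sets are allowed.

    Validates monotone time and non-negative concentrations, naming the
    offending row on failure.
    """
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing 'time' column")
    unknown = [c for c in df.columns if c not in ("time",) + _CHRONICLE_COLS]
    if unknown:
        raise ValueError(f"{path}: unknown columns {unknown}")
    t = df["time"].to_numpy(float)
    bad = np.where(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValueError(f"{path}: time not strictly increasing at row {bad[0] + 1}")
    for c in _CHRONICLE_COLS:
        if c == "dCO2dt" or c not in df.columns:
            continue  # a rate column may legitimately dip below 0 with noise
        neg = np.where(df[c].to_numpy(float) < 0)[0]
        if neg.size:
            raise ValueError(f"{path}: negative {c} at row {neg[0]}")
    return Chronicle.from_frame(df, meta=meta)


def write_chronicle(ch: Chronicle, path: str | Path) -> None:
    ch.to_frame().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------

_YIELD_SCHEMAS = {
    "linear_smoothed": ({"a", "b", "N_dagger"}, YieldLinearSmoothed),
    "quad_exp": ({"a", "b", "N_dagger"}, YieldQuadExp),
    "constant": ({"Y"}, YieldConstant),
}


def yield_from_dict(d: dict) -> YieldFunction:
    """Build a yield function from its JSON representation."""
    d = dict(d)
    fam = d.pop("family", None)
    if fam not in _YIELD_SCHEMAS:
        raise ValueError(f"unknown yield family {fam!r}; "
                         f"expected one of {sorted(_YIELD_SCHEMAS)}")
    keys, cls = _YIELD_SCHEMAS[fam]
    _check_keys(f"yield[{fam}]", d, keys)
    return cls(**d)


def _check_keys(section: str, d: dict, expected: set[str]) -> None:
    missing = expected - d.keys()
    extra = d.keys() - expected
    if missing:
        raise ValueError(f"{section}: missing key(s) {sorted(missing)}")
    if extra:
        raise ValueError(f"{section}: unknown key(s) {sorted(extra)}")


def params_from_dict(doc: dict) -> ParameterSet:
    _check_keys("parameter set", {k: v for k, v in doc.items() if k != "meta"},
                {"growth", "yield", "second_step"})
    g = dict(doc["growth"])
    _check_keys("growth", g, {"mu_N_max", "K_N"})
    s = dict(doc["second_step"])
    _check_keys("second_step", s, {"k", "beta", "mu_S_max", "K_S", "K_E"})
    return ParameterSet(
        growth=GrowthParams(**g),
        yield_fn=yield_from_dict(doc["yield"]),
        second_step=SecondStepParams(**s),
        meta=dict(doc.get("meta", {})),
    )


def params_to_dict(ps: ParameterSet) -> dict:
    sp = ps.second_step
    return {
        "growth": {"mu_N_max": ps.growth.mu_N_max, "K_N": ps.growth.K_N},
        "yield": ps.yield_fn.params_dict(),
        "second_step": {"k": sp.k, "beta": sp.beta, "mu_S_max": sp.mu_S_max,
                        "K_S": sp.K_S, "K_E": sp.K_E},
        "meta": dict(ps.meta),
    }


def read_params(path: str | Path) -> ParameterSet:
    with open(path) as fh:
        return params_from_dict(json.load(fh))


def write_params(ps: ParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(params_to_dict(ps), fh, indent=2)
        fh.write("\n")


def available_presets() -> list[str]:
    pkg = resources.files("mainferm") / "presets"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".json"))


def load_preset(name: str) -> ParameterSet:
    """Load a shipped parameter preset by name (or a JSON file path)."""
    pkg = resources.files("mainferm") / "presets" / f"{name}.json"
    if pkg.is_file():
        return params_from_dict(json.loads(pkg.read_text()))
    p = Path(name)
    if p.is_file():
        return read_params(p)
    raise ValueError(f"unknown preset {name!r}; "
                     f"available: {available_presets()}")
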