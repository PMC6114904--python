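"""File formats: lifetime tables (TSV/CSV) and parameter files (JSON).

Lifetime tables are delimited text with header ``force_pN, lifetime_s``
and an optional ``censored`` column (0/1); TSV is the default on write,
comma and whitespace delimiters are accepted on read.  Parameter files are
flat JSON with the keys of the published best-fit table plus optional
environment overrides; a packaged ``table1.json`` carries the wild-type
values.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import LifetimeDataset
from .landscape import InvalidParametersError, ModelParameters, PhysicalEnvironment

__all__ = [
    "read_lifetime_table",
    "write_lifetime_table",
    "read_params",
    "write_params",
    "load_table1",
]

PARAM_KEYS = {
    "E0": "E0", "E1": "E1", "H": "H", "G": "G",
    "d_nm": "d", "r0_nm": "r0",
    "alpha_min_deg": "alpha_min", "alpha_c_deg": "alpha_c",
    "alpha_max_deg": "alpha_max", "phi_deg": "phi",
}
ENV_KEYS = {"temperature_K": "temperature_K", "viscosity_Pa_s": "viscosity_Pa_s",
            "measure": "measure"}


class ParseError(ValueError):
    """Malformed input file; the message lists offending lines/keys."""


def read_lifetime_table(path) -> LifetimeDataset:
    """Read a delimited lifetime table, reporting malformed rows by line."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse delimited text ({exc})") from exc
    df.columns = [c.strip() for c in df.columns]
    missing = {"force_pN", "lifetime_s"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    problems = []
    for col in ("force_pN", "lifetime_s"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for i in np.flatnonzero(vals.isna().to_numpy()):
            problems.append(f"line {i + 2}: non-numeric {col} = {df[col].iloc[i]!r}")
        df[col] = vals
    bad_t = np.flatnonzero((df["lifetime_s"] <= 0).to_numpy())
    problems += [f"line {i + 2}: non-positive lifetime_s" for i in bad_t]
    bad_f = np.flatnonzero((df["force_pN"] < 0).to_numpy())
    problems += [f"line {i + 2}: negative force_pN" for i in bad_f]
    if problems:
        raise ParseError(f"{path}: " + "; ".join(problems))
    censored = (
        df["censored"].astype(float).astype(bool).to_numpy()
        if "censored" in df.columns
        else None
    )
    return LifetimeDataset.from_arrays(
        df["force_pN"].to_numpy(), df["lifetime_s"].to_numpy(), censored,
        provenance=str(path),
    )


def write_lifetime_table(dataset: LifetimeDataset, path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _params_from_dict(raw: dict, source: str) -> tuple[ModelParameters, PhysicalEnvironment]:
    unknown = set(raw) - set(PARAM_KEYS) - set(ENV_KEYS)
    if unknown:
        raise ParseError(f"{source}: unknown key(s) {sorted(unknown)}")
    missing = set(PARAM_KEYS) - set(raw)
    if missing:
        raise ParseError(f"{source}: missing key(s) {sorted(missing)}")
    try:
        params = ModelParameters(**{arg: float(raw[k]) for k, arg in PARAM_KEYS.items()})
    except InvalidParametersError as exc:
        raise ParseError(f"{source}: {exc}") from exc
    env_kw = {arg: raw[k] for k, arg in ENV_KEYS.items() if k in raw}
    env = PhysicalEnvironment(**env_kw)
    return params, env


def read_params(path) -> tuple[ModelParameters, PhysicalEnvironment]:
    """Read and validate a parameter JSON file."""
    path = Path(path)
    raw = json.loads(path.read_text())
    return _params_from_dict(raw, str(path))


def write_params(params: ModelParameters, env: PhysicalEnvironment, path) -> None:
    out = {
        "E0": params.E0, "E1": params.E1, "H": params.H, "G": params.G,
        "d_nm": params.d, "r0_nm": params.r0,
        "alpha_min_deg": params.alpha_min, "alpha_c_deg": params.alpha_c,
        "alpha_max_deg": params.alpha_max, "phi_deg": params.phi,
        "temperature_K": env.temperature_K, "viscosity_Pa_s": env.viscosity_Pa_s,
        "measure": env.measure,
    }
    Path(path).write_text(json.dumps(out, indent=2) + "\n")


def load_table1() -> tuple[ModelParameters, PhysicalEnvironment]:
    """The packaged wild-type best-fit parameter set."""
    raw = json.loads(
        resources.files("catchbond").joinpath("data/table1.json").read_text()
    )
    return _params_from_dict(raw, "table1.json")
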