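"""Readers and writers for the package's CSV/JSON artifacts, plus packaged
parameter tables.

All tabular interchange is plain CSV with declared schemas; temperature
columns must announce their unit in the header (``T_C`` or ``T_K``) — no
silent guessing.  Fit results and synthetic-data truth sidecars are JSON.

Packaged fixtures (installed with the package, under ``pcsaftsle/data``):

* ``pcsaft_parameters.csv`` — published pure-component PC-SAFT parameters
  for 8 drugs and 3 polymers (columns: name, kind, Mw, m_over_Mw, sigma,
  u_kB, eps_assoc_kB, kappa_assoc, n_donor, n_acceptor);
* ``melting_properties.csv`` — melting onset (deg C), enthalpy of fusion
  (kJ/mol) and the heat-capacity difference Cp(T) = a + b*T of the 8 drugs;
* ``petox_average_parameters.csv`` — averaged fitted parameters for three
  poly(2-ethyl-2-oxazoline) grades.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .eos import AssociationScheme, BinarySystem, Component
from .fitting import (
    DEFAULT_BOUNDS,
    Bounds,
    FitResult,
    ParamVectorAH,
    SolubilityDataset,
)
from .sle import MeltingProperties, SolubilityPoint

__all__ = [
    "LoadError",
    "RunConfig",
    "load_components",
    "load_melting",
    "load_dataset",
    "write_dataset",
    "write_curve",
    "read_curve",
    "write_fit_result",
    "read_fit_result",
    "packaged_components",
    "packaged_melting",
    "packaged_petox_averages",
    "make_binary_system",
]

CELSIUS_OFFSET = 273.15

_COMPONENT_COLUMNS = [
    "name",
    "Mw",
    "m_over_Mw",
    "sigma",
    "u_kB",
    "eps_assoc_kB",
    "kappa_assoc",
    "n_donor",
    "n_acceptor",
]
_MELTING_COLUMNS = ["name", "Tm_onset_C", "dfusH_kJ_mol"]


class LoadError(ValueError):
    """A CSV/JSON artifact violates its declared schema."""


@dataclass
class RunConfig:
    """Configuration of one CLI run (flags merged over an optional TOML file)."""

    components_path: str | None = None
    melting_path: str | None = None
    dataset_path: str | None = None
    out_path: str | None = None
    seed: int = 0
    kij_mode: str = "fixed"  # fixed | optimize
    k_ij: float = 0.0
    bounds: Bounds = field(default_factory=lambda: DEFAULT_BOUNDS)
    verbosity: int = 0

    def digest(self) -> str:
        """Stable hash of the configuration, for logging."""
        payload = json.dumps(
            {
                "components": self.components_path,
                "melting": self.melting_path,
                "dataset": self.dataset_path,
                "seed": self.seed,
                "kij_mode": self.kij_mode,
                "k_ij": self.k_ij,
                "bounds": [list(self.bounds.low), list(self.bounds.high)],
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise LoadError(f"{path}: empty file") from exc
    if df.empty:
        raise LoadError(f"{path}: no data rows")
    return df


def load_components(path) -> list[Component]:
    """Load validated components from a parameter CSV.

    Association-site counts are read from the donor/acceptor split columns.
    Malformed rows are rejected together, with their (1-based) row numbers.
    """
    df = _read_csv(path)
    missing = [c for c in _COMPONENT_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing columns {missing}")
    comps: list[Component] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            comps.append(
                Component(
                    name=str(row["name"]),
                    Mw=float(row["Mw"]),
                    m_over_Mw=float(row["m_over_Mw"]),
                    sigma=float(row["sigma"]),
                    u_kB=float(row["u_kB"]),
                    assoc=AssociationScheme(
                        n_donor=int(row["n_donor"]),
                        n_acceptor=int(row["n_acceptor"]),
                        eps_assoc_kB=float(row["eps_assoc_kB"]),
                        kappa_assoc=float(row["kappa_assoc"]),
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {int(idx) + 2}: {exc}")
    if errors:
        raise LoadError(f"{path}: " + "; ".join(errors))
    return comps


_CP_EXPR = re.compile(
    r"^\s*([+-]?\d+(?:\.\d+)?)\s*(?:([+-])\s*(\d+(?:\.\d+)?)\s*[*·]?\s*T)?\s*$"
)


def _parse_cp(text: str) -> tuple[float, float]:
    """Parse a heat-capacity expression like ``99.3`` or ``176.2 - 0.3*T``."""
    m = _CP_EXPR.match(str(text))
    if not m:
        raise LoadError(f"cannot parse heat-capacity expression {text!r}")
    a = float(m.group(1))
    b = 0.0
    if m.group(2):
        b = float(m.group(3))
        if m.group(2) == "-":
            b = -b
    return a, b


def load_melting(path) -> dict[str, MeltingProperties]:
    """Load melting properties keyed by component name.

    Temperatures are given in deg C and converted to kelvin here; the
    heat-capacity difference may come as ``dfusCp_a``/``dfusCp_b`` columns or
    as a single ``dfusCp`` expression column (``a``, ``a + b*T``).
    """
    df = _read_csv(path)
    missing = [c for c in _MELTING_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing columns {missing}")
    has_ab = "dfusCp_a" in df.columns
    has_expr = "dfusCp" in df.columns
    if not has_ab and not has_expr:
        raise LoadError(f"{path}: need dfusCp_a/dfusCp_b columns or a dfusCp column")
    out: dict[str, MeltingProperties] = {}
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            if has_ab:
                a = float(row["dfusCp_a"])
                b = float(row.get("dfusCp_b", 0.0)) if "dfusCp_b" in df.columns else 0.0
            else:
                a, b = _parse_cp(row["dfusCp"])
            out[str(row["name"])] = MeltingProperties(
                Tm_onset=float(row["Tm_onset_C"]) + CELSIUS_OFFSET,
                dfusH=float(row["dfusH_kJ_mol"]) * 1e3,
                dfusCp_a=a,
                dfusCp_b=b,
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {int(idx) + 2}: {exc}")
    if errors:
        raise LoadError(f"{path}: " + "; ".join(errors))
    return out


def load_dataset(path) -> SolubilityDataset:
    """Load one (T, w) solubility dataset; the T column declares its unit."""
    df = _read_csv(path)
    if "w_api" not in df.columns:
        raise LoadError(f"{path}: missing column w_api")
    if "T_K" in df.columns:
        T = df["T_K"].astype(float).to_numpy()
    elif "T_C" in df.columns:
        T = df["T_C"].astype(float).to_numpy() + CELSIUS_OFFSET
    else:
        raise LoadError(f"{path}: temperature column must be named T_K or T_C")
    system = str(df["system"].iloc[0]) if "system" in df.columns else Path(str(path)).stem
    return SolubilityDataset(system=system, T=tuple(T), w=tuple(df["w_api"].astype(float)))


def write_dataset(path, dataset: SolubilityDataset) -> None:
    pd.DataFrame(
        {"system": dataset.system, "T_K": dataset.T, "w_api": dataset.w}
    ).to_csv(path, index=False)


def write_curve(path, points: list[SolubilityPoint]) -> None:
    pd.DataFrame(
        {
            "T_K": [p.T for p in points],
            "x_API": [p.x_API for p in points],
            "w_API": [p.w_API for p in points],
            "gamma_API": [p.gamma_API for p in points],
            "converged": [p.converged for p in points],
        }
    ).to_csv(path, index=False)


def read_curve(path) -> list[SolubilityPoint]:
    df = _read_csv(path)
    need = ["T_K", "x_API", "w_API", "gamma_API", "converged"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing columns {missing}")
    return [
        SolubilityPoint(
            T=float(r["T_K"]),
            x_API=float(r["x_API"]),
            w_API=float(r["w_API"]),
            gamma_API=float(r["gamma_API"]),
            converged=bool(r["converged"]),
        )
        for _, r in df.iterrows()
    ]


def write_fit_result(path, result: FitResult) -> None:
    payload = {
        "params": {k: getattr(result.params, k) for k in "ABCDEFGH"},
        "k_ij": result.k_ij,
        "rmsrd": result.rmsrd,
        "w_calc": list(result.w_calc),
        "trace": [[s, i, v] for s, i, v in result.trace],
        "seed": result.seed,
        "converged": result.converged,
        "n_eval": result.n_eval,
        "bounds": {"low": list(result.bounds.low), "high": list(result.bounds.high)},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_fit_result(path) -> FitResult:
    data = json.loads(Path(path).read_text())
    return FitResult(
        params=ParamVectorAH(**data["params"]),
        k_ij=float(data["k_ij"]),
        rmsrd=float(data["rmsrd"]),
        w_calc=tuple(data["w_calc"]),
        trace=tuple((s, int(i), float(v)) for s, i, v in data["trace"]),
        seed=data["seed"],
        converged=bool(data["converged"]),
        n_eval=int(data["n_eval"]),
        bounds=Bounds(
            low=tuple(data["bounds"]["low"]), high=tuple(data["bounds"]["high"])
        ),
    )


def _data_path(filename: str):
    return resources.files("pcsaftsle").joinpath("data", filename)


def packaged_components() -> list[Component]:
    """The published drug/polymer PC-SAFT parameter table shipped in the package."""
    with resources.as_file(_data_path("pcsaft_parameters.csv")) as p:
        return load_components(p)


def packaged_melting() -> dict[str, MeltingProperties]:
    """The packaged melting-property table of the eight drugs."""
    with resources.as_file(_data_path("melting_properties.csv")) as p:
        return load_melting(p)


def packaged_petox_averages() -> pd.DataFrame:
    """Averaged poly(2-ethyl-2-oxazoline) parameters per molecular-weight grade."""
    with resources.as_file(_data_path("petox_average_parameters.csv")) as p:
        return _read_csv(p)


def make_binary_system(
    api_name: str,
    polymer_name: str,
    k_ij: float = 0.0,
    components: list[Component] | None = None,
) -> BinarySystem:
    """Build a binary system from named entries of a component table."""
    comps = components if components is not None else packaged_components()
    by_name = {c.name: c for c in comps}
    try:
        return BinarySystem(by_name[api_name], by_name[polymer_name], k_ij=k_ij)
    except KeyError as exc:
        raise LoadError(
            f"unknown component {exc.args[0]!r}; available: {sorted(by_name)}"
        ) from exc
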