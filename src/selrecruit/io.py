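"""Reading and writing pools, covariate specs, weights and outcomes.

Pools travel as a CSV (one column per covariate, coded values) with a
YAML sidecar describing each covariate's name and kind; weights as a
two-column CSV (id, rho); outcomes as (id, y) for binary and
(id, time, event) for survival.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pools import CovariateSpec, PoolTable
from .recruitment import RecruitmentWeights

__all__ = [
    "read_pool",
    "write_pool",
    "read_spec",
    "write_spec",
    "read_weights",
    "write_weights",
    "write_binary_outcomes",
    "write_survival_outcomes",
]


def write_spec(specs: list[CovariateSpec], path) -> None:
    entries = []
    for s in specs:
        entry: dict = {"name": s.name, "kind": s.kind}
        if s.coding:
            entry["coding"] = s.coding
        if s.q05_anchor is not None:
            entry["q05_anchor"] = float(s.q05_anchor)
        if s.q95_anchor is not None:
            entry["q95_anchor"] = float(s.q95_anchor)
        entries.append(entry)
    Path(path).write_text(yaml.safe_dump({"covariates": entries}, sort_keys=False))


def read_spec(path) -> list[CovariateSpec]:
    data = yaml.safe_load(Path(path).read_text())
    return [
        CovariateSpec(
            name=e["name"],
            kind=e["kind"],
            coding=e.get("coding"),
            q05_anchor=e.get("q05_anchor"),
            q95_anchor=e.get("q95_anchor"),
        )
        for e in data["covariates"]
    ]


def write_pool(pool: PoolTable, csv_path, spec_path=None) -> None:
    df = pool.covariates.copy()
    df.insert(0, "id", pool.ids)
    df.to_csv(csv_path, index=False)
    if spec_path is not None:
        write_spec(pool.specs, spec_path)


def read_pool(csv_path, spec_path) -> PoolTable:
    df = pd.read_csv(csv_path)
    ids = df.pop("id").to_numpy() if "id" in df.columns else None
    specs = read_spec(spec_path)
    return PoolTable(df[[s.name for s in specs]], specs, ids=ids)


def write_weights(weights: RecruitmentWeights, ids, path) -> None:
    pd.DataFrame({"id": np.asarray(ids), "rho": weights.rho}).to_csv(path, index=False)


def read_weights(path, protocol: str = "loaded") -> tuple[np.ndarray, RecruitmentWeights]:
    df = pd.read_csv(path)
    rho = df["rho"].to_numpy(dtype=float)
    return df["id"].to_numpy(), RecruitmentWeights(
        rho=rho / rho.sum(), c=float(rho.sum()), protocol=protocol
    )


def write_binary_outcomes(ids, y, path) -> None:
    pd.DataFrame({"id": np.asarray(ids), "y": np.asarray(y)}).to_csv(path, index=False)


def write_survival_outcomes(ids, times, events, path) -> None:
    pd.DataFrame(
        {"id": np.asarray(ids), "time": np.asarray(times), "event": np.asarray(events)}
    ).to_csv(path, index=False)
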