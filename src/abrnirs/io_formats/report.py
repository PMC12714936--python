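"""Result tables: validated containers plus CSV/JSON persistence."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["ResultTable", "write_report", "read_report"]

_P_COLUMNS = ("p_raw", "p_corrected", "p_value", "p_fdr")


@dataclass
class ResultTable:
    """A named statistics table with stable row order.

    Any column whose name starts with ``p_`` must hold probabilities in
    [0, 1]; a ``significant`` column, when present alongside a corrected
    p column, must equal ``p < alpha``.
    """

    name: str
    table: pd.DataFrame
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for col in self.table.columns:
            if col in _P_COLUMNS or col.startswith("p_"):
                vals = self.table[col].dropna()
                if ((vals < 0) | (vals > 1)).any():
                    raise ValueError(f"column {col!r} outside [0, 1]")
        corrected = next(
            (c for c in ("p_corrected", "p_fdr") if c in self.table.columns), None
        )
        if corrected and "significant" in self.table.columns:
            expect = self.table[corrected] < self.alpha
            if not (self.table["significant"].astype(bool) == expect).all():
                raise ValueError("significant flags inconsistent with corrected p")


def write_report(tables: list[ResultTable], path: str | Path) -> list[Path]:
    """Write one CSV per table plus a JSON bundle under directory ``path``."""
    if not tables:
        raise ValueError("no tables to write")
    out_dir = Path(path)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    bundle = {}
    for t in tables:
        csv_path = out_dir / f"{t.name}.csv"
        t.table.to_csv(csv_path, index=False)
        written.append(csv_path)
        bundle[t.name] = {
            "alpha": t.alpha,
            "columns": list(t.table.columns),
            "rows": json.loads(t.table.to_json(orient="records")),
        }
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(bundle, indent=2))
    written.append(json_path)
    return written


def read_report(path: str | Path) -> list[ResultTable]:
    """Read back a report bundle written by :func:`write_report`."""
    bundle = json.loads((Path(path) / "report.json").read_text())
    tables = []
    for name, spec in bundle.items():
        df = pd.DataFrame(spec["rows"], columns=spec["columns"])
        tables.append(ResultTable(name, df, alpha=spec["alpha"]))
    return tables
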