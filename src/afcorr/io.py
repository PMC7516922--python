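"""Reading paired data, suite configs, and writing measure reports."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .measures import PairedSample
from .simulate import MEASURES, NoiseSpec, RelationshipSpec
from .transform import SmootherSpec

__all__ = ["MeasureReport", "read_pairs", "load_suite_config", "suite_cells"]

logger = logging.getLogger("afcorr")


@dataclass
class MeasureReport:
    """Computed measure values plus the provenance needed to rerun them."""

    values: dict
    source: str
    seed: int | None
    smoother: SmootherSpec
    version: str

    def to_dict(self) -> dict:
        return {
            "values": {k: float(v) for k, v in self.values.items()},
            "provenance": {
                "source": self.source,
                "seed": self.seed,
                "smoother": {
                    "method": self.smoother.method,
                    "span": self.smoother.span,
                    "min_neighbors": self.smoother.min_neighbors,
                },
                "version": self.version,
            },
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "measure": k,
                "value": float(f"{v:.12g}"),
                "value_2dp": round(float(v), 2),
            }
            for k, v in self.values.items()
        ]
        return pd.DataFrame(rows)


def read_pairs(
    path: str | Path,
    format: str | None = None,
    x_column: str | int = 0,
    y_column: str | int = 1,
    header: bool | None = None,
) -> PairedSample:
    """Read two numeric columns from a CSV/TSV file into a paired sample.

    Rows with a missing value in either column are dropped (the count is
    logged); a cell that is present but not numeric is a hard error naming
    the row.  Columns may be addressed by name (requires a header) or by
    zero-based index.

    Raises
    ------
    ValueError
        On an unparseable numeric cell, a missing column, or fewer than 4
        complete rows.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    sep = "\t" if format == "tsv" else ","
    by_name = isinstance(x_column, str) or isinstance(y_column, str)
    if header is None:
        header = by_name
    df = pd.read_csv(path, sep=sep, header=0 if header else None, dtype=str)
    df.columns = [str(c) for c in df.columns] if header else list(range(df.shape[1]))

    def pick(col):
        if isinstance(col, str):
            if col not in df.columns:
                raise ValueError(f"column {col!r} not found in {path.name}")
            return df[col]
        if col >= df.shape[1]:
            raise ValueError(f"column index {col} out of range for {path.name}")
        return df.iloc[:, col]

    raw_x, raw_y = pick(x_column), pick(y_column)

    def parse(raw, label):
        out = np.empty(len(raw))
        for i, cell in enumerate(raw):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or (
                isinstance(cell, str) and cell.strip() == ""
            ):
                out[i] = np.nan
                continue
            try:
                out[i] = float(cell)
            except (TypeError, ValueError):
                row = i + (2 if header else 1)  # 1-based, counting the header
                raise ValueError(
                    f"unparseable numeric cell {cell!r} in column {label} "
                    f"at row {row} of {path.name}"
                ) from None
        return out

    x = parse(raw_x, str(x_column))
    y = parse(raw_y, str(y_column))
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = int(np.sum(~keep))
    if dropped:
        logger.info("dropped %d incomplete row(s) from %s", dropped, path.name)
    if keep.sum() < 4:
        raise ValueError(
            f"fewer than 4 usable rows in {path.name} ({int(keep.sum())} found)"
        )
    return PairedSample(x[keep], y[keep])


def load_suite_config(path: str | Path) -> dict:
    """Load and validate a JSON suite configuration.

    Schema::

        {
          "n": 100,                       # optional, default 100
          "T": 100,                       # optional, default 100
          "x_design": "even_grid",        # optional
          "relationships": ["linear", ...],
          "noise_levels": ["none", "low", "moderate", "high"],
          "noise_family": "gaussian",     # optional
          "measures": ["pearson_abs", "dcor", "af_xy"]
        }
    """
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("suite config must be a JSON object")
    cfg.setdefault("n", 100)
    cfg.setdefault("T", 100)
    cfg.setdefault("x_design", "even_grid")
    cfg.setdefault("noise_family", "gaussian")
    cfg.setdefault("noise_levels", ["none", "low", "moderate", "high"])
    cfg.setdefault("measures", ["pearson_abs", "dcor", "af_xy"])
    cfg.setdefault("relationships", ["linear", "poly4", "exponential", "parabolic"])
    unknown = [m for m in cfg["measures"] if m not in MEASURES]
    if unknown:
        raise ValueError(f"unknown measures in config: {unknown}")
    for lv in cfg["noise_levels"]:
        if lv not in ("none", "low", "moderate", "high"):
            raise ValueError(f"unknown noise level {lv!r}")
    return cfg


def suite_cells(cfg: dict):
    """Expand a validated suite config into (RelationshipSpec, NoiseSpec) cells."""
    cells = []
    for rel in cfg["relationships"]:
        for lv in cfg["noise_levels"]:
            family = "none" if lv == "none" else cfg["noise_family"]
            cells.append(
                (
                    RelationshipSpec(rel, n=int(cfg["n"]), x_design=cfg["x_design"]),
                    NoiseSpec(family=family, level=lv),
                )
            )
    return cells
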