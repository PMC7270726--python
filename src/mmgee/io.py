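"""Reading long-format data, model/contrast configuration, and reports.

Input data are delimited text with a header row: one observation per
line with a cluster id column, response columns, covariate columns and
an optional weight column.  Missing values (empty fields or an NA
token) are dropped per model, so an endpoint missing for a subject
simply contributes a zero score there.  Categorical covariates are
expanded to indicator columns against the first observed level.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gee import GEEModelSpec
from .inference import ContrastHypothesis

__all__ = [
    "read_long_table",
    "load_config",
    "build_model_specs",
    "build_contrast",
    "write_json_report",
]

_NA_TOKENS = ["", "NA", "NaN", "nan", "."]


def read_long_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited text table, sniffing the separator if not given."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, na_values=_NA_TOKENS, keep_default_na=True)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _expand_categoricals(data: pd.DataFrame, covariates: list[str]):
    """Replace non-numeric covariate columns by 0/1 indicators, reference
    level = first observed."""
    out = data.copy()
    cols: list[str] = []
    for c in covariates:
        if c not in out.columns:
            raise KeyError(f"covariate column {c!r} not found in input data")
        if pd.api.types.is_numeric_dtype(out[c]):
            cols.append(c)
            continue
        levels = list(pd.unique(out[c].dropna()))
        for lev in levels[1:]:
            name = f"{c}[{lev}]"
            out[name] = (out[c] == lev).astype(float)
            out.loc[out[c].isna(), name] = np.nan
            cols.append(name)
    return out, cols


def build_model_specs(data: pd.DataFrame, config: dict) -> list[GEEModelSpec]:
    """Build one GEEModelSpec per entry of config['models']."""
    id_col = config.get("id_col", "id")
    weight_col = config.get("weight_col")
    specs = []
    for mc in config["models"]:
        expanded, cols = _expand_categoricals(data, list(mc["covariates"]))
        specs.append(
            GEEModelSpec.from_dataframe(
                expanded,
                response=mc["response"],
                covariates=cols,
                family=mc.get("family", "gaussian"),
                working_correlation=mc.get("working_correlation", "independence"),
                id_col=id_col,
                weight_col=weight_col,
                intercept=mc.get("intercept", True),
                name=mc.get("name", mc["response"]),
                scale_divisor=mc.get("scale_divisor", "n-p"),
            )
        )
    return specs


def build_contrast(config: dict, total_params: int) -> ContrastHypothesis:
    """Contrast from config: either 'matrix' (list of stacked rows) or
    'file' (delimited matrix text), plus optional 'rhs'."""
    cc = config["contrast"]
    if "matrix" in cc:
        L = np.asarray(cc["matrix"], dtype=float)
    elif "file" in cc:
        L = np.loadtxt(cc["file"], delimiter=cc.get("sep", ","), ndmin=2)
    else:
        raise KeyError("contrast config needs 'matrix' or 'file'")
    if L.shape[1] != total_params:
        raise ValueError(
            f"contrast has {L.shape[1]} columns but the stacked coefficient "
            f"vector has {total_params} entries"
        )
    r = np.asarray(cc.get("rhs", np.zeros(L.shape[0])), dtype=float)
    return ContrastHypothesis(L=L, r=r, row_names=cc.get("row_names"))


def write_json_report(obj: dict, path: str | Path | None) -> str:
    """Serialize a report dict to JSON (file or string)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.reset_index().to_dict(orient="records")
        raise TypeError(f"not JSON serializable: {type(o)}")

    text = json.dumps(obj, indent=2, default=default)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
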