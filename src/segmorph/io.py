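"""Reading and writing the pipeline's tabular formats.

The canonical measurement table is tidy CSV with columns
``species, larva_id, segment, x_anterior_um, x_posterior_um,
body_length_um`` (one row per larva and abdominal segment).  Deposited
tables with one row per larva and paired anterior/posterior columns per
segment are converted on load.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .exceptions import DataError
from .simulate import SEGMENTS

TIDY_COLUMNS = ["species", "larva_id", "segment", "x_anterior_um", "x_posterior_um", "body_length_um"]


def load_measurements(path):
    """Load a measurement table (tidy or wide per-larva layout) as tidy CSV."""
    df = pd.read_csv(path)
    if set(TIDY_COLUMNS) <= set(df.columns):
        return df[TIDY_COLUMNS]
    return _wide_to_tidy(df)


def _wide_to_tidy(df):
    cols = {c.lower().strip(): c for c in df.columns}

    def find(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None

    sp = find("species", "sp")
    lid = find("larva_id", "larva", "id", "sample")
    length = find("body_length_um", "body_length", "length", "y", "total_length")
    if sp is None or length is None:
        raise DataError(
            "cannot interpret measurement table: need either the tidy layout "
            f"({TIDY_COLUMNS}) or per-larva columns with species and body length"
        )
    rows = []
    for i, rec in df.iterrows():
        larva = rec[lid] if lid else f"larva_{i:05d}"
        for k, seg in enumerate(SEGMENTS, start=1):
            ant = find(f"a{k}_anterior", f"a{k}_ant", f"x{k}", f"a{k}", seg.lower())
            post = find(f"a{k}_posterior", f"a{k}_post", f"xp{k}")
            if ant is None:
                raise DataError(f"no anterior-border column found for segment {seg}")
            x_ant = float(rec[ant])
            # fractions are converted to micrometers via body length
            L = float(rec[length])
            if x_ant < 1.5:
                x_ant *= L
            if post is not None:
                x_post = float(rec[post])
                if x_post < 1.5:
                    x_post *= L
            else:
                x_post = np.nan
            rows.append((rec[sp], larva, seg, x_ant, x_post, L))
    return pd.DataFrame(rows, columns=TIDY_COLUMNS)


def write_measurements(df, path):
    df[TIDY_COLUMNS].to_csv(path, index=False)


def load_trait_means(path):
    """Species x segment CSV (first column species, columns A1..A8)."""
    df = pd.read_csv(path, index_col=0)
    segs = [s for s in SEGMENTS if s in df.columns]
    if not segs:
        raise DataError("trait table has no segment columns (A1..A8)")
    return df[segs]


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
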