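"""File I/O: cohort/ROI CSVs, YAML configs, JSON results, digests.

All tabular outputs are UTF-8 CSV/TSV with explicit header rows and missing
values as empty fields, so that write -> read -> write round-trips
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import GeneratorConfig, NULLIPAROUS_CATEGORY, TSLB_CATEGORIES
from .synthetic import SUBTYPES

__all__ = ["write_cohort", "read_cohort", "write_rois", "read_rois",
           "write_yaml", "read_yaml", "write_json", "file_digest"]

_BOOL_COLS = ("parous", "breastfed", "fam_hx")


def write_cohort(cohort: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = cohort.copy()
    for c in _BOOL_COLS:
        out[c] = out[c].map({True: "true", False: "false"})
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for c in _BOOL_COLS:
        # the CSV reader may or may not have parsed "true"/"false" already
        df[c] = df[c].map({"true": True, "false": False,
                           True: True, False: False}).astype(bool)
    df["tslb_cat"] = pd.Categorical(
        df["tslb_cat"], categories=list(TSLB_CATEGORIES) + [NULLIPAROUS_CATEGORY],
        ordered=True,
    )
    df["subtype"] = pd.Categorical(df["subtype"], categories=SUBTYPES)
    df["menopause"] = pd.Categorical(df["menopause"],
                                     categories=("no", "not sure", "yes"))
    return df


def write_rois(rois: pd.DataFrame, path) -> Path:
    path = Path(path)
    rois.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")
    return path


def read_rois(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_yaml(obj: dict, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(obj, sort_keys=True), encoding="utf-8")
    return path


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text(encoding="utf-8"))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n",
                    encoding="utf-8")
    return path


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_generator_sidecar(config: GeneratorConfig, path) -> Path:
    """YAML sidecar recording every generator parameter and the seed."""
    return write_yaml(config.to_dict(), path)
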