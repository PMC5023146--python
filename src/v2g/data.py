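"""Packaged cohort tables (16 repaired-TOF patients) and their loader.

The CSV fixtures transcribe the published per-patient tables of the cohort:

* ``table1`` -- demographics and pre/post-PVR CMR volumes / ejection fraction.
* ``table2`` -- per-patient wall-averaged stresses (kPa) from the 1G and 2G
  models at the four landmark states (BF, EF, BE, EE).
* ``table3`` -- the corresponding strains.
* ``table4`` -- cohort-level wall thickness / curvature aggregates.
* ``table6`` -- per-patient begin-ejection metrics plus the outcome group
  (1 = better, 2 = worse post-PVR EF response).

``printed_aggregates`` holds the tables' printed summary rows (means, SDs and
correlation rows) exactly as published -- including the demographics table's
internally inconsistent overall dEF mean, which is transcribed, flagged and
not corrected.  Files are checksum-verified on load.
"""

from __future__ import annotations

import hashlib
import io
import json
from importlib import resources

import pandas as pd

from .errors import V2GError

FIXTURES = ("table1", "table2", "table3", "table4", "table6")
_INDEX_COL = {"table1": "patient", "table2": "patient", "table3": "patient",
              "table4": "metric", "table6": "patient"}


def _read_bytes(filename: str) -> bytes:
    ref = resources.files("v2g").joinpath("_fixture_data").joinpath(filename)
    return ref.read_bytes()


def _manifest() -> dict:
    return json.loads(_read_bytes("manifest.json"))


def _verified_bytes(filename: str) -> bytes:
    raw = _read_bytes(filename)
    expected = _manifest().get(filename)
    if expected is None:
        raise V2GError(f"{filename} missing from fixture manifest")
    got = hashlib.sha256(raw).hexdigest()
    if got != expected:
        raise V2GError(f"fixture {filename} corrupted "
                       f"(sha256 {got[:12]}... != {expected[:12]}...)")
    return raw


def load_fixture(name: str) -> pd.DataFrame:
    """Load one packaged table as a typed DataFrame (checksum-verified)."""
    if name not in FIXTURES:
        raise V2GError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    raw = _verified_bytes(f"{name}.csv")
    df = pd.read_csv(io.BytesIO(raw))
    return df.set_index(_INDEX_COL[name])


def printed_aggregates() -> dict:
    """The tables' printed summary rows (means, SDs, correlations)."""
    return json.loads(_verified_bytes("printed_aggregates.json"))


def cohort_table() -> pd.DataFrame:
    """Table-6-style per-patient begin-ejection cohort table."""
    return load_fixture("table6")


def predictor_matrix() -> pd.DataFrame:
    """The fixture-derived 8-predictor matrix plus outcome group.

    Stress phase columns come from the per-patient 2G stresses (table2);
    geometry and volume come from the begin-ejection table (table6).
    """
    from .prediction import build_predictors

    t2 = load_fixture("table2")
    t6 = load_fixture("table6")
    geom = t6.rename(columns={"EDV": "EDV"})[["WT", "C-cur", "L-cur", "EDV",
                                              "group"]]
    return build_predictors(t2, geom)
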