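"""Tidy-CSV readers/writers and JSON report serialization.

Cohort CSV schema (long layout): ``individual_id, time_min, glucose_mmol_l,
insulin_mu_l``.  Individuals with an incomplete set of glucose and/or
insulin measurements at the canonical five time points are excluded (and
counted); duplicate (id, time) rows are an error.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import OGTT_TIMES, OgttResponse

__all__ = ["read_ogtt_csv", "write_ogtt_csv", "write_report", "read_report", "REPORT_SCHEMA_VERSION"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"
_COLUMNS = ("individual_id", "time_min", "glucose_mmol_l", "insulin_mu_l")


def read_ogtt_csv(path: str | Path, times=OGTT_TIMES) -> list[OgttResponse]:
    """Read a tidy OGTT cohort CSV; return complete five-point responses.

    Incomplete individuals are excluded with a logged count.  Malformed rows
    (non-numeric, missing columns) and duplicate (id, time) pairs raise.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        logger.warning("%s: empty cohort file", path)
        return []
    for col in ("time_min", "glucose_mmol_l", "insulin_mu_l"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()].tolist()
        if bad:
            lines = [i + 2 for i in bad]  # header + 1-based
            raise ValueError(f"{path}: malformed {col} values at lines {lines[:10]}")
        df[col] = vals
    dup = df.duplicated(subset=["individual_id", "time_min"], keep=False)
    if dup.any():
        lines = [i + 2 for i in df.index[dup].tolist()]
        raise ValueError(f"{path}: duplicate (individual_id, time_min) rows at lines {lines[:10]}")

    want = np.asarray(times, dtype=float)
    out: list[OgttResponse] = []
    excluded = 0
    for iid, grp in df.groupby("individual_id", sort=True):
        grp = grp.sort_values("time_min")
        t = grp["time_min"].to_numpy(dtype=float)
        complete = (
            len(t) == len(want)
            and np.allclose(t, want)
            and grp[["glucose_mmol_l", "insulin_mu_l"]].notna().all().all()
        )
        if not complete:
            excluded += 1
            continue
        out.append(
            OgttResponse.from_arrays(
                iid, t, grp["glucose_mmol_l"].to_numpy(), grp["insulin_mu_l"].to_numpy()
            )
        )
    if excluded:
        logger.info("%s: excluded %d incomplete individual(s)", path, excluded)
    read_ogtt_csv.last_excluded = excluded  # inspectable exclusion count
    return out


read_ogtt_csv.last_excluded = 0


def write_ogtt_csv(responses: list[OgttResponse], path: str | Path) -> None:
    rows = []
    for r in responses:
        for t, g, i in zip(r.times, r.glucose, r.insulin):
            rows.append(
                {
                    "individual_id": r.individual_id,
                    "time_min": t,
                    "glucose_mmol_l": g,
                    "insulin_mu_l": i,
                }
            )
    pd.DataFrame(rows, columns=list(_COLUMNS)).to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return super().default(o)


def write_report(report: dict, path: str | Path) -> None:
    """JSON report with a stamped schema version; round-trips via
    :func:`read_report`."""
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **report}
    Path(path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder, allow_nan=True))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
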