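"""File formats: long-format cohort CSV, theta JSON, trace JSON-lines.

The canonical cohort table is long format, one row per measurement slot:

    subject_id, baseline_age, time, marker, value, label, conversion_time, role

``role`` is ``observed`` (value present) or ``candidate`` (value empty).
CSV dialect: RFC 4180, UTF-8, '.' decimal separator.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .decision import SequentialTrace
from .model import (
    MarkerCatalog,
    MarkerModelParams,
    MeasurementSlot,
    ModelTheta,
    Observation,
    PrevalenceParams,
    SubjectRecord,
    default_catalog,
)

__all__ = [
    "LONG_COLUMNS",
    "read_long_table",
    "write_long_table",
    "records_to_frame",
    "records_from_frame",
    "theta_to_json",
    "theta_from_json",
    "write_traces_jsonl",
]

LONG_COLUMNS = (
    "subject_id",
    "baseline_age",
    "time",
    "marker",
    "value",
    "label",
    "conversion_time",
    "role",
)


class ParseError(ValueError):
    """Row-addressed validation error for the long table."""


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        common = {
            "subject_id": r.subject_id,
            "baseline_age": r.baseline_age,
            "label": r.label,
            "conversion_time": r.conversion_time,
        }
        for o in r.observations:
            rows.append(
                dict(common, time=o.slot.time, marker=o.slot.marker,
                     value=o.value, role="observed")
            )
        for s in r.candidates:
            rows.append(
                dict(common, time=s.time, marker=s.marker, value=np.nan,
                     role="candidate")
            )
    frame = pd.DataFrame(rows, columns=list(LONG_COLUMNS))
    return frame.sort_values(["subject_id", "time", "marker"]).reset_index(drop=True)


def write_long_table(records: Sequence[SubjectRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def records_from_frame(
    frame: pd.DataFrame, catalog: Optional[MarkerCatalog] = None
) -> list[SubjectRecord]:
    catalog = catalog or default_catalog()
    if tuple(frame.columns) != LONG_COLUMNS:
        raise ParseError(
            f"header must be exactly {list(LONG_COLUMNS)}, got {list(frame.columns)}"
        )
    records = []
    order = {m: j for j, m in enumerate(catalog)}
    for sid, grp in frame.groupby("subject_id", sort=True):
        grp = grp.sort_values(
            ["time", "marker"],
            key=lambda col: col.map(order) if col.name == "marker" else col,
        )
        ages = grp["baseline_age"].unique()
        if len(ages) != 1:
            raise ParseError(f"subject {sid}: inconsistent baseline_age values")
        labels = grp["label"].dropna().unique()
        if len(labels) > 1:
            raise ParseError(f"subject {sid}: inconsistent labels")
        label = int(labels[0]) if len(labels) else None
        conv = grp["conversion_time"].dropna().unique()
        conv_time = float(conv[0]) if len(conv) else None
        observations, candidates = [], []
        seen = set()
        for row in grp.itertuples():
            if row.marker not in catalog:
                raise ParseError(
                    f"row {row.Index}: unknown marker {row.marker!r} "
                    f"(catalog: {list(catalog)})"
                )
            key = (row.marker, float(row.time), row.role)
            if key in seen:
                raise ParseError(
                    f"row {row.Index}: duplicate slot {key} for subject {sid}"
                )
            seen.add(key)
            slot = MeasurementSlot(time=float(row.time), marker=row.marker)
            if row.role == "observed":
                if not np.isfinite(row.value):
                    raise ParseError(
                        f"row {row.Index}: non-finite value for observed slot "
                        f"({row.marker}, t={row.time}) of subject {sid}"
                    )
                observations.append(Observation(slot=slot, value=float(row.value)))
            elif row.role == "candidate":
                candidates.append(slot)
            else:
                raise ParseError(
                    f"row {row.Index}: role must be 'observed' or 'candidate', "
                    f"got {row.role!r}"
                )
        records.append(
            SubjectRecord(
                subject_id=str(sid),
                baseline_age=float(ages[0]),
                label=label,
                conversion_time=conv_time,
                observations=observations,
                candidates=candidates,
            )
        )
    return records


def read_long_table(path, catalog: Optional[MarkerCatalog] = None) -> list[SubjectRecord]:
    frame = pd.read_csv(
        path, dtype={"subject_id": str}, float_precision="round_trip"
    )
    return records_from_frame(frame, catalog=catalog)


# ---------------------------------------------------------------------------
# theta JSON


def theta_to_json(theta: ModelTheta, path=None) -> str:
    """Serialize theta to JSON (lossless round trip).

    ``psi`` is stored both as the full matrix and as its Cholesky factor
    for audit; the matrix is authoritative on read.
    """
    mk = theta.markers
    psi = np.asarray(mk.psi)
    try:
        chol = np.linalg.cholesky(psi + 1e-12 * np.eye(psi.shape[0])).tolist()
    except np.linalg.LinAlgError:
        chol = None
    payload = {
        "catalog": list(theta.catalog.markers),
        "prevalence": {
            "lambda0": theta.prevalence.lambda0,
            "lambda1": theta.prevalence.lambda1,
        },
        "beta": mk.beta.tolist(),
        "psi": psi.tolist(),
        "psi_cholesky": chol,
        "rho": mk.rho.tolist(),
        "psi_by_class": None if mk.psi_by_class is None else mk.psi_by_class.tolist(),
        "rho_by_class": None if mk.rho_by_class is None else mk.rho_by_class.tolist(),
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def theta_from_json(source) -> ModelTheta:
    """Read theta back; ``source`` is a path or a JSON string."""
    if isinstance(source, str) and source.lstrip().startswith("{"):
        payload = json.loads(source)
    else:
        with open(source, encoding="utf-8") as fh:
            payload = json.load(fh)
    catalog = MarkerCatalog(markers=tuple(payload["catalog"]))
    mk = MarkerModelParams(
        beta=np.array(payload["beta"]),
        psi=np.array(payload["psi"]),
        rho=np.array(payload["rho"]),
        psi_by_class=(
            None if payload.get("psi_by_class") is None
            else np.array(payload["psi_by_class"])
        ),
        rho_by_class=(
            None if payload.get("rho_by_class") is None
            else np.array(payload["rho_by_class"])
        ),
    )
    prev = PrevalenceParams(**payload["prevalence"])
    return ModelTheta(prevalence=prev, markers=mk, catalog=catalog)


def write_traces_jsonl(traces: Sequence[SequentialTrace], path) -> None:
    """One JSON object per step per line, for audit."""
    with open(path, "w", encoding="utf-8") as fh:
        for tr in traces:
            for row in tr.to_step_dicts():
                fh.write(json.dumps(row) + "\n")
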