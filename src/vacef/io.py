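"""Tabular I/O: beat tables in, per-beat results and agreement summaries out.

Beat tables are delimited text (comma by default, delimiter sniffed or
overridden) with the header

    id, pep_ms, et_ms, sbp_mmhg, dbp_mmhg [, ef_echo_percent]

Unit suffixes in column names make the file convention explicit: times in ms,
pressures in mmHg, ejection fractions in percent.  Internally all fractions
are kept in (0, 1); conversion happens only here.  Unknown columns are
preserved and passed through to the result table.

Result tables carry one output row per input row, in order; rows that fail
validation or solving are flagged with an error code, never dropped.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .agreement import AgreementReport, PairedMeasurements, bland_altman
from .coupling import (
    BeatRecord,
    CouplingConstants,
    SolverSettings,
    beat_to_ef,
)
from .errors import (
    InvalidInputError,
    NonConvergenceError,
    NoSolutionError,
    SchemaError,
)

__all__ = [
    "BeatTable",
    "REQUIRED_COLUMNS",
    "read_beat_table",
    "compute_results",
    "write_result_table",
    "write_agreement_report",
    "run_compute",
]

REQUIRED_COLUMNS = ("id", "pep_ms", "et_ms", "sbp_mmhg", "dbp_mmhg")
ECHO_COLUMN = "ef_echo_percent"

# plausibility bands enforced (as row warnings) unless range checking is off
_PEP_RANGE = (20.0, 400.0)
_ET_RANGE = (100.0, 600.0)


@dataclass
class BeatTable:
    """Validated beat table: parsed rows plus per-row validation issues."""

    frame: pd.DataFrame
    issues: dict[int, str] = field(default_factory=dict)  # row index -> message

    def __len__(self) -> int:
        return len(self.frame)


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text().splitlines()[0] if path.stat().st_size else ""
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_beat_table(path: str | Path, delimiter: str | None = None) -> BeatTable:
    """Read and validate a beat table.

    Raises :class:`SchemaError` for an empty file or missing required columns.
    Row-level problems (non-positive times, inverted pressures, unparseable
    numbers) are collected in ``issues`` keyed by row position; valid rows are
    unaffected.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    if path.stat().st_size == 0:
        raise SchemaError(f"empty input file: {path}")
    sep = delimiter or _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, dtype={"id": str}, skipinitialspace=True)
    frame.columns = [str(c).strip() for c in frame.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s) {missing}; expected header "
            f"{list(REQUIRED_COLUMNS)} (optionally {ECHO_COLUMN})"
        )
    issues: dict[int, str] = {}
    for i, row in frame.iterrows():
        try:
            BeatRecord(
                pep=float(row["pep_ms"]),
                et=float(row["et_ms"]),
                sbp=float(row["sbp_mmhg"]),
                dbp=float(row["dbp_mmhg"]),
                id=str(row["id"]),
            )
        except (InvalidInputError, ValueError, TypeError) as exc:
            issues[i] = str(exc)
    return BeatTable(frame=frame, issues=issues)


def _range_warnings(pep: float, et: float) -> list[str]:
    out = []
    if not _PEP_RANGE[0] <= pep <= _PEP_RANGE[1]:
        out.append(f"pep {pep:g} ms outside plausible range {_PEP_RANGE}")
    if not _ET_RANGE[0] <= et <= _ET_RANGE[1]:
        out.append(f"et {et:g} ms outside plausible range {_ET_RANGE}")
    return out


def compute_results(
    table: BeatTable,
    constants: CouplingConstants = CouplingConstants(),
    settings: SolverSettings = SolverSettings(),
    check_ranges: bool = True,
) -> pd.DataFrame:
    """Run the coupling pipeline on every valid row of a beat table.

    Returns a result frame with one row per input row (order preserved).
    Failed rows have NaN numeric fields, ``converged`` False and the failure
    reason in ``warnings``.  Unknown input columns are appended unchanged.
    """
    records = []
    for i, row in table.frame.iterrows():
        base = {"id": row["id"]}
        if i in table.issues:
            records.append(
                {**base, "pes_mmhg": math.nan, "ees_over_ea": math.nan, "k": math.nan,
                 "pmax_mmhg": math.nan, "eff_percent": math.nan, "ef_eff_percent": math.nan,
                 "converged": False, "warnings": f"invalid-input: {table.issues[i]}"}
            )
            continue
        beat = BeatRecord(
            pep=float(row["pep_ms"]), et=float(row["et_ms"]),
            sbp=float(row["sbp_mmhg"]), dbp=float(row["dbp_mmhg"]), id=str(row["id"]),
        )
        warns = _range_warnings(beat.pep, beat.et) if check_ranges else []
        try:
            est = beat_to_ef(beat, constants, settings)
        except (NoSolutionError, NonConvergenceError) as exc:
            records.append(
                {**base, "pes_mmhg": math.nan, "ees_over_ea": math.nan, "k": math.nan,
                 "pmax_mmhg": math.nan, "eff_percent": math.nan, "ef_eff_percent": math.nan,
                 "converged": False,
                 "warnings": "; ".join([f"{type(exc).__name__}: {exc}"] + warns)}
            )
            continue
        records.append(
            {**base, "pes_mmhg": est.pes, "ees_over_ea": est.ees_over_ea, "k": est.k,
             "pmax_mmhg": est.pmax, "eff_percent": 100.0 * est.eff,
             "ef_eff_percent": 100.0 * est.ef, "converged": est.converged,
             "warnings": "; ".join(list(est.warnings) + warns)}
        )
    result = pd.DataFrame.from_records(records)
    passthrough = [c for c in table.frame.columns if c not in REQUIRED_COLUMNS]
    for c in passthrough:
        result[c] = table.frame[c].values
    return result


def write_result_table(frame: pd.DataFrame, path: str | Path, sig_digits: int = 6) -> None:
    """Write a result table as CSV, floats at ``sig_digits`` significant digits."""
    frame.to_csv(path, index=False, float_format=f"%.{sig_digits}g")


def write_agreement_report(report: AgreementReport, path: str | Path) -> None:
    """Serialize an agreement report as JSON (NaN written as null)."""
    payload = {
        k: (None if isinstance(v, float) and math.isnan(v) else v)
        for k, v in report.to_dict().items()
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def run_compute(
    input_path: str | Path,
    output_path: str | Path,
    constants: CouplingConstants = CouplingConstants(),
    settings: SolverSettings = SolverSettings(),
    delimiter: str | None = None,
    loa_multiplier: float = 2.0,
    check_ranges: bool = True,
) -> dict:
    """End-to-end batch run: read beats, compute EF, write results.

    If the input carries an ``ef_echo_percent`` column, a Bland-Altman report
    comparing it with the computed EF (echo as reference) is written next to
    the output as ``<output stem>.agreement.json``.

    Returns a summary dict with row counts (total/converged/warned/failed) and
    the agreement report if one was produced.
    """
    output_path = Path(output_path)
    # fail before computing if the destination is unwritable
    output_path.parent.mkdir(parents=True, exist_ok=True)
    output_path.touch()

    table = read_beat_table(input_path, delimiter=delimiter)
    result = compute_results(table, constants, settings, check_ranges=check_ranges)
    write_result_table(result, output_path)

    summary = {
        "rows": len(result),
        "converged": int(result["converged"].sum()),
        "warned": int((result["warnings"].fillna("") != "").sum()),
        "failed": int((~result["converged"]).sum()),
        "output": str(output_path),
    }
    if ECHO_COLUMN in table.frame.columns:
        ok = result["converged"].to_numpy() & ~table.frame[ECHO_COLUMN].isna().to_numpy()
        if ok.sum() >= 3:
            pairs = PairedMeasurements(
                reference=table.frame.loc[ok, ECHO_COLUMN].to_numpy(float),
                test=result.loc[ok, "ef_eff_percent"].to_numpy(float),
            )
            report = bland_altman(pairs, multiplier=loa_multiplier)
            agree_path = output_path.with_suffix(".agreement.json")
            write_agreement_report(report, agree_path)
            summary["agreement"] = report.to_dict()
            summary["agreement_output"] = str(agree_path)
    return summary


def cohort_to_frames(subjects) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a synthetic cohort into a beat table and a ground-truth table."""
    beats = pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "pep_ms": [s.beat.pep for s in subjects],
            "et_ms": [s.beat.et for s in subjects],
            "sbp_mmhg": [s.beat.sbp for s in subjects],
            "dbp_mmhg": [s.beat.dbp for s in subjects],
            "ef_echo_percent": [100.0 * s.ef_echo_observed for s in subjects],
        }
    )
    truth = pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "coupling_true": [s.coupling_true for s in subjects],
            "edv_ml": [s.loop.edv for s in subjects],
            "esv_ml": [s.loop.esv for s in subjects],
            "v0_ml": [s.loop.v0 for s in subjects],
            "pes_mmhg": [s.loop.pes for s in subjects],
            "ef_true_percent": [100.0 * s.ef_true for s in subjects],
        }
    )
    return beats, truth
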