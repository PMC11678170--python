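"""Event-record dataset reader/writer (NONMEM-style tabular dialect).

Columns: ID, TIME (day), EVID (0 observation / 1 dose), AMT (mg, dose
rows only), DVID ('pk' | 'pasi', observation rows only), DV (observed
value), CENS (0 quantified, -1 outside the quantification range), WT
(body weight, kg).  Comma-separated, period decimal, UTF-8, mandatory
header; missing values are explicit empty fields.

The first PASI row at TIME 0 of each subject is the observed baseline
(PASIi,0): it anchors the B2 baseline method and is therefore stored on
the ObservationSet rather than among the likelihood records.
"""

from __future__ import annotations

import csv
from collections import Counter

from .errors import DatasetError
from .estimation import ObservationSet, Record
from .mipd import Regimen
from .model import DoseEvent

__all__ = ["read_dataset", "write_dataset", "infer_regimen", "COLUMNS"]

COLUMNS = ["ID", "TIME", "EVID", "AMT", "DVID", "DV", "CENS", "WT"]


def _fmt(x) -> str:
    if x is None or x == "":
        return ""
    return f"{float(x):.10g}"


def write_dataset(obs_sets, path) -> None:
    """Write a list of ObservationSet to the event-record CSV dialect."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(COLUMNS)
        for obs in obs_sets:
            rows = []
            for d in obs.doses:
                rows.append((d.time, 1, _fmt(d.amount), "", "", ""))
            rows.append((0.0, 0, "", "pasi", _fmt(obs.pasi_obs0), "0"))
            for r in obs.records:
                rows.append((r.time, 0, "", r.kind, _fmt(r.value), "-1" if r.censored else "0"))
            rows.sort(key=lambda t: (t[0], t[1] == 1))  # observations before doses at ties
            for time, evid, amt, dvid, dv, cens in rows:
                w.writerow(
                    [obs.patient_id, _fmt(time), evid, amt, dvid, dv, cens, _fmt(obs.weight)]
                )


def _parse_float(field, value, line):
    try:
        return float(value)
    except ValueError:
        raise DatasetError(f"line {line}: {field} is not a number: {value!r}")


def read_dataset(path, tolerance_ids=()) -> list:
    """Parse and validate an event-record CSV; split into ObservationSet.

    tolerance_ids: patient IDs whose tolerance submodel is active (the
    dataset itself does not carry this designation).  Malformed rows
    raise DatasetError with the offending line number.
    """
    tolerance_ids = {str(t) for t in tolerance_ids}
    per_patient: dict = {}
    order = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetError("empty file")
        if header != COLUMNS:
            raise DatasetError(f"bad header {header!r}; expected {COLUMNS!r}")
        for line, row in enumerate(reader, start=2):
            if len(row) != len(COLUMNS):
                raise DatasetError(f"line {line}: expected {len(COLUMNS)} fields, got {len(row)}")
            rec = dict(zip(COLUMNS, row))
            pid = rec["ID"]
            if not pid:
                raise DatasetError(f"line {line}: empty ID")
            time = _parse_float("TIME", rec["TIME"], line)
            if time < 0:
                raise DatasetError(f"line {line}: negative TIME")
            evid = rec["EVID"]
            wt = _parse_float("WT", rec["WT"], line)
            if pid not in per_patient:
                per_patient[pid] = {"doses": [], "records": [], "weight": wt, "baseline": None}
                order.append(pid)
            entry = per_patient[pid]
            if evid == "1":
                if rec["DV"] != "" or rec["DVID"] != "":
                    raise DatasetError(f"line {line}: dose row must not carry DV/DVID")
                if rec["AMT"] == "":
                    raise DatasetError(f"line {line}: dose row missing AMT")
                amt = _parse_float("AMT", rec["AMT"], line)
                entry["doses"].append(DoseEvent(time=time, amount=amt))
            elif evid == "0":
                if rec["AMT"] != "":
                    raise DatasetError(f"line {line}: observation row must not carry AMT")
                dvid = rec["DVID"]
                if dvid not in ("pk", "pasi"):
                    raise DatasetError(f"line {line}: DVID must be 'pk' or 'pasi', got {dvid!r}")
                cens_field = rec["CENS"]
                if cens_field not in ("0", "-1"):
                    raise DatasetError(f"line {line}: CENS must be 0 or -1, got {cens_field!r}")
                cens = cens_field == "-1"
                dv = _parse_float("DV", rec["DV"], line) if rec["DV"] != "" else None
                if dv is None:
                    raise DatasetError(f"line {line}: observation row missing DV")
                if dvid == "pasi" and time == 0.0 and not cens and entry["baseline"] is None:
                    entry["baseline"] = dv
                else:
                    entry["records"].append(Record(time=time, kind=dvid, value=dv, censored=cens))
            else:
                raise DatasetError(f"line {line}: EVID must be 0 or 1, got {evid!r}")
    out = []
    for pid in order:
        e = per_patient[pid]
        if e["baseline"] is None:
            raise DatasetError(f"patient {pid}: no baseline PASI row at TIME 0")
        e["doses"].sort(key=lambda d: d.time)
        e["records"].sort(key=lambda r: (r.time, r.kind))
        out.append(
            ObservationSet(
                patient_id=pid,
                records=e["records"],
                doses=e["doses"],
                weight=e["weight"],
                pasi_obs0=e["baseline"],
                tolerance_active=pid in tolerance_ids,
            )
        )
    return out


def infer_regimen(obs: ObservationSet) -> Regimen:
    """Infer the maintenance regimen from a dosing history.

    Uses the modal dose amount and the modal inter-dose interval (in
    whole weeks) over the recorded events.
    """
    if len(obs.doses) < 2:
        raise DatasetError(f"patient {obs.patient_id}: need >= 2 doses to infer a regimen")
    amounts = Counter(d.amount for d in obs.doses)
    times = sorted(d.time for d in obs.doses)
    weeks = Counter(round((b - a) / 7.0) for a, b in zip(times[:-1], times[1:]))
    return Regimen(dose=amounts.most_common(1)[0][0], interval=int(weeks.most_common(1)[0][0]))
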