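"""The three dosimetry report documents.

* dosimetric report — several candidate activities with full per-compartment
  dosimetry and rule flags, for the physicist to sign;
* treatment plan — the single chosen activity and its dosimetry;
* treatment verification — predicted (pre-therapy) versus delivered
  (post-therapy) doses with signed percent differences.

Reports are pure functions of the case record: identical inputs give
byte-identical outputs.  Timestamps and operator identifiers are injected
by the caller, never generated here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .compartment import PlanOption, SphereType, dose_results_frame, plan_options
from .errors import IncompleteCaseError, InvalidInputError, ReconciliationError
from .grid import Session
from .quantify import ConversionFactor
from .shunt import ShuntAssessment
from .voi import SegmentationSet


@dataclass
class SessionRecord:
    """Everything measured in one imaging session (PRE or POST)."""

    session: Session
    shunt: ShuntAssessment | None = None
    cf: ConversionFactor | None = None
    seg: SegmentationSet | None = None
    doses: list = field(default_factory=list)
    dose_map_path: str | None = None

    def __post_init__(self):
        self.session = Session(self.session)

    @property
    def complete(self) -> bool:
        return self.cf is not None and self.seg is not None and bool(self.doses)


@dataclass
class CaseRecord:
    """One patient case: pre- and (optionally) post-therapy sessions."""

    case_id: str
    sphere_type: SphereType = SphereType.GLASS
    sessions: dict = field(default_factory=dict)
    chosen_activity_gbq: float | None = None

    def __post_init__(self):
        self.sphere_type = SphereType(self.sphere_type)
        self.sessions = {Session(k): v for k, v in self.sessions.items()}

    def session(self, which) -> SessionRecord:
        which = Session(which)
        if which not in self.sessions:
            raise IncompleteCaseError(f"case '{self.case_id}' has no {which.value} session")
        return self.sessions[which]


def save_case(case: CaseRecord, path=None):
    """Serialise a case record to JSON (round-trips with :func:`load_case`)."""
    from .compartment import DoseResult

    def dose_dict(r: DoseResult) -> dict:
        return {"name": r.name, "role": r.role.value, "activity_GBq": r.activity_gbq,
                "mass_kg": r.mass_kg, "mean_dose_Gy": r.mean_dose_gy,
                "absorbed_fraction_applied": r.absorbed_fraction_applied,
                "flags": [f.value for f in r.flags]}

    payload = {"case_id": case.case_id, "sphere_type": case.sphere_type.value,
               "chosen_activity_GBq": case.chosen_activity_gbq, "sessions": {}}
    for sess, rec in case.sessions.items():
        payload["sessions"][sess.value] = {
            "shunt": json.loads(rec.shunt.to_json()) if rec.shunt else None,
            "cf": None if rec.cf is None else {
                "value": rec.cf.value, "basis": rec.cf.basis.value,
                "session": rec.cf.session.value, "approximate": rec.cf.approximate},
            "seg": json.loads(rec.seg.to_json()) if rec.seg else None,
            "doses": [dose_dict(r) for r in rec.doses],
            "dose_map_path": rec.dose_map_path,
        }
    text = json.dumps(payload, indent=2, default=float)
    if path is None:
        return text
    with open(path, "w") as fh:
        fh.write(text)


def load_case(source) -> CaseRecord:
    """Rebuild a :class:`CaseRecord` from JSON written by :func:`save_case`."""
    from .compartment import DoseResult, PlanFlag
    from .voi import Role

    if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
        payload = json.loads(source)
    else:
        with open(source) as fh:
            payload = json.load(fh)
    sessions = {}
    for name, rec in payload.get("sessions", {}).items():
        shunt = (ShuntAssessment.from_json(json.dumps(rec["shunt"]))
                 if rec.get("shunt") else None)
        cf = None
        if rec.get("cf"):
            c = rec["cf"]
            cf = ConversionFactor(c["value"], c["basis"], c["session"],
                                  c.get("approximate", False))
        seg = (SegmentationSet.from_json(json.dumps(rec["seg"]))
               if rec.get("seg") else None)
        doses = [DoseResult(d["name"], Role(d["role"]), d["activity_GBq"],
                            d["mass_kg"], d["mean_dose_Gy"],
                            d.get("absorbed_fraction_applied", False),
                            [PlanFlag(f) for f in d.get("flags", [])])
                 for d in rec.get("doses", [])]
        sessions[Session(name)] = SessionRecord(Session(name), shunt, cf, seg,
                                                doses, rec.get("dose_map_path"))
    return CaseRecord(payload["case_id"], payload.get("sphere_type", "GLASS"),
                      sessions, payload.get("chosen_activity_GBq"))


def _provenance(timestamp: str) -> dict:
    return {"package": "y90dose", "version": __version__, "timestamp": timestamp}


def make_dosimetric_report(case: CaseRecord, candidate_activities,
                           cumulative_prior_lung_dose_gy: float = 0.0,
                           timestamp: str = "") -> dict:
    """Pre-therapy dosimetric report: one option block per candidate activity.

    Returns a JSON-serialisable dict; use :func:`report_to_csv` for the
    human-readable table.
    """
    candidates = list(candidate_activities)
    if not candidates:
        raise InvalidInputError("at least one candidate activity is required")
    pre = case.session(Session.PRE)
    if not pre.complete:
        raise IncompleteCaseError(
            f"case '{case.case_id}': PRE session incomplete (need CF, segmentation, doses)")
    if pre.shunt is None:
        raise IncompleteCaseError(f"case '{case.case_id}': PRE shunt assessment missing")

    # per-GBq conversion factor: CF scales linearly with the activity basis
    cf_per_gbq = ConversionFactor(
        pre.cf.value / _basis_activity(pre), pre.cf.basis, pre.cf.session,
        pre.cf.approximate)
    options = plan_options(pre.seg, cf_per_gbq, candidates, case.sphere_type,
                           pre.shunt, cumulative_prior_lung_dose_gy)
    return {
        "document": "dosimetric_report",
        "case_id": case.case_id,
        "sphere_type": case.sphere_type.value,
        "provenance": _provenance(timestamp),
        "shunt": json.loads(pre.shunt.to_json()),
        "vf": pre.seg.vf,
        "options": [_option_dict(o) for o in options],
    }


def _basis_activity(session_record: SessionRecord) -> float:
    """Total activity the session's CF was built from (A = CF · N_total)."""
    seg = session_record.seg
    n_liver = seg.get("perfused_liver").counts
    try:
        n_lung = seg.get("lung").counts
    except KeyError:
        n_lung = 0.0
    return session_record.cf.value * (n_liver + n_lung)


def _option_dict(option: PlanOption) -> dict:
    return {
        "candidate_activity_GBq": option.candidate_activity_gbq,
        "lung_dose_Gy": option.lung_dose_gy,
        "flags": [f.value for f in option.flags],
        "suggested_activity_GBq": option.suggested_activity_gbq,
        "notes": list(option.notes),
        "doses": dose_results_frame(option.doses).to_dict(orient="records"),
    }


def make_treatment_plan(case: CaseRecord, timestamp: str = "") -> dict:
    """The signed plan: the chosen activity and its dosimetry only."""
    if case.chosen_activity_gbq is None:
        raise IncompleteCaseError(f"case '{case.case_id}': no chosen activity")
    report = make_dosimetric_report(case, [case.chosen_activity_gbq],
                                    timestamp=timestamp)
    report["document"] = "treatment_plan"
    report["chosen_activity_GBq"] = case.chosen_activity_gbq
    return report


def make_verification_report(case: CaseRecord, timestamp: str = "") -> dict:
    """Predicted vs delivered doses with signed percent differences."""
    pre, post = case.session(Session.PRE), case.session(Session.POST)
    for which, rec in (("PRE", pre), ("POST", post)):
        if not rec.complete:
            raise IncompleteCaseError(
                f"case '{case.case_id}': {which} session incomplete")
    pre_by = {r.name: r for r in pre.doses}
    post_by = {r.name: r for r in post.doses}
    unmatched = sorted(set(pre_by) ^ set(post_by))
    if unmatched:
        raise ReconciliationError(
            f"case '{case.case_id}': compartments present in only one session: "
            f"{unmatched}", unmatched)
    rows = []
    for name in pre_by:
        dpre, dpost = pre_by[name].mean_dose_gy, post_by[name].mean_dose_gy
        pct = 100.0 * (dpost - dpre) / dpre if dpre else float("nan")
        rows.append({"compartment": name, "predicted_dose_Gy": dpre,
                     "delivered_dose_Gy": dpost, "percent_difference": pct})
    return {
        "document": "treatment_verification",
        "case_id": case.case_id,
        "provenance": _provenance(timestamp),
        "comparison": rows,
    }


def report_to_json(report: dict, path=None):
    text = json.dumps(report, indent=2, default=float)
    if path is None:
        return text
    with open(path, "w") as fh:
        fh.write(text)


def report_to_csv(report: dict, path):
    """Flatten a report into its human-readable CSV table."""
    if report["document"] == "treatment_verification":
        pd.DataFrame(report["comparison"]).to_csv(path, index=False)
        return
    frames = []
    for opt in report["options"]:
        df = pd.DataFrame(opt["doses"])
        df.insert(0, "candidate_GBq", opt["candidate_activity_GBq"])
        df["lung_dose_Gy"] = opt["lung_dose_Gy"]
        df["flags"] = ";".join(opt["flags"])
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
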