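"""MIMIC-III v1.4 cohort extraction (optional stage; no MIMIC data required
to build or test the package — fixtures use the same table schema).

Implements the inclusion/exclusion rules, 30-day readmission labelling,
variable construction and preprocessing needed to turn raw MIMIC-III CSV
tables (PATIENTS, ADMISSIONS, ICUSTAYS, DIAGNOSES_ICD, PROCEDURES_ICD,
PRESCRIPTIONS, CHARTEVENTS, OUTPUTEVENTS) into the same stays/events/
vocabulary schema the synthetic generator emits.

Conventions (documented choices):

* the 30-day boundary is inclusive: a next ICU admission exactly 30.0 days
  after discharge counts as a readmission;
* any later ICUSTAY row of the same patient is a readmission candidate,
  including transfers within one hospitalisation;
* diagnosis/procedure codes from all admissions up to and including the
  index admission are used, with elapsed time = days between that
  admission's hospital discharge and the index ICU discharge (0 for the
  index admission itself — the simplifying assumption that its codes are
  available at discharge);
* medications and vital signs are restricted to the index ICU stay, elapsed
  in hours before ICU discharge;
* vital signs follow the seven OASIS components, binned at the published
  OASIS cut-points; the CHARTEVENTS/OUTPUTEVENTS item ids for each vital are
  the ``CHART_ITEMIDS`` / ``OUTPUT_ITEMIDS`` tables below (MetaVision and
  CareVue ids for the seven signs);
* MIMIC ages shifted above 89 are capped at 90; events with equal timestamps
  are ordered by code index for determinism.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Cohort, StayRecord, Vocabulary, DXPROC, MEDVIT
from .synthetic import STATIC_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "OASIS_BINS", "oasis_bin_vital", "apply_exclusions", "label_readmission",
    "dedupe_consecutive", "relabel_rare", "elapsed_time", "split_patients",
    "build_static_vector", "extract_cohort", "CHART_ITEMIDS", "OUTPUT_ITEMIDS",
]

# -- OASIS vital-sign binning -------------------------------------------------

# Upper bin edges (inclusive) and labels, from the published OASIS
# categorisation. Values above the last edge fall in the final bin.
OASIS_BINS: dict[str, tuple[list[float], list[str]]] = {
    "gcs": ([7, 13, 14], ["lt8", "8_13", "14", "15"]),
    "heart_rate": ([32.99, 88, 106, 125],
                   ["lt33", "33_88", "89_106", "107_125", "gt125"]),
    "mean_arterial_pressure": ([20.64, 50.99, 61.32, 143.44],
                               ["lt20.65", "20.65_50.99", "51_61.32",
                                "61.33_143.44", "gt143.44"]),
    "respiratory_rate": ([5.99, 12, 22, 30, 44],
                         ["lt6", "6_12", "13_22", "23_30", "31_44", "gt44"]),
    "temperature": ([33.21, 35.93, 36.39, 36.88, 39.88],
                    ["lt33.22", "33.22_35.93", "35.94_36.39", "36.40_36.88",
                     "36.89_39.88", "gt39.88"]),
    "urine_output": ([670.99, 1426.99, 2543.99, 6896],
                     ["lt671", "671_1426.99", "1427_2543.99", "2544_6896",
                      "gt6896"]),
    "ventilated": ([0.5], ["no", "yes"]),
}

# Plausible physiological ranges; measurements outside are flagged and dropped.
PHYSIO_BOUNDS: dict[str, tuple[float, float]] = {
    "gcs": (3, 15),
    "heart_rate": (0, 350),
    "mean_arterial_pressure": (0, 350),
    "respiratory_rate": (0, 120),
    "temperature": (20, 45),
    "urine_output": (0, 20000),
    "ventilated": (0, 1),
}


def oasis_bin_vital(vital: str, value: float,
                    bounds: dict | None = None) -> str | None:
    """Categorical OASIS bin code for a vital-sign measurement.

    Returns ``None`` (and logs) for values outside the configured
    physiological bounds; callers drop such measurements.
    """
    if vital not in OASIS_BINS:
        raise KeyError(f"unknown vital {vital!r}; expected one of {sorted(OASIS_BINS)}")
    lo, hi = (bounds or PHYSIO_BOUNDS)[vital]
    if not (lo <= value <= hi) or not math.isfinite(value):
        logger.warning("dropping out-of-range %s measurement %r", vital, value)
        return None
    edges, labels = OASIS_BINS[vital]
    # edges are inclusive upper bounds: a value equal to an edge falls in
    # the lower bin (searchsorted side="left")
    k = int(np.searchsorted(edges, value, side="left"))
    return f"{vital}:{labels[k]}"


# -- study-population rules ---------------------------------------------------

def apply_exclusions(stays: pd.DataFrame, death_times: pd.Series,
                     birth_dates: pd.Series) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the cohort exclusion rules; returns (included stays, counts).

    ``stays`` needs columns patient_id, stay_id, intime, outtime (datetimes);
    ``death_times``/``birth_dates`` are indexed by patient_id (NaT allowed).
    Excluded are stays where the patient (a) died during the ICU stay,
    (b) was younger than 18 years at discharge, or (c) died within 30 days
    of discharge without an intervening ICU readmission. Stays with a
    missing discharge timestamp are rejected with a logged reason.
    """
    stays = stays.sort_values(["patient_id", "intime"]).reset_index(drop=True)
    counts = {"missing_outtime": 0, "died_in_stay": 0, "under_18": 0,
              "died_within_30d_no_readmit": 0}
    keep = np.ones(len(stays), dtype=bool)
    next_intime = stays.groupby("patient_id")["intime"].shift(-1)
    for i, row in stays.iterrows():
        if pd.isna(row.outtime):
            logger.warning("stay %s rejected: missing discharge timestamp", row.stay_id)
            counts["missing_outtime"] += 1
            keep[i] = False
            continue
        dod = death_times.get(row.patient_id, pd.NaT)
        dob = birth_dates.get(row.patient_id, pd.NaT)
        if pd.notna(dod) and row.intime <= dod <= row.outtime:
            counts["died_in_stay"] += 1
            keep[i] = False
            continue
        age = (row.outtime - dob).days / 365.25 if pd.notna(dob) else np.nan
        if not np.isnan(age) and age > 120:  # MIMIC date-shifted elderly
            age = 90.0
        if np.isnan(age) or age < 18.0:
            counts["under_18"] += 1
            keep[i] = False
            continue
        if pd.notna(dod) and (dod - row.outtime) <= pd.Timedelta(days=30):
            nxt = next_intime.iloc[i]
            readmitted_before_death = pd.notna(nxt) and nxt <= dod
            if not readmitted_before_death:
                counts["died_within_30d_no_readmit"] += 1
                keep[i] = False
    return stays[keep].reset_index(drop=True), counts


def label_readmission(stays_of_patient: pd.DataFrame) -> pd.Series:
    """Binary 30-day readmission label per stay of one patient.

    ``stays_of_patient`` must be sorted by ``intime``; label is 1 iff the
    next ICU admission starts within 30 days (inclusive) of this stay's
    discharge. Overlapping stays raise with the conflicting ids.
    """
    st = stays_of_patient
    labels = np.zeros(len(st), dtype=int)
    for i in range(len(st) - 1):
        out_t = st.iloc[i].outtime
        next_in = st.iloc[i + 1].intime
        if next_in < out_t:
            raise ValueError(
                f"overlapping ICU stays: {st.iloc[i].stay_id} and "
                f"{st.iloc[i + 1].stay_id}")
        if (next_in - out_t) <= pd.Timedelta(days=30):
            labels[i] = 1
    return pd.Series(labels, index=st.index)


def dedupe_consecutive(events: list[tuple[str, float]],
                       vital_codes: set[str] | None = None) -> list[tuple[str, float]]:
    """Keep only the latest observation of each consecutive run of identical
    vital-sign codes; non-vital codes are untouched.

    ``events`` are (code, time) pairs sorted by time ascending. If
    ``vital_codes`` is None every code is treated as a vital.
    """
    out: list[tuple[str, float]] = []
    for code, t in events:
        is_vital = vital_codes is None or code in vital_codes
        if out and is_vital and out[-1][0] == code:
            out[-1] = (code, t)
        else:
            out.append((code, t))
    return out


def relabel_rare(stay_values: dict, threshold: int = 100,
                 other: str = "other") -> tuple[dict, dict[str, int]]:
    """Map values associated with fewer than ``threshold`` distinct stays to
    ``"other"``; returns (raw value -> mapped value, per-value stay counts)."""
    counts: dict[str, int] = {}
    for values in stay_values.values():
        for v in set(values):
            counts[v] = counts.get(v, 0) + 1
    mapping = {v: (v if n >= threshold else other) for v, n in counts.items()}
    return mapping, counts


def elapsed_time(event_timestamp, reference_timestamp, unit: str = "days",
                 tolerance_hours: float = 24.0) -> float:
    """Non-negative elapsed time between an event and the index ICU discharge.

    Events slightly after the reference (within ``tolerance_hours``) are
    clamped to 0; beyond that a warning is logged and 0 is still returned
    (the availability assumption for discharge-coded events).
    """
    delta = pd.Timestamp(reference_timestamp) - pd.Timestamp(event_timestamp)
    hours = delta.total_seconds() / 3600.0
    if hours < -tolerance_hours:
        logger.warning("event %.1f h after reference; clamping elapsed time to 0",
                       -hours)
    hours = max(0.0, hours)
    return hours / 24.0 if unit == "days" else hours


def split_patients(patient_ids, test_fraction: float = 0.10,
                   seed: int = 0) -> dict:
    """Random patient-level split into train_valid / test."""
    unique = sorted(set(patient_ids))
    rng = np.random.default_rng(seed)
    draws = rng.random(len(unique))
    return {p: ("test" if d < test_fraction else "train_valid")
            for p, d in zip(unique, draws)}


# -- static covariates --------------------------------------------------------

_ETHNICITY_MAP = {
    "WHITE": None, "BLACK": "ethnicity_black", "AFRICAN": "ethnicity_black",
    "HISPANIC": "ethnicity_hispanic", "LATINO": "ethnicity_hispanic",
    "ASIAN": "ethnicity_asian",
}
_INSURANCE_MAP = {
    "MEDICARE": None, "MEDICAID": "insurance_medicaid",
    "PRIVATE": "insurance_private", "GOVERNMENT": "insurance_government",
    "SELF PAY": "insurance_self_pay",
}
_MARITAL_MAP = {
    "MARRIED": None, "LIFE PARTNER": None, "SINGLE": "marital_single",
    "WIDOWED": "marital_widowed_divorced", "DIVORCED": "marital_widowed_divorced",
    "SEPARATED": "marital_widowed_divorced",
}
_ADMLOC_MAP = {
    "EMERGENCY ROOM ADMIT": None,
    "PHYS REFERRAL/NORMAL DELI": "admloc_physician_referral",
    "CLINIC REFERRAL/PREMATURE": "admloc_clinic_referral",
    "TRANSFER FROM HOSP/EXTRAM": "admloc_transfer_hospital",
}


def _onehot_from(raw: str | float, table: dict, fallback: str | None) -> str | None:
    if not isinstance(raw, str):
        return fallback
    raw_u = raw.upper()
    for key, col in table.items():
        if key in raw_u:
            return col
    return fallback


def build_static_vector(raw: dict) -> np.ndarray:
    """Encode raw covariates into the fixed static layout.

    Reference groups (female; white; married/life partner; Medicare;
    emergency-room admission) map to all-zero categorical entries. Numeric
    covariates pass through unstandardised. ``raw`` keys: age, icu_los_days,
    preicu_los_days, n_recent_admissions, gender ('M'/'F'), elective (bool),
    ethnicity, insurance, marital_status, admission_location (MIMIC strings).
    """
    x = np.zeros(len(STATIC_NAMES))
    for k in ("age", "icu_los_days", "preicu_los_days", "n_recent_admissions"):
        x[STATIC_NAMES.index(k)] = float(raw.get(k, 0.0))
    x[STATIC_NAMES.index("gender_male")] = 1.0 if str(raw.get("gender", "F")).upper() == "M" else 0.0
    x[STATIC_NAMES.index("elective_surgery")] = 1.0 if raw.get("elective") else 0.0
    for value, table, fallback in (
            (raw.get("ethnicity"), _ETHNICITY_MAP, "ethnicity_other"),
            (raw.get("insurance"), _INSURANCE_MAP, None),
            (raw.get("marital_status"), _MARITAL_MAP, "marital_other"),
            (raw.get("admission_location"), _ADMLOC_MAP, "admloc_other")):
        col = _onehot_from(value, table, fallback)
        if col is not None:
            x[STATIC_NAMES.index(col)] = 1.0
    return x


def decode_static_vector(x: np.ndarray) -> dict:
    """Inverse of :func:`build_static_vector` up to category granularity."""
    out = {k: float(x[STATIC_NAMES.index(k)])
           for k in ("age", "icu_los_days", "preicu_los_days", "n_recent_admissions")}
    out["gender"] = "M" if x[STATIC_NAMES.index("gender_male")] else "F"
    out["elective"] = bool(x[STATIC_NAMES.index("elective_surgery")])
    for prefix, ref in (("ethnicity", "white"), ("insurance", "medicare"),
                        ("marital", "married"), ("admloc", "emergency")):
        cols = [n for n in STATIC_NAMES if n.startswith(prefix + "_")]
        active = [n for n in cols if x[STATIC_NAMES.index(n)] > 0]
        out[prefix] = active[0].split("_", 1)[1] if active else ref
    return out


# -- CHARTEVENTS / OUTPUTEVENTS item ids (MetaVision + CareVue) ---------------

CHART_ITEMIDS: dict[str, list[int]] = {
    "gcs_total": [198],                      # CareVue GCS total
    "gcs_eye": [184, 220739],
    "gcs_verbal": [723, 223900],
    "gcs_motor": [454, 223901],
    "heart_rate": [211, 220045],
    "mean_arterial_pressure": [456, 52, 220052, 220181],
    "respiratory_rate": [618, 220210],
    "temperature_c": [676, 223762],
    "temperature_f": [678, 223761],
    "ventilated": [722, 223848, 720],        # ventilator type / mode
}
OUTPUT_ITEMIDS: dict[str, list[int]] = {
    "urine_output": [40055, 43175, 40069, 40094, 226559, 226560, 226561],
}


# -- full extraction ----------------------------------------------------------

def _read(mimic_dir: Path, name: str) -> pd.DataFrame:
    for candidate in (name, name.lower(), name + ".csv", name.lower() + ".csv",
                      name + ".csv.gz"):
        p = mimic_dir / candidate
        if p.exists():
            df = pd.read_csv(p)
            df.columns = [c.upper() for c in df.columns]
            return df
    raise FileNotFoundError(f"table {name} not found under {mimic_dir}")


def extract_cohort(mimic_dir: str | Path, rare_threshold: int = 100,
                   test_fraction: float = 0.10, seed: int = 0) -> Cohort:
    """Run the full extraction pipeline on a directory of MIMIC-III CSVs."""
    mimic_dir = Path(mimic_dir)
    patients = _read(mimic_dir, "PATIENTS")
    admissions = _read(mimic_dir, "ADMISSIONS")
    icustays = _read(mimic_dir, "ICUSTAYS")
    for df, cols in ((patients, ["DOB", "DOD"]),
                     (admissions, ["ADMITTIME", "DISCHTIME"]),
                     (icustays, ["INTIME", "OUTTIME"])):
        for c in cols:
            df[c] = pd.to_datetime(df[c], errors="coerce")

    stays = icustays.rename(columns={
        "SUBJECT_ID": "patient_id", "ICUSTAY_ID": "stay_id",
        "INTIME": "intime", "OUTTIME": "outtime", "HADM_ID": "hadm_id"})
    death_times = patients.set_index("SUBJECT_ID")["DOD"]
    birth_dates = patients.set_index("SUBJECT_ID")["DOB"]
    stays = stays[["patient_id", "stay_id", "hadm_id", "intime", "outtime"]] \
        .sort_values(["patient_id", "intime"]).reset_index(drop=True)
    # labels use ALL stays: a readmission still counts as an outcome even if
    # the readmitting stay is itself excluded from the analysis sample
    if len(stays):
        labels = stays.groupby("patient_id", group_keys=False).apply(
            label_readmission, include_groups=False)
        stays["label"] = labels.values
    else:
        stays["label"] = []
    included, _counts = apply_exclusions(stays, death_times, birth_dates)

    split = split_patients(included["patient_id"], test_fraction, seed)

    gender = patients.set_index("SUBJECT_ID")["GENDER"]
    adm = admissions.set_index("HADM_ID")
    dx = _read(mimic_dir, "DIAGNOSES_ICD")
    proc = _read(mimic_dir, "PROCEDURES_ICD")
    rx = _read(mimic_dir, "PRESCRIPTIONS")
    rx["STARTDATE"] = pd.to_datetime(rx["STARTDATE"], errors="coerce")
    chart = _read(mimic_dir, "CHARTEVENTS")
    chart["CHARTTIME"] = pd.to_datetime(chart["CHARTTIME"], errors="coerce")
    try:
        outev = _read(mimic_dir, "OUTPUTEVENTS")
        outev["CHARTTIME"] = pd.to_datetime(outev["CHARTTIME"], errors="coerce")
    except FileNotFoundError:
        outev = pd.DataFrame(columns=["ICUSTAY_ID", "ITEMID", "CHARTTIME", "VALUE"])

    # raw (value, elapsed) events per stay, then rare-value relabelling
    raw_dx: dict = {}
    raw_mv: dict = {}
    statics: dict = {}
    for _, st in included.iterrows():
        ref = st.outtime
        # all diagnosis/procedure codes of admissions discharged on or before
        # the index ICU discharge
        pid_adm = admissions[admissions["SUBJECT_ID"] == st.patient_id]
        events_dx = []
        for _, a in pid_adm.iterrows():
            if pd.isna(a.DISCHTIME):
                continue
            is_index = a["HADM_ID"] == st.hadm_id
            if not is_index and a.DISCHTIME > ref:
                continue
            el = 0.0 if is_index else elapsed_time(a.DISCHTIME, ref, "days")
            for _, r in dx[dx["HADM_ID"] == a["HADM_ID"]].iterrows():
                events_dx.append((f"d_{r['ICD9_CODE']}", el))
            for _, r in proc[proc["HADM_ID"] == a["HADM_ID"]].iterrows():
                events_dx.append((f"p_{r['ICD9_CODE']}", el))
        raw_dx[st.stay_id] = events_dx

        events_mv = []
        stay_rx = rx[(rx["HADM_ID"] == st.hadm_id)
                     & rx["STARTDATE"].notna()
                     & (rx["STARTDATE"] >= st.intime - pd.Timedelta(days=1))
                     & (rx["STARTDATE"] <= st.outtime)]
        for _, r in stay_rx.iterrows():
            events_mv.append((f"m_{str(r['DRUG']).strip()}",
                              elapsed_time(r.STARTDATE, ref, "hours")))
        events_mv.extend(_vital_events(chart, outev, st, ref))
        # consecutive duplicate vitals: keep the latest (time-ascending scan)
        events_mv.sort(key=lambda e: -e[1])
        vital_codes = {c for c, _ in events_mv if c.startswith("v_")}
        events_mv = dedupe_consecutive(events_mv, vital_codes)
        raw_mv[st.stay_id] = events_mv

        a_index = adm.loc[st.hadm_id]
        age = (st.outtime - birth_dates.get(st.patient_id)).days / 365.25
        if age > 120:
            age = 90.0
        prior = included[(included["patient_id"] == st.patient_id)
                         & (included["intime"] < st.intime)
                         & (included["intime"] >= st.intime - pd.Timedelta(days=365))]
        statics[st.stay_id] = build_static_vector({
            "age": min(age, 90.0),
            "icu_los_days": (st.outtime - st.intime).total_seconds() / 86400.0,
            "preicu_los_days": max(0.0, (st.intime - a_index["ADMITTIME"])
                                   .total_seconds() / 86400.0),
            "n_recent_admissions": len(prior),
            "gender": gender.get(st.patient_id, "F"),
            "elective": str(a_index.get("ADMISSION_TYPE", "")).upper() == "ELECTIVE",
            "ethnicity": a_index.get("ETHNICITY"),
            "insurance": a_index.get("INSURANCE"),
            "marital_status": a_index.get("MARITAL_STATUS"),
            "admission_location": a_index.get("ADMISSION_LOCATION"),
        })

    map_dx, counts_dx = relabel_rare({k: [c for c, _ in v] for k, v in raw_dx.items()},
                                     rare_threshold, other="d_other")
    map_mv, counts_mv = relabel_rare({k: [c for c, _ in v] for k, v in raw_mv.items()},
                                     rare_threshold, other="mv_other")
    names_dx = sorted(set(map_dx.values()))
    names_mv = sorted(set(map_mv.values()))
    idx_dx = {n: i for i, n in enumerate(names_dx)}
    idx_mv = {n: i for i, n in enumerate(names_mv)}
    groups: dict[str, list[int]] = {}
    for n, i in idx_mv.items():
        if n.startswith("v_"):
            groups.setdefault(n.split(":")[0], []).append(i)
    vocab = Vocabulary(
        sizes={DXPROC: max(1, len(names_dx)), MEDVIT: max(1, len(names_mv))},
        code_names={DXPROC: names_dx, MEDVIT: names_mv},
        stay_counts={DXPROC: [counts_dx.get(n, 0) for n in names_dx],
                     MEDVIT: [counts_mv.get(n, 0) for n in names_mv]},
        vital_groups=groups)

    records = []
    for _, st in included.iterrows():
        seqs = {}
        for raw, mapping, idx in ((raw_dx, map_dx, idx_dx), (raw_mv, map_mv, idx_mv)):
            ev = [(idx[mapping[c]], t) for c, t in raw[st.stay_id]]
            ev.sort(key=lambda e: (-e[1], e[0]))  # oldest first; ties by code
            seqs[id(raw)] = (np.array([c for c, _ in ev], dtype=int),
                             np.array([t for _, t in ev], dtype=float))
        records.append(StayRecord(
            patient_id=int(st.patient_id), stay_id=int(st.stay_id),
            static=statics[st.stay_id],
            codes_dxproc=seqs[id(raw_dx)][0], elapsed_dxproc=seqs[id(raw_dx)][1],
            codes_medvit=seqs[id(raw_mv)][0], elapsed_medvit=seqs[id(raw_mv)][1],
            label=int(st.label), split=split[st.patient_id]))
    return Cohort(records, vocab, list(STATIC_NAMES))


def _vital_events(chart: pd.DataFrame, outev: pd.DataFrame, st,
                  ref) -> list[tuple[str, float]]:
    """OASIS-binned vital-sign events for one ICU stay."""
    ev: list[tuple[str, float]] = []
    rows = chart[chart["ICUSTAY_ID"] == st.stay_id] if "ICUSTAY_ID" in chart else chart.iloc[0:0]

    def add(vital: str, value: float, when) -> None:
        code = oasis_bin_vital(vital, value)
        if code is not None:
            ev.append((f"v_{code}", elapsed_time(when, ref, "hours")))

    gcs_parts: dict = {}
    for _, r in rows.iterrows():
        item = int(r["ITEMID"])
        try:
            val = float(r["VALUENUM"]) if "VALUENUM" in r and pd.notna(r["VALUENUM"]) \
                else float(r["VALUE"])
        except (TypeError, ValueError):
            continue
        when = r["CHARTTIME"]
        if item in CHART_ITEMIDS["gcs_total"]:
            add("gcs", val, when)
        elif item in CHART_ITEMIDS["gcs_eye"] or item in CHART_ITEMIDS["gcs_verbal"] \
                or item in CHART_ITEMIDS["gcs_motor"]:
            part = ("eye" if item in CHART_ITEMIDS["gcs_eye"] else
                    "verbal" if item in CHART_ITEMIDS["gcs_verbal"] else "motor")
            key = when
            gcs_parts.setdefault(key, {})[part] = val
        elif item in CHART_ITEMIDS["heart_rate"]:
            add("heart_rate", val, when)
        elif item in CHART_ITEMIDS["mean_arterial_pressure"]:
            add("mean_arterial_pressure", val, when)
        elif item in CHART_ITEMIDS["respiratory_rate"]:
            add("respiratory_rate", val, when)
        elif item in CHART_ITEMIDS["temperature_c"]:
            add("temperature", val, when)
        elif item in CHART_ITEMIDS["temperature_f"]:
            add("temperature", (val - 32.0) * 5.0 / 9.0, when)
        elif item in CHART_ITEMIDS["ventilated"]:
            add("ventilated", 1.0, when)
    for when, parts in gcs_parts.items():
        if len(parts) == 3:
            add("gcs", sum(parts.values()), when)
    out_rows = outev[outev["ICUSTAY_ID"] == st.stay_id] if "ICUSTAY_ID" in outev else outev.iloc[0:0]
    urine_ids = set(OUTPUT_ITEMIDS["urine_output"])
    daily: dict = {}
    for _, r in out_rows.iterrows():
        if int(r["ITEMID"]) in urine_ids and pd.notna(r["CHARTTIME"]):
            day = r["CHARTTIME"].normalize()
            try:
                daily[day] = daily.get(day, 0.0) + float(r["VALUE"])
            except (TypeError, ValueError):
                continue
    for day, total in daily.items():
        add("urine_output", total, day + pd.Timedelta(hours=23, minutes=59))
    return ev
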