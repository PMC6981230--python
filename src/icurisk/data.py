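"""Core data containers: timestamped code events, labelled ICU stays, cohorts.

A stay is the unit of prediction: static covariates, two event streams on
different time scales (diagnoses/procedures in days before the index ICU
discharge; medications/vital signs in hours), and a binary 30-day readmission
label. Cohorts serialise to three CSV files plus JSON sidecars so the
synthetic generator and the MIMIC extraction stage emit the same schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DXPROC = "dx_proc"
MEDVIT = "med_vit"
STREAMS = (DXPROC, MEDVIT)


@dataclass
class CodeEvent:
    """One timestamped code occurrence."""
    code: int
    stream: str
    elapsed: float  # days (dx_proc) or hours (med_vit) before index discharge


@dataclass
class StayRecord:
    """One labelled ICU stay."""
    patient_id: int | str
    stay_id: int | str
    static: np.ndarray
    codes_dxproc: np.ndarray  # int codes, sorted largest elapsed first
    elapsed_dxproc: np.ndarray  # days
    codes_medvit: np.ndarray
    elapsed_medvit: np.ndarray  # hours
    label: int
    split: str = "train_valid"

    def events(self, stream: str) -> list[CodeEvent]:
        if stream == DXPROC:
            return [CodeEvent(int(c), DXPROC, float(t))
                    for c, t in zip(self.codes_dxproc, self.elapsed_dxproc)]
        return [CodeEvent(int(c), MEDVIT, float(t))
                for c, t in zip(self.codes_medvit, self.elapsed_medvit)]


@dataclass
class Vocabulary:
    """Dense code index per stream, with per-code stay counts.

    ``vital_groups`` optionally partitions med/vit codes into vital-sign
    groups (each group holding the codes for one sign's bins); the logistic
    baseline uses it to pick each sign's most recent code.
    """
    sizes: dict[str, int]
    code_names: dict[str, list[str]] = field(default_factory=dict)
    stay_counts: dict[str, list[int]] = field(default_factory=dict)
    vital_groups: dict[str, list[int]] = field(default_factory=dict)

    def size(self, stream: str) -> int:
        return self.sizes[stream]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "sizes": self.sizes,
            "code_names": self.code_names,
            "stay_counts": self.stay_counts,
            "vital_groups": self.vital_groups,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        d = json.loads(Path(path).read_text())
        return cls(sizes=d["sizes"], code_names=d.get("code_names", {}),
                   stay_counts=d.get("stay_counts", {}),
                   vital_groups=d.get("vital_groups", {}))


@dataclass
class Cohort:
    """A set of labelled stays with shared vocabulary and covariate layout."""
    stays: list[StayRecord]
    vocabulary: Vocabulary
    static_names: list[str]

    def __len__(self) -> int:
        return len(self.stays)

    def subset(self, split: str) -> "Cohort":
        return Cohort([s for s in self.stays if s.split == split],
                      self.vocabulary, self.static_names)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.stays], dtype=int)

    @property
    def patient_ids(self) -> np.ndarray:
        return np.array([s.patient_id for s in self.stays])

    # -- serialisation (CSV + JSON sidecar) -----------------------------------

    def to_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        ev_dx, ev_mv = [], []
        for s in self.stays:
            row = {"patient_id": s.patient_id, "stay_id": s.stay_id,
                   "label": s.label, "split": s.split}
            row.update({name: v for name, v in zip(self.static_names, s.static)})
            rows.append(row)
            for c, t in zip(s.codes_dxproc, s.elapsed_dxproc):
                ev_dx.append({"stay_id": s.stay_id, "code": int(c), "elapsed_time": float(t)})
            for c, t in zip(s.codes_medvit, s.elapsed_medvit):
                ev_mv.append({"stay_id": s.stay_id, "code": int(c), "elapsed_time": float(t)})
        pd.DataFrame(rows).to_csv(out / "stays.csv", index=False)
        cols = ["stay_id", "code", "elapsed_time"]
        pd.DataFrame(ev_dx, columns=cols).to_csv(out / "events_dxproc.csv", index=False)
        pd.DataFrame(ev_mv, columns=cols).to_csv(out / "events_medvit.csv", index=False)
        self.vocabulary.to_json(out / "vocabulary.json")

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "Cohort":
        src = Path(in_dir)
        stays_df = pd.read_csv(src / "stays.csv")
        vocab = Vocabulary.from_json(src / "vocabulary.json")
        static_names = [c for c in stays_df.columns
                        if c not in ("patient_id", "stay_id", "label", "split")]
        ev = {}
        for stream, fname in ((DXPROC, "events_dxproc.csv"), (MEDVIT, "events_medvit.csv")):
            df = pd.read_csv(src / fname)
            ev[stream] = {k: g for k, g in df.groupby("stay_id")}
        stays = []
        for _, row in stays_df.iterrows():
            seqs = {}
            for stream in STREAMS:
                g = ev[stream].get(row["stay_id"])
                if g is None:
                    seqs[stream] = (np.empty(0, dtype=int), np.empty(0))
                else:
                    g = g.sort_values("elapsed_time", ascending=False, kind="stable")
                    seqs[stream] = (g["code"].to_numpy(dtype=int),
                                    g["elapsed_time"].to_numpy(dtype=float))
            stays.append(StayRecord(
                patient_id=row["patient_id"], stay_id=row["stay_id"],
                static=row[static_names].to_numpy(dtype=float),
                codes_dxproc=seqs[DXPROC][0], elapsed_dxproc=seqs[DXPROC][1],
                codes_medvit=seqs[MEDVIT][0], elapsed_medvit=seqs[MEDVIT][1],
                label=int(row["label"]), split=str(row["split"])))
        return cls(stays, vocab, static_names)


def pad_batch(stays: list[StayRecord]) -> dict[str, np.ndarray]:
    """Pad a list of stays into rectangular arrays with masks.

    Padded positions carry code 0 and elapsed 0 but mask 0; encoders must not
    let them influence any output.
    """
    B = len(stays)
    out: dict[str, np.ndarray] = {
        "static": np.stack([s.static for s in stays]).astype(float),
        "label": np.array([s.label for s in stays], dtype=float),
    }
    for stream, codes_attr, el_attr in (
            (DXPROC, "codes_dxproc", "elapsed_dxproc"),
            (MEDVIT, "codes_medvit", "elapsed_medvit")):
        L = max(1, max(len(getattr(s, codes_attr)) for s in stays))
        codes = np.zeros((B, L), dtype=int)
        elapsed = np.zeros((B, L))
        mask = np.zeros((B, L))
        for i, s in enumerate(stays):
            c = getattr(s, codes_attr)
            codes[i, :len(c)] = c
            elapsed[i, :len(c)] = getattr(s, el_attr)
            mask[i, :len(c)] = 1.0
        out[f"codes_{stream}"] = codes
        out[f"elapsed_{stream}"] = elapsed
        out[f"mask_{stream}"] = mask
    return out
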