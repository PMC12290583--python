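"""Term-annotated coordinate database (Neurosynth-style, emulated).

A :class:`CoordinateDatabase` holds, per study, its reported foci (mm) and
optional subject count, plus a study -> term annotation map.  It is the
input both to meta-analytic coactivation modeling (which studies report a
focus inside a seed?) and to term-association maps for functional decoding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CoordinateDatabase", "load_database", "save_database"]


@dataclass
class CoordinateDatabase:
    """studies: id -> (foci (N,3) mm, n_subjects or None);
    annotations: id -> set of term ids."""

    studies: dict
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for sid, entry in self.studies.items():
            if isinstance(entry, tuple):
                foci, n = entry
            else:
                foci, n = entry, None
            foci = np.atleast_2d(np.asarray(foci, dtype=float))
            if not np.all(np.isfinite(foci)):
                raise ValueError(f"study {sid!r} has non-finite foci")
            clean[sid] = (foci, n)
        self.studies = clean
        for sid in self.annotations:
            if sid not in self.studies:
                raise ValueError(f"annotation references unknown study {sid!r}")
        self.annotations = {s: set(t) for s, t in self.annotations.items()}

    @property
    def study_ids(self) -> list:
        return list(self.studies)

    @property
    def terms(self) -> list:
        out = set()
        for t in self.annotations.values():
            out |= t
        return sorted(out)

    def studies_with_term(self, term) -> list:
        return [s for s, t in self.annotations.items() if term in t]

    def foci_of(self, study_id) -> np.ndarray:
        return self.studies[study_id][0]

    def __len__(self):
        return len(self.studies)


def save_database(db: CoordinateDatabase, foci_path, annotations_path) -> None:
    """Write the two-TSV form (foci: study_id, x, y, z[, n]; annotations:
    study_id, term)."""
    rows = []
    for sid, (foci, n) in db.studies.items():
        for xyz in foci:
            rows.append({"study_id": sid, "x": xyz[0], "y": xyz[1], "z": xyz[2],
                         "n": n if n is not None else ""})
    pd.DataFrame(rows).to_csv(foci_path, sep="\t", index=False)
    ann = [{"study_id": s, "term": t}
           for s, terms in db.annotations.items() for t in sorted(terms)]
    pd.DataFrame(ann, columns=["study_id", "term"]).to_csv(
        annotations_path, sep="\t", index=False
    )


def load_database(foci_path, annotations_path=None) -> CoordinateDatabase:
    df = pd.read_csv(foci_path, sep="\t", dtype={"study_id": str})
    studies = {}
    for sid, sub in df.groupby("study_id", sort=False):
        n = None
        if "n" in sub.columns:
            nv = pd.to_numeric(sub["n"], errors="coerce").dropna()
            if len(nv):
                n = int(nv.iloc[0])
        studies[sid] = (sub[["x", "y", "z"]].to_numpy(float), n)
    annotations: dict = {}
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", dtype=str)
        for _, row in ann.iterrows():
            annotations.setdefault(row["study_id"], set()).add(row["term"])
    return CoordinateDatabase(studies=studies, annotations=annotations)


def save_database_json(db: CoordinateDatabase, path) -> None:
    obj = {
        "studies": {s: {"foci": f.tolist(), "n": n}
                    for s, (f, n) in db.studies.items()},
        "annotations": {s: sorted(t) for s, t in db.annotations.items()},
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def load_database_json(path) -> CoordinateDatabase:
    with open(path) as fh:
        obj = json.load(fh)
    return CoordinateDatabase(
        studies={s: (np.asarray(d["foci"]), d.get("n"))
                 for s, d in obj["studies"].items()},
        annotations={s: set(t) for s, t in obj["annotations"].items()},
    )
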