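"""Plain-text cohort serialization.

Layout: one whitespace-delimited dense matrix file per subject per
modality (``<id>_sc.txt``, ``<id>_fc.txt``; row-major, K columns), a
tab-separated region table (``regions.tsv``: region_id, hemisphere,
axis_rank, x, y, z, volume), and a JSON manifest (``cohort.json``)
holding subject ids, relative file paths, the generating spec, and the
seed.  All downstream stages read only this layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .synth import Cohort, CohortSpec, SubjectData

__all__ = ["save_cohort", "load_cohort"]

_REGION_COLS = ["region_id", "hemisphere", "axis_rank", "x", "y", "z", "volume"]


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort to a directory; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for subj in cohort.subjects:
        sc_name = f"{subj.subject_id}_sc.txt"
        fc_name = f"{subj.subject_id}_fc.txt"
        np.savetxt(out / sc_name, subj.sc)
        np.savetxt(out / fc_name, subj.fc)
        entry = {"subject_id": subj.subject_id, "sc": sc_name, "fc": fc_name}
        if subj.fd_runs is not None:
            fd_name = f"{subj.subject_id}_fd.txt"
            lengths = [len(run) for run in subj.fd_runs]
            np.savetxt(out / fd_name, np.concatenate(subj.fd_runs))
            entry["fd"] = fd_name
            entry["fd_run_lengths"] = lengths
        entries.append(entry)
    cohort.regions[_REGION_COLS].to_csv(out / "regions.tsv", sep="\t",
                                        index=False)
    manifest = {
        "subjects": entries,
        "regions": "regions.tsv",
        "spec": cohort.spec.to_dict() if cohort.spec is not None else None,
        "provenance": cohort.provenance,
    }
    path = out / "cohort.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Read a cohort back from its manifest."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    regions = pd.read_csv(root / manifest["regions"], sep="\t")
    missing = set(_REGION_COLS) - set(regions.columns)
    if missing:
        raise InvalidInputError(f"regions.tsv missing columns: {sorted(missing)}")
    subjects = []
    for entry in manifest["subjects"]:
        sc = np.loadtxt(root / entry["sc"])
        fc = np.loadtxt(root / entry["fc"])
        subj = SubjectData(subject_id=entry["subject_id"], sc=sc, fc=fc)
        if "fd" in entry:
            flat = np.loadtxt(root / entry["fd"])
            runs, start = [], 0
            for length in entry["fd_run_lengths"]:
                runs.append(flat[start:start + length])
                start += length
            subj.fd_runs = runs
        subj.validate()
        subjects.append(subj)
    spec = (CohortSpec.from_dict(manifest["spec"])
            if manifest.get("spec") else None)
    return Cohort(subjects=subjects, regions=regions, spec=spec,
                  provenance=manifest.get("provenance", {}))
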