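"""Quality control and consistency masking on a saved cohort.

Applies the motion-QC run filters to the framewise-displacement traces
and computes the group-consistency mask (top quartile of edges by
across-subject weight CV removed) on the training half.
"""

import argparse
import json
from pathlib import Path

from sfcoupling import io, prep
from sfcoupling.gnn import split_cohort
from sfcoupling.pipeline import stage_seed

ap = argparse.ArgumentParser()
ap.add_argument("--cohort", default="results/cohort/cohort.json")
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out", default="results/prep_report.json")
args = ap.parse_args()

cohort = io.load_cohort(args.cohort)
qc = prep.qc_filter_runs([s.fd_runs or [] for s in cohort.subjects])
train, test = split_cohort(list(range(cohort.n_subjects)),
                           seed=stage_seed(args.seed, "split"))
mask = prep.consistency_mask([cohort.subjects[i].sc for i in train])

report = {
    "qc": {"excluded_subjects": qc.excluded_subjects,
           "runs_dropped_spike_rule": len(qc.dropped_rule1),
           "runs_dropped_fence_rule": len(qc.dropped_rule2),
           "mean_fd_fence_mm": qc.mean_fd_threshold},
    "mask": {"percentile": mask.percentile, "cv_threshold": mask.threshold,
             "edges_evaluated": mask.n_evaluated,
             "edges_removed_by_cv": mask.n_removed_by_cv},
    "split": {"train": train, "test": test},
}
Path(args.out).parent.mkdir(parents=True, exist_ok=True)
Path(args.out).write_text(json.dumps(report, indent=2, sort_keys=True))
print(f"QC excluded {len(qc.excluded_subjects)} subjects; consistency mask "
      f"removed {mask.n_removed_by_cv}/{mask.n_evaluated} edges "
      f"(CV > {mask.threshold:.3f})")
print(f"wrote {args.out}")
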