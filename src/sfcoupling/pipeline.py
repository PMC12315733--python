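"""End-to-end study orchestration at desk scale.

:func:`run_study` chains every stage: cohort generation (or loading),
motion QC, train/test split, consistency masking, GNN training, FC
prediction, global and regional coupling decomposition for both the
correlation and GNN approaches, the rewired-topology null, and
axis-alignment with spin-test significance — emitting one structured
report.  :func:`run_repeated_cv` repeats the two-fold split with role
reversal and aggregates coupling and alignment statistics across folds.

Reproducibility: every stage draws its seed from the master seed via a
documented derivation (``SeedSequence([master_seed, stage_tag])``), so
a rerun with the same master seed yields a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import coupling as cpl
from . import gnn, nulls
from .axis import align_map, outlier_mask, spearman_rho
from .errors import InvalidSpecError
from .io import load_cohort
from .prep import consistency_mask, qc_filter_runs
from .synth import Cohort, CohortSpec, generate_cohort

__all__ = ["RunConfig", "run_study", "run_repeated_cv", "stage_seed"]

_STAGE_TAGS = {
    "cohort": 1, "split": 2, "mask": 3, "train": 4,
    "rewire": 5, "spin": 6, "cv": 7,
}


def stage_seed(master_seed: int, stage: str, extra: int = 0) -> int:
    """Derive a per-stage 31-bit seed from the master seed."""
    ss = np.random.SeedSequence([master_seed, _STAGE_TAGS[stage], extra])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one study run needs.

    ``cohort_spec`` and ``manifest_path`` are mutually exclusive cohort
    sources.  When generating, the cohort seed is derived from
    ``master_seed`` (the spec's own seed field is overridden) so one
    integer reproduces the whole study.
    """

    cohort_spec: CohortSpec | None = None
    manifest_path: str | None = None
    gnn_config: gnn.GnnConfig | None = None
    mask_percentile: float = 75.0
    mask_scope: str = "train"        # "train" or "all"
    approaches: tuple[str, ...] = ("correlation", "gnn")
    n_rotations: int = 1000
    swaps_per_edge: int = 10
    outlier_k: float = 3.0
    run_rewired_null: bool = True
    run_alignment: bool = True
    split_fraction: float = 0.5
    master_seed: int = 0
    out_dir: str | None = None

    def resolved_cohort(self) -> Cohort:
        if (self.cohort_spec is None) == (self.manifest_path is None):
            raise InvalidSpecError(
                "exactly one of cohort_spec / manifest_path must be set")
        if self.manifest_path is not None:
            return load_cohort(self.manifest_path)
        spec = self.cohort_spec.replace(
            seed=stage_seed(self.master_seed, "cohort"))
        return generate_cohort(spec)

    def resolved_gnn_config(self, k: int) -> gnn.GnnConfig:
        cfg = self.gnn_config
        if cfg is None:
            cfg = gnn.GnnConfig(gcn_dims=(k, 64, 64))
        if cfg.gcn_dims[0] != k:
            cfg = cfg.replace(gcn_dims=(k,) + tuple(cfg.gcn_dims[1:]))
        return cfg.replace(seed=stage_seed(self.master_seed, "train"))


def _decomposition_record(dec: cpl.CouplingDecomposition) -> dict:
    return {
        "total": dec.total, "group": dec.group, "individual": dec.individual,
        "individual_fraction": dec.individual_fraction,
        "t_statistic": dec.t_statistic, "p_value": dec.p_value,
    }


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the report."""
    report: dict = {"schema_version": 1, "master_seed": config.master_seed,
                    "stages": []}
    cohort = config.resolved_cohort()
    k = cohort.n_regions
    report["cohort"] = {"n_subjects": cohort.n_subjects, "n_regions": k,
                        "provenance": cohort.provenance}
    report["stages"].append("cohort")

    # Motion QC (only when FD traces are present).
    if any(s.fd_runs is not None for s in cohort.subjects):
        qc = qc_filter_runs([s.fd_runs or [] for s in cohort.subjects])
        keep = [i for i in range(cohort.n_subjects)
                if i not in set(qc.excluded_subjects)]
        report["qc"] = {
            "excluded_subjects": qc.excluded_subjects,
            "dropped_rule1": len(qc.dropped_rule1),
            "dropped_rule2": len(qc.dropped_rule2),
            "mean_fd_threshold": qc.mean_fd_threshold,
        }
        cohort = Cohort(subjects=[cohort.subjects[i] for i in keep],
                        regions=cohort.regions, spec=cohort.spec,
                        provenance=cohort.provenance)
        report["stages"].append("qc")

    # Train/test split.
    ids = list(range(cohort.n_subjects))
    train_ids, test_ids = gnn.split_cohort(
        ids, fraction=config.split_fraction,
        seed=stage_seed(config.master_seed, "split"))
    report["split"] = {"train": train_ids, "test": test_ids}
    report["stages"].append("split")

    # Consistency mask (training subjects by default to avoid leakage).
    mask_ids = train_ids if config.mask_scope == "train" else ids
    mask = consistency_mask([cohort.subjects[i].sc for i in mask_ids],
                            percentile=config.mask_percentile)
    report["mask"] = {"scope": config.mask_scope,
                      "percentile": config.mask_percentile,
                      "threshold": mask.threshold,
                      "n_evaluated": mask.n_evaluated,
                      "n_removed_by_cv": mask.n_removed_by_cv}
    report["stages"].append("mask")

    masked_sc = [mask.apply(s.sc) for s in cohort.subjects]
    fcs = [s.fc for s in cohort.subjects]
    train_scs = [masked_sc[i] for i in train_ids]
    train_fcs = [fcs[i] for i in train_ids]
    test_scs = [masked_sc[i] for i in test_ids]
    test_fcs = [fcs[i] for i in test_ids]

    # GNN training and prediction.
    cfg = config.resolved_gnn_config(k)
    model, losses = gnn.train_model(train_scs, train_fcs, cfg)
    preds = [gnn.predict_fc(sc, model) for sc in test_scs]
    g_pred, g_emp = gnn.group_level_predict(model, test_scs, test_fcs)
    report["gnn"] = {
        "config": cfg.to_dict(),
        "final_train_loss": float(losses[-1]),
        "initial_train_loss": float(losses[0]),
        "group_level_r": cpl.coupling_pair(g_pred, g_emp, "gnn",
                                           sc_mask=mask.keep),
    }
    report["stages"].append("train")

    # Global coupling + decomposition, both approaches.
    sources = {"correlation": test_scs, "gnn": preds}
    report["global"] = {}
    cp_matrices = {}
    for approach in config.approaches:
        cp = cpl.cross_coupling_matrix(sources[approach], test_fcs, approach,
                                       sc_mask=mask.keep)
        cp_matrices[approach] = cp
        dec = cpl.decompose(cp)
        report["global"][approach] = _decomposition_record(dec)
    report["stages"].append("global_coupling")

    # Regional effect maps.
    regional = {}
    for approach in config.approaches:
        regional[approach] = cpl.regional_effect_maps(
            sources[approach], test_fcs, approach, sc_mask=mask.keep)
    report["regional"] = {
        a: {col: regional[a][col].to_numpy().tolist()
            for col in ("total", "group", "individual",
                        "normalized_individual")}
        for a in regional
    }
    report["stages"].append("regional_coupling")

    # Rewired-topology null (GNN approach).
    if config.run_rewired_null and "gnn" in config.approaches:
        r_emp = np.diag(cp_matrices["gnn"]).copy()
        comp = nulls.rewired_training_run(
            train_scs, train_fcs, test_scs, test_fcs, cfg, r_emp,
            swaps_per_edge=config.swaps_per_edge,
            rng=np.random.default_rng(stage_seed(config.master_seed, "rewire")),
            sc_mask=mask.keep)
        report["rewired_null"] = {
            "r_empirical_mean": float(np.mean(comp.r_empirical)),
            "r_rewired_mean": float(np.mean(comp.r_rewired)),
            "r2_drop": comp.r2_drop,
            "r_empirical": comp.r_empirical.tolist(),
            "r_rewired": comp.r_rewired.tolist(),
        }
        report["stages"].append("rewired_null")

    # Axis alignment with spin-test significance.
    if config.run_alignment:
        coords = cohort.regions[["x", "y", "z"]].to_numpy()
        hemis = cohort.regions["hemisphere"].to_numpy()
        ranks = cohort.regions["axis_rank"].to_numpy(dtype=float)
        perms = nulls.spin_rotations(
            coords, hemis, config.n_rotations,
            rng=np.random.default_rng(stage_seed(config.master_seed, "spin")))
        report["alignment"] = {}
        for approach in config.approaches:
            maps = regional[approach]
            rec = {}
            for name in ("total", "group", "individual",
                         "normalized_individual"):
                res = align_map(maps[name].to_numpy(), ranks, perms,
                                outlier_k=config.outlier_k)
                rec[name] = {"rho": res.rho, "p_spin": res.p_spin,
                             "n_regions_used": res.n_regions_used,
                             "outliers_excluded": res.outliers_excluded}
            report["alignment"][approach] = rec
        report["stages"].append("alignment")

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for approach, cp in cp_matrices.items():
            np.savetxt(out / f"coupling_matrix_{approach}.txt", cp)
        for approach in regional:
            regional[approach].to_csv(out / f"regional_effects_{approach}.tsv",
                                      sep="\t")
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report


def run_repeated_cv(config: RunConfig, repeats: int = 10) -> dict:
    """Repeated two-fold cross-validation with role reversal.

    Each repeat draws a fresh random half-split and evaluates twice
    (train on each half, test on the other), so every subject is tested
    exactly once per repeat.  Aggregates mean and SD across all
    2*repeats fold evaluations of the global coupling, individual
    fraction, and axis-alignment rhos (GNN approach).
    """
    cohort = config.resolved_cohort()
    k = cohort.n_regions
    fcs = [s.fc for s in cohort.subjects]
    ids = list(range(cohort.n_subjects))
    ranks = cohort.regions["axis_rank"].to_numpy(dtype=float)

    fold_stats: list[dict] = []
    for rep in range(repeats):
        half_a, half_b = gnn.split_cohort(
            ids, fraction=0.5,
            seed=stage_seed(config.master_seed, "cv", extra=rep))
        for fold, (tr, te) in enumerate(((half_a, half_b), (half_b, half_a))):
            mask = consistency_mask([cohort.subjects[i].sc for i in tr],
                                    percentile=config.mask_percentile)
            masked = {i: mask.apply(cohort.subjects[i].sc) for i in tr + te}
            cfg = config.resolved_gnn_config(k).replace(
                seed=stage_seed(config.master_seed, "cv",
                                extra=1_000_000 + 2 * rep + fold))
            model, _ = gnn.train_model([masked[i] for i in tr],
                                       [fcs[i] for i in tr], cfg)
            preds = [gnn.predict_fc(masked[i], model) for i in te]
            cp = cpl.cross_coupling_matrix(preds, [fcs[i] for i in te], "gnn",
                                           sc_mask=mask.keep)
            dec = cpl.decompose(cp)
            maps = cpl.regional_effect_maps(preds, [fcs[i] for i in te],
                                            "gnn", sc_mask=mask.keep)
            stat = {"repeat": rep, "fold": fold,
                    "coupling_mean": dec.total,
                    "individual_fraction": dec.individual_fraction}
            for name in ("group", "individual"):
                vals = maps[name].to_numpy()
                keep = outlier_mask(vals, k=config.outlier_k)
                stat[f"rho_{name}"] = spearman_rho(vals[keep], ranks[keep])
            fold_stats.append(stat)

    agg = {}
    for key in ("coupling_mean", "individual_fraction", "rho_group",
                "rho_individual"):
        vals = np.array([s[key] for s in fold_stats])
        agg[key] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    return {"repeats": repeats, "n_folds": len(fold_stats),
            "folds": fold_stats, "aggregate": agg,
            "master_seed": config.master_seed}
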