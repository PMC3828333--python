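"""End-to-end orchestration: simulate/load -> preprocess -> cluster ->
compare -> enrich -> survival/transition -> markers -> matched mortality.

Every stage writes TSV/JSON intermediates into the output directory and is
recorded in a manifest (stage, outputs, seed, config hash, package version)
so single stages can be re-run and diffed.  The run is deterministic given
the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import feature_enrichment, results_frame
from .group_stats import subgroup_summary_table
from .markers import forward_select, permutation_auc_test
from .matched_mortality import matched_mortality_summary
from .panel_io import (
    global_nonzero_min,
    load_cohort,
    log10_view,
    resolve_censored,
    to_molar,
    write_assay_tsv,
    write_clinical_tsv,
)
from .subgrouping import cluster_rows
from .survival import g_rho_test, km_curve, transition_analysis
from .synthetic_cohort import generate_cohort, vasst_like

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One-object configuration for a full pipeline run."""

    out_dir: str
    seed: int = 0
    # either synthetic (n_patients used) or paths to real inputs
    synthetic: bool = True
    n_patients: int = 363
    assay_path: str | None = None
    clinical_path: str | None = None
    catalog_path: str | None = None
    k_baseline: int = 3
    k_late: int = 2
    distance: str = "euclidean"
    linkage: str = "ward"
    contrasts: list[list[str]] = field(default_factory=lambda: [["High", "Low"], ["High", "Medium"]])
    fdr: float = 0.05
    n_perm: int = 100
    n_iter: int = 100
    allow_products: bool = True
    reference_label: str = "High"
    # scope of the zero-replacement half-minimum: both timepoints jointly or per matrix
    joint_zero_minimum: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must be in (0, 1)")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": [],
    }

    def record(stage: str, outputs: list[str]) -> None:
        manifest["stages"].append({"stage": stage, "outputs": outputs})
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    try:
        # --- stage: inputs -------------------------------------------------
        if config.synthetic:
            spec = vasst_like(n_patients=config.n_patients, seed=config.seed)
            baseline, late, clinical, true_labels = generate_cohort(spec)
            catalog = spec.catalog
            write_assay_tsv({"baseline": baseline, "24h": late}, out / "assay.tsv")
            write_clinical_tsv(clinical, out / "clinical.tsv")
            true_labels.to_csv(out / "true_labels.tsv", sep="\t")
            record("simulate", ["assay.tsv", "clinical.tsv", "true_labels.tsv"])
        else:
            if not config.assay_path or not config.clinical_path:
                raise FileNotFoundError("assay_path and clinical_path required")
            matrices, clinical, catalog = load_cohort(
                config.assay_path, config.clinical_path, config.catalog_path
            )
            baseline, late = matrices["baseline"], matrices["24h"]
            record("load", [])

        # --- stage: preprocess --------------------------------------------
        if config.joint_zero_minimum:
            half_min = global_nonzero_min(baseline, late) / 2.0
            baseline_r = resolve_censored(baseline, zero_fill=half_min)
            late_r = resolve_censored(late, zero_fill=half_min)
        else:
            baseline_r = resolve_censored(baseline)
            late_r = resolve_censored(late)
        molar = {
            "baseline": to_molar(baseline_r, catalog),
            "24h": to_molar(late_r, catalog),
        }
        for tp, m in molar.items():
            log10_view(m).to_csv(out / f"log10_pM_{tp}.tsv", sep="\t")
        record("preprocess", [f"log10_pM_{tp}.tsv" for tp in molar])

        # --- stage: clustering ---------------------------------------------
        assignments = {}
        for tp, k in (("baseline", config.k_baseline), ("24h", config.k_late)):
            a = cluster_rows(
                log10_view(molar[tp]),
                distance=config.distance,
                linkage_method=config.linkage,
                k=k,
            )
            assignments[tp] = a
            pd.DataFrame(
                {"cluster_index": a.clusters, "label": a.labels}
            ).rename_axis("patient_id").to_csv(out / f"subgroups_{tp}.tsv", sep="\t")
            pd.DataFrame(
                a.linkage_record, columns=["child_a", "child_b", "height", "size"]
            ).to_csv(out / f"dendrogram_{tp}.tsv", sep="\t", index=False)
        record("cluster", [f"subgroups_{tp}.tsv" for tp in assignments])

        # --- stage: comparison tables ---------------------------------------
        for tp, a in assignments.items():
            contrasts = [
                (hi, lo)
                for hi, lo in (tuple(c) for c in config.contrasts)
                if hi in a.label_order and lo in a.label_order
            ]
            if contrasts:
                table = subgroup_summary_table(molar[tp], a, contrasts)
                table.to_csv(out / f"comparison_{tp}.tsv", sep="\t", index=False)
        record("compare", [f"comparison_{tp}.tsv" for tp in assignments])

        # --- stage: enrichment ----------------------------------------------
        for tp, a in assignments.items():
            res = results_frame(feature_enrichment(clinical, a), fdr=config.fdr)
            res.to_csv(out / f"enrichment_{tp}.tsv", sep="\t", index=False)
        record("enrich", [f"enrichment_{tp}.tsv" for tp in assignments])

        # --- stage: survival -------------------------------------------------
        surv_out = []
        for tp, a in assignments.items():
            curves = []
            for label in a.label_order:
                ids = a.members(label)
                curve = km_curve(
                    clinical.table.loc[ids, "survival_time"],
                    clinical.table.loc[ids, "event"],
                )
                curve.insert(0, "label", label)
                curves.append(curve)
            pd.concat(curves).to_csv(out / f"km_{tp}.tsv", sep="\t", index=False)
            ids = a.patient_ids
            res = g_rho_test(
                clinical.table.loc[ids, "survival_time"],
                clinical.table.loc[ids, "event"],
                a.labels.loc[ids],
            )
            surv_out.append(
                {"timepoint": tp, "chisq": res.chisq, "df": res.df, "p": res.p}
            )
        pd.DataFrame(surv_out).to_csv(out / "logrank.tsv", sep="\t", index=False)
        trans = transition_analysis(assignments["baseline"], assignments["24h"], clinical)
        trans.table.to_csv(out / "transitions.tsv", sep="\t", index=False)
        record("survival", ["logrank.tsv", "transitions.tsv"])

        # --- stage: marker models --------------------------------------------
        marker_report = {}
        for tp, a in assignments.items():
            for label in a.label_order:
                model = forward_select(
                    molar[tp], a, label, allow_products=config.allow_products
                )
                entry = {
                    "terms": [t.__dict__ for t in model.terms],
                    "intercept": model.intercept,
                    "intercept_se": model.intercept_se,
                    "auc": model.auc,
                    "converged": model.converged,
                }
                if model.terms and config.n_perm:
                    perm = permutation_auc_test(
                        molar[tp], a, label, model.term_ids,
                        n_perm=config.n_perm, seed=config.seed,
                    )
                    entry["permutation"] = {
                        "null_mean": perm.null_mean,
                        "null_sd": perm.null_sd,
                        "null_max": perm.null_max,
                        "p_empirical": perm.p_empirical,
                    }
                marker_report[f"{tp}:{label}"] = entry
        with open(out / "markers.json", "w") as fh:
            json.dump(marker_report, fh, indent=2)
        record("markers", ["markers.json"])

        # --- stage: matched mortality ----------------------------------------
        matched_rows = []
        for tp, a in assignments.items():
            if config.reference_label not in a.label_order:
                continue
            summary = matched_mortality_summary(
                a, clinical, config.reference_label,
                n_iter=config.n_iter, seed=config.seed,
            )
            s = summary.summary.copy()
            s.insert(0, "timepoint", tp)
            s["n_matched_per_subgroup"] = summary.n_matched_per_subgroup
            matched_rows.append(s)
        if matched_rows:
            pd.concat(matched_rows).to_csv(out / "matched.tsv", sep="\t", index=False)
        record("matched", ["matched.tsv"])
    except Exception as exc:
        manifest["error"] = {"stage": "aborted", "cause": repr(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise

    return manifest
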