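"""Pipeline orchestration, table rendering and run manifests.

``run_pipeline`` executes the full analysis on a counts + metadata pair
(or a freshly simulated cohort): exclusion cascade, alpha diversity and
rarefaction, species- and genus-level NB screens with FPRP/BFDP
noteworthiness, the disease interaction analyses for the configured
etiologic sets, and the prevalence cross-tabulation. Every stage's row
accounting and every seed land in a machine-readable manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential_abundance import screen_all_taxa
from .disease_association import (combined_set_model, prevalence_table,
                                  screen_disease_associations)
from .diversity import cohort_rarefaction, diversity_group_tests, \
    alpha_diversity_table
from .filtering import apply_all_filters
from .io_model import CountMatrix, SampleFrame, align, write_counts, \
    write_metadata
from .noteworthiness import annotate_noteworthiness

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "min_reads": 200,
    "min_rel_abund": 1e-5,
    "min_subjects": 10,
    "q": 0.05,
    "shannon_base": 2.0,
    "rarefaction_min_total": 65000,
    "rarefaction_depths": [1000, 5000, 10000, 25000, 50000, 65000],
    "priors": [0.001, 0.01, 0.05],
    "rr1": 1.5,
    "genus_mode": "genus_only",
    "outcomes": ["periodontitis", "caries"],
    "etiologic_sets": {},        # outcome -> list of taxon ids
}


def render_or(or_value, ci) -> str:
    """Render an odds ratio with CI, or the literal ``Undefined``."""
    if or_value is None or not np.isfinite(or_value):
        return "Undefined"
    return f"{or_value:.2f} ({ci[0]:.2f}, {ci[1]:.2f})"


def render_disease_table(df: pd.DataFrame) -> pd.DataFrame:
    """Human-readable layout: taxon, per-group OR (95% CI), interaction p."""
    rows = []
    for _, r in df.iterrows():
        rows.append({
            "taxon": r["taxon_id"],
            "pheu_or_95ci": render_or(r["or_pheu"], r["ci_pheu"]),
            "phiv_or_95ci": render_or(r["or_phiv"], r["ci_phiv"]),
            "interaction_p": ("Undefined" if r["degenerate"]
                              else f"{r['interaction_p']:.3g}"),
        })
    return pd.DataFrame(rows,
                        columns=["taxon", "pheu_or_95ci", "phiv_or_95ci",
                                 "interaction_p"])


def render_prevalence_table(tab: pd.DataFrame) -> pd.DataFrame:
    out = tab.copy()
    out["n_percent"] = [f"{r.n} ({r.percent:.1f})" for r in out.itertuples()]
    return out[["group", "periodontitis", "caries", "n_percent"]]


def run_pipeline(cm: CountMatrix, sf: SampleFrame, out_dir,
                 config: dict | None = None, seed: int = 0) -> Path:
    """Run every stage and write outputs + manifest under ``out_dir``."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": seed, "config": _jsonable(cfg),
                "started": time.strftime("%Y-%m-%dT%H:%M:%S"), "stages": []}
    stage = None
    try:
        stage = "align"
        cm, sf = align(cm, sf)
        manifest["stages"].append({"stage": stage, "n_samples": sf.n_samples,
                                   "n_taxa": cm.n_taxa})

        stage = "filtering"
        cm, sf, reports = apply_all_filters(
            cm, sf, min_reads=cfg["min_reads"],
            min_rel_abund=cfg["min_rel_abund"],
            min_subjects=cfg["min_subjects"])
        with open(out_dir / "filter_report.json", "w") as fh:
            json.dump([r.to_dict() for r in reports], fh, indent=1)
        manifest["stages"].append({"stage": stage,
                                   "reports": [{k: v for k, v in r.to_dict().items()
                                                if k != "removed_ids"}
                                               for r in reports],
                                   "n_samples": sf.n_samples,
                                   "n_taxa": cm.n_taxa})

        stage = "diversity"
        div = alpha_diversity_table(cm, base=cfg["shannon_base"])
        div.to_csv(out_dir / "alpha_diversity.tsv", sep="\t", index=False)
        tests = diversity_group_tests(cm, sf, base=cfg["shannon_base"])
        with open(out_dir / "diversity_tests.json", "w") as fh:
            json.dump({m: dataclasses.asdict(c) for m, c in tests.items()},
                      fh, indent=1)
        rar = cohort_rarefaction(cm, cfg["rarefaction_depths"],
                                 min_total=cfg["rarefaction_min_total"])
        rar.to_csv(out_dir / "rarefaction.tsv", sep="\t", index=False)
        manifest["stages"].append({"stage": stage, "n_samples": len(div),
                                   "n_rarefied": rar["sample_id"].nunique()
                                   if len(rar) else 0})

        for level in ("species", "genus"):
            stage = f"diffabund_{level}"
            da = screen_all_taxa(cm, sf, level=level, q=cfg["q"],
                                 genus_mode=cfg["genus_mode"])
            da = annotate_noteworthiness(da, priors=tuple(cfg["priors"]),
                                         rr1=cfg["rr1"])
            da.to_csv(out_dir / f"diffabund_{level}.tsv", sep="\t", index=False)
            manifest["stages"].append({
                "stage": stage, "n_taxa": len(da),
                "n_converged": int(da["converged"].sum()),
                "n_bh_significant": int(da["bh_significant"].sum()),
                "n_noteworthy": int(da["noteworthy"].sum())})

        for outcome in cfg["outcomes"]:
            stage = f"disease_{outcome}"
            sets = cfg["etiologic_sets"].get(outcome)
            if sets:
                df = screen_disease_associations(outcome, cm, sf, taxa=sets)
                combined = combined_set_model(outcome, cm, sets, sf,
                                              set_name="all_combined")
                df = pd.concat([df, pd.DataFrame([{
                    "taxon_id": "all_combined", "outcome": outcome,
                    "or_pheu": combined.or_group0, "ci_pheu": combined.ci_group0,
                    "or_phiv": combined.or_group1, "ci_phiv": combined.ci_group1,
                    "interaction_log_or": combined.interaction_log_or,
                    "interaction_p": combined.interaction_p,
                    "degenerate": combined.degenerate}])],
                    ignore_index=True)
            else:
                df = screen_disease_associations(outcome, cm, sf)
            render_disease_table(df).to_csv(
                out_dir / f"disease_{outcome}.tsv", sep="\t", index=False)
            manifest["stages"].append({
                "stage": stage, "n_models": len(df),
                "n_degenerate": int(df["degenerate"].sum())})

        stage = "prevalence"
        tab = prevalence_table(sf)
        render_prevalence_table(tab).to_csv(out_dir / "prevalence.tsv",
                                            sep="\t", index=False)
        manifest["stages"].append({"stage": stage, "n_cells": len(tab)})
    except Exception:
        manifest["failed_stage"] = stage
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out_dir


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))


def write_cohort(cm: CountMatrix, sf: SampleFrame, truth, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_counts(cm, out_dir / "counts.tsv")
    write_metadata(sf, out_dir / "metadata.tsv")
    truth.to_json(out_dir / "truth.json")
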