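"""Sample- and taxon-exclusion rules, applied in a fixed order.

Order: (1) exclude samples flagged for antibiotic use in the prior 3
months; (2) drop samples with fewer than 200 reads; (3) drop taxa whose
pooled relative abundance (taxon total / grand total) is below 1e-5;
(4) drop taxa present (count > 0) in fewer than 10 subjects. Each step
returns a :class:`FilterReport` with conserved accounting
(in = out + removed) and the removed ids.

An optional ``UNMATCHED`` row (reads the upstream classifier could not
assign) is dropped with a logged count before any taxon rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_model import CountMatrix, SampleFrame

logger = logging.getLogger(__name__)

UNMATCHED_ID = "UNMATCHED"


@dataclass
class FilterReport:
    rule: str
    axis: str                      # "samples" or "taxa"
    n_in: int
    n_out: int
    removed_ids: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_in - len(self.removed_ids) == self.n_out, \
            "filter accounting not conserved"

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)

    def to_dict(self) -> dict:
        return {"rule": self.rule, "axis": self.axis, "n_in": self.n_in,
                "n_out": self.n_out, "n_removed": self.n_removed,
                "removed_ids": list(self.removed_ids), **self.extra}


def exclude_antibiotic_samples(sf: SampleFrame, cm: CountMatrix | None = None):
    """Remove samples with antibiotic use in the prior 3 months.

    Returns (SampleFrame, CountMatrix | None, FilterReport). The count
    matrix, when given, is restricted to the retained samples.
    """
    flags = sf.data["antibiotic_past_3mo"] == 1
    removed = sf.data.loc[flags, "sample_id"].tolist()
    kept = sf.data.loc[~flags, "sample_id"].tolist()
    per_group = (sf.data.loc[flags].groupby("group", observed=True)
                 .size().to_dict())
    report = FilterReport("antibiotic_past_3mo", "samples",
                          sf.n_samples, len(kept), removed,
                          extra={"removed_by_group": per_group})
    if not kept:
        logger.error("antibiotic filter removed every sample")
    sf_out = sf.select_samples(kept)
    cm_out = cm.select_samples([s for s in cm.samples if s in set(kept)]) \
        if cm is not None else None
    return sf_out, cm_out, report


def drop_low_read_samples(cm: CountMatrix, min_reads: int = 200):
    """Remove samples whose column sum is strictly below ``min_reads``."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    totals = cm.sample_totals()
    removed = totals.index[totals < min_reads].tolist()
    kept = totals.index[totals >= min_reads].tolist()
    report = FilterReport(f"reads<{min_reads}", "samples",
                          cm.n_samples, len(kept), removed)
    return cm.select_samples(kept), report


def drop_rare_taxa_rel_abund(cm: CountMatrix, threshold: float = 1e-5):
    """Remove taxa with pooled relative abundance strictly below threshold.

    Pooled relative abundance = taxon total across all samples / grand
    total; a taxon exactly at the threshold is retained.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0,1)")
    taxon_totals = cm.counts.sum(axis=1)
    grand = taxon_totals.sum()
    rel = taxon_totals / grand
    removed = rel.index[rel < threshold].tolist()
    kept = rel.index[rel >= threshold].tolist()
    report = FilterReport(f"rel_abund<{threshold:g}", "taxa",
                          cm.n_taxa, len(kept), removed)
    return cm.select_taxa(kept), report


def drop_low_prevalence_taxa(cm: CountMatrix, min_subjects: int = 10):
    """Remove taxa with a nonzero count in fewer than ``min_subjects``
    samples (both groups combined)."""
    if min_subjects < 1:
        raise ValueError("min_subjects must be >= 1")
    prevalence = (cm.counts > 0).sum(axis=1)
    removed = prevalence.index[prevalence < min_subjects].tolist()
    kept = prevalence.index[prevalence >= min_subjects].tolist()
    report = FilterReport(f"prevalence<{min_subjects}", "taxa",
                          cm.n_taxa, len(kept), removed)
    return cm.select_taxa(kept), report


def drop_unmatched_row(cm: CountMatrix):
    """Drop the optional UNMATCHED bucket row, logging its read total."""
    if UNMATCHED_ID not in cm.counts.index:
        report = FilterReport("unmatched_row", "taxa", cm.n_taxa, cm.n_taxa, [])
        return cm, report
    n_reads = int(cm.counts.loc[UNMATCHED_ID].sum())
    logger.info("dropping UNMATCHED row (%d reads)", n_reads)
    kept = [t for t in cm.taxon_ids if t != UNMATCHED_ID]
    report = FilterReport("unmatched_row", "taxa", cm.n_taxa, len(kept),
                          [UNMATCHED_ID], extra={"unmatched_reads": n_reads})
    return cm.select_taxa(kept), report


def apply_all_filters(cm: CountMatrix, sf: SampleFrame,
                      min_reads: int = 200, min_rel_abund: float = 1e-5,
                      min_subjects: int = 10):
    """Run the full exclusion cascade in the declared order.

    Returns (CountMatrix, SampleFrame, list[FilterReport]).
    """
    reports = []
    sf, cm, rep = exclude_antibiotic_samples(sf, cm)
    reports.append(rep)
    cm, rep = drop_unmatched_row(cm)
    reports.append(rep)
    cm, rep = drop_low_read_samples(cm, min_reads)
    reports.append(rep)
    sf = sf.select_samples(cm.samples)
    cm, rep = drop_rare_taxa_rel_abund(cm, min_rel_abund)
    reports.append(rep)
    cm, rep = drop_low_prevalence_taxa(cm, min_subjects)
    reports.append(rep)
    return cm, sf, reports
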