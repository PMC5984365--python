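"""Disease-association interaction analysis.

Logistic regression of a binary oral-disease outcome (periodontitis or
caries) on HIV group, a taxon's log10-transformed count, their
multiplicative interaction, the adjustment covariates, and log10 total
sample counts. Zeros are replaced with half the taxon's minimum non-zero
value before the log10 transform (half-minimum computed across all
included samples, both groups pooled).

Reported per group as odds ratios per tenfold increase in counts:
OR(PHEU) = exp(b_taxon), OR(PHIV) = exp(b_taxon + b_interaction), each
with a Wald 95% CI, plus the Wald p-value of the interaction term.
Separated or otherwise degenerate fits are flagged and rendered
"Undefined" rather than raising.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .differential_abundance import DEFAULT_COVARIATES
from .io_model import CountMatrix, SampleFrame

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054


@dataclass
class DiseaseAssocResult:
    taxon_or_set: str
    outcome: str
    or_group0: float | None          # PHEU, per tenfold count increase
    ci_group0: tuple | None
    or_group1: float | None          # PHIV
    ci_group1: tuple | None
    interaction_log_or: float | None
    interaction_p: float | None
    degenerate: bool = False

    @classmethod
    def undefined(cls, taxon_or_set: str, outcome: str) -> "DiseaseAssocResult":
        return cls(taxon_or_set, outcome, None, None, None, None, None, None,
                   degenerate=True)


def log10_halfmin_transform(counts) -> np.ndarray:
    """log10 of counts with zeros replaced by half the minimum non-zero value.

    Strictly increasing on the original values, so ranks are preserved.
    """
    x = np.asarray(counts, dtype=float)
    nz = x[x > 0]
    if nz.size == 0:
        raise ValueError("all-zero taxon (should have been filtered)")
    return np.log10(np.where(x == 0, nz.min() / 2.0, x))


def _logit_design(sf: SampleFrame, taxon_log10: np.ndarray,
                  covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    g = sf.group_indicator()
    X = pd.DataFrame({
        "const": 1.0,
        "group": g.astype(float),
        "taxon": taxon_log10,
        "group_x_taxon": g * taxon_log10,
    }, index=sf.data.index)
    for c in covariates:
        X[c] = sf.data[c].astype(float)
    X["log10_total_reads"] = np.log10(sf.data["total_reads"].astype(float))
    return X


def fit_interaction_model(outcome_name: str, taxon_counts, sf: SampleFrame,
                          taxon_id: str = "",
                          covariates=DEFAULT_COVARIATES) -> DiseaseAssocResult:
    """Fit the group × taxon interaction logistic model for one taxon."""
    y = sf.data[outcome_name].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome_name!r} has a single class")
    t = log10_halfmin_transform(taxon_counts)
    X = _logit_design(sf, t, covariates)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200, method="newton")
    except Exception as exc:  # separation raises PerfectSeparationError
        logger.info("logistic fit degenerate for %s/%s: %s",
                    taxon_id, outcome_name, exc)
        return DiseaseAssocResult.undefined(taxon_id, outcome_name)
    if not _logit_ok(res):
        return DiseaseAssocResult.undefined(taxon_id, outcome_name)

    b = res.params
    cov = res.cov_params()
    b_t, b_i = float(b["taxon"]), float(b["group_x_taxon"])
    se_t = float(np.sqrt(cov.loc["taxon", "taxon"]))
    var1 = (cov.loc["taxon", "taxon"] + cov.loc["group_x_taxon", "group_x_taxon"]
            + 2 * cov.loc["taxon", "group_x_taxon"])
    se1 = float(np.sqrt(var1))
    se_i = float(np.sqrt(cov.loc["group_x_taxon", "group_x_taxon"]))
    p_int = float(2 * stats.norm.sf(abs(b_i / se_i)))
    return DiseaseAssocResult(
        taxon_or_set=taxon_id, outcome=outcome_name,
        or_group0=float(np.exp(b_t)),
        ci_group0=(float(np.exp(b_t - Z975 * se_t)),
                   float(np.exp(b_t + Z975 * se_t))),
        or_group1=float(np.exp(b_t + b_i)),
        ci_group1=(float(np.exp(b_t + b_i - Z975 * se1)),
                   float(np.exp(b_t + b_i + Z975 * se1))),
        interaction_log_or=b_i, interaction_p=p_int, degenerate=False)


def _logit_ok(res) -> bool:
    if not res.mle_retvals.get("converged", False):
        return False
    bse = np.asarray(res.bse)
    params = np.asarray(res.params)
    return bool(np.all(np.isfinite(bse)) and np.all(bse < 1e2)
                and np.all(np.abs(params) < 50))


def combined_set_model(outcome_name: str, cm: CountMatrix, taxon_set,
                       sf: SampleFrame, set_name: str = "combined",
                       covariates=DEFAULT_COVARIATES) -> DiseaseAssocResult:
    """Interaction model on the summed counts of a named etiologic set."""
    taxon_set = list(taxon_set)
    if not taxon_set:
        raise ValueError("empty taxon set")
    missing = [t for t in taxon_set if t not in set(cm.taxon_ids)]
    if missing:
        logger.warning("set %s: %d/%d taxa missing from count matrix: %s",
                       set_name, len(missing), len(taxon_set), missing)
    present = [t for t in taxon_set if t not in set(missing)]
    if not present:
        raise ValueError(f"no taxa of set {set_name!r} in the count matrix")
    summed = cm.counts.loc[present].sum(axis=0).to_numpy()
    res = fit_interaction_model(outcome_name, summed, sf, taxon_id=set_name,
                                covariates=covariates)
    return res


def screen_disease_associations(outcome_name: str, cm: CountMatrix,
                                sf: SampleFrame, taxa=None,
                                covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Interaction models for each taxon (default: all taxa in the matrix)."""
    taxa = list(taxa) if taxa is not None else cm.taxon_ids
    rows = []
    for t in taxa:
        r = fit_interaction_model(outcome_name, cm.counts.loc[t].to_numpy(),
                                  sf, taxon_id=t, covariates=covariates)
        rows.append({
            "taxon_id": t, "outcome": outcome_name,
            "or_pheu": r.or_group0, "ci_pheu": r.ci_group0,
            "or_phiv": r.or_group1, "ci_phiv": r.ci_group1,
            "interaction_log_or": r.interaction_log_or,
            "interaction_p": r.interaction_p, "degenerate": r.degenerate})
    return pd.DataFrame(rows)


def prevalence_table(sf: SampleFrame) -> pd.DataFrame:
    """Group × periodontitis × caries cross-tabulation with within-group
    percentages.

    One row per (group, periodontitis, caries) cell with ``n`` and
    ``percent`` (denominator = group size).
    """
    df = sf.data
    rows = []
    for group in sorted(df["group"].unique()):
        sub = df[df["group"] == group]
        denom = len(sub)
        for perio in (0, 1):
            for caries in (0, 1):
                n = int(((sub["periodontitis"] == perio)
                         & (sub["caries"] == caries)).sum())
                rows.append({"group": group, "periodontitis": perio,
                             "caries": caries, "n": n,
                             "percent": 100.0 * n / denom if denom else np.nan,
                             "group_n": denom})
    return pd.DataFrame(rows)


def group_prevalence(sf: SampleFrame, outcome: str) -> dict:
    """Per-group prevalence (%) of one outcome."""
    df = sf.data
    out = {}
    for group, sub in df.groupby("group", observed=True):
        out[group] = 100.0 * float(sub[outcome].mean())
    return out
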