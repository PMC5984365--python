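"""Per-taxon negative-binomial group comparison.

For each taxon, counts are modeled with an NB2 negative-binomial
regression (log link, dispersion estimated by maximum likelihood jointly
with the coefficients) on a group indicator (PHIV vs PHEU reference) plus
adjustment covariates: age, sex, dental visit in the past year, race
(white vs other), ethnicity (Hispanic vs not), and total sequencing reads
(entered log-transformed with a free coefficient by default; an offset
mode fixes its coefficient at 1). The exponentiated group coefficient is
the rate ratio — the fold change in mean counts between groups — with a
Wald 95% CI and two-sided p-value. Multiplicity is controlled with the
Benjamini–Hochberg step-up procedure at q = 0.05, separately within the
species-level and genus-level families.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import CountMatrix, SampleFrame

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "dental_visit_past_year",
                      "race_white", "ethnicity_hispanic")


@dataclass
class DiffAbundResult:
    taxon_id: str
    level: str                      # "species" | "genus"
    rate_ratio: float               # exp(theta_hat), PHIV vs PHEU
    log_rr: float
    se: float
    ci95: tuple
    p_value: float
    dispersion: float               # NB size parameter k_hat = 1/alpha_hat
    converged: bool
    bh_significant: bool | None = None
    p_adjusted: float | None = None

    @classmethod
    def failed(cls, taxon_id: str, level: str) -> "DiffAbundResult":
        return cls(taxon_id, level, np.nan, np.nan, np.nan,
                   (np.nan, np.nan), np.nan, np.nan, False)


def _design_matrix(sf: SampleFrame, covariates, total_reads_mode: str):
    X = pd.DataFrame({"const": 1.0, "group": sf.group_indicator()},
                     index=sf.data.index)
    for c in covariates:
        X[c] = sf.data[c].astype(float)
    offset = None
    if total_reads_mode == "covariate":
        X["log_total_reads"] = np.log(sf.data["total_reads"].astype(float))
    elif total_reads_mode == "offset":
        offset = np.log(sf.data["total_reads"].astype(float)).to_numpy()
    elif total_reads_mode != "none":
        raise ValueError(f"unknown total_reads_mode {total_reads_mode!r}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if corr.size else ("?", "?")
        raise ValueError(f"rank-deficient design matrix; near-collinear "
                         f"columns include {worst}")
    return X, offset


def fit_taxon_nb(counts, sf: SampleFrame, taxon_id: str = "",
                 level: str = "species",
                 covariates=DEFAULT_COVARIATES,
                 total_reads_mode: str = "covariate") -> DiffAbundResult:
    """Fit the NB2 regression for one taxon; never raises on non-convergence.

    ``total_reads_mode``: "covariate" (log total reads with a free
    coefficient, the default), "offset" (coefficient fixed at 1), or
    "none" (omit).
    """
    y = np.asarray(counts, dtype=float)
    X, offset = _design_matrix(sf, covariates, total_reads_mode)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.NegativeBinomial(y, X, offset=offset,
                                        loglike_method="nb2")
            res = model.fit(disp=0, maxiter=200)
            if not _converged(res):
                res = model.fit(disp=0, method="bfgs", maxiter=500,
                                start_params=res.params)
    except Exception as exc:  # optimizer/linalg failure
        logger.warning("NB fit failed for %s: %s", taxon_id, exc)
        return DiffAbundResult.failed(taxon_id, level)
    if not _converged(res):
        logger.warning("NB fit did not converge for %s", taxon_id)
        return DiffAbundResult.failed(taxon_id, level)
    theta = float(res.params["group"])
    se = float(res.bse["group"])
    z = theta / se
    p = float(2 * stats.norm.sf(abs(z)))
    alpha = float(res.params.get("alpha", np.nan))
    k_hat = 1.0 / alpha if alpha > 0 else np.inf
    return DiffAbundResult(
        taxon_id=taxon_id, level=level,
        rate_ratio=float(np.exp(theta)), log_rr=theta, se=se,
        ci95=(float(np.exp(theta - 1.959963984540054 * se)),
              float(np.exp(theta + 1.959963984540054 * se))),
        p_value=max(p, np.finfo(float).tiny), dispersion=k_hat,
        converged=True)


def _converged(res) -> bool:
    ok = bool(res.mle_retvals.get("converged", False))
    se = res.bse["group"] if "group" in res.bse else np.nan
    return ok and np.isfinite(se) and 0 < se < 1e3


def bh_adjust(p_values, q: float = 0.05):
    """Benjamini–Hochberg step-up decisions and adjusted p-values.

    NaN entries (non-converged fits) are excluded from the family with a
    logged count and returned as non-significant with NaN adjusted p.
    Returns (reject: bool array, p_adjusted: float array).
    """
    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    if (~ok).sum():
        logger.info("bh_adjust: excluding %d NaN p-values from the family",
                    int((~ok).sum()))
    reject = np.zeros(p.shape, dtype=bool)
    p_adj = np.full(p.shape, np.nan)
    if ok.sum():
        rej, adj, *_ = multipletests(p[ok], alpha=q, method="fdr_bh")
        reject[ok] = rej
        p_adj[ok] = adj
    return reject, p_adj


def aggregate_genus(cm: CountMatrix, mode: str = "genus_only") -> CountMatrix:
    """Collapse a species-level matrix to genus level.

    ``mode="genus_only"`` keeps, for each genus, only the reads *not*
    classified to species (the genus-only rows; genera lacking such a row
    are omitted). ``mode="total"`` sums every row of the genus.
    """
    tax = cm.taxonomy
    if mode == "genus_only":
        keep = tax.index[tax["species"] == ""]
        sub = cm.counts.loc[keep].copy()
        sub.index = pd.Index(tax.loc[keep, "genus"], name="taxon_id")
        counts = sub.groupby(level=0).sum()
    elif mode == "total":
        grp = cm.counts.groupby(tax["genus"].to_numpy()).sum()
        grp.index.name = "taxon_id"
        counts = grp
    else:
        raise ValueError(f"unknown genus aggregation mode {mode!r}")
    counts = counts.loc[counts.index != ""]
    taxonomy = pd.DataFrame({"genus": counts.index, "species": ""},
                            index=counts.index)
    return CountMatrix(counts.astype(np.int64), taxonomy)


def screen_all_taxa(cm: CountMatrix, sf: SampleFrame, level: str = "species",
                    q: float = 0.05, genus_mode: str = "genus_only",
                    covariates=DEFAULT_COVARIATES,
                    total_reads_mode: str = "covariate") -> pd.DataFrame:
    """Fit the NB screen for every taxon at the requested level.

    Returns a DataFrame (one row per taxon) with rate ratios, Wald CIs,
    p-values and BH decisions at level ``q``; non-converged taxa carry NaN
    estimates and are excluded from the BH family.
    """
    if level == "genus":
        cm = aggregate_genus(cm, mode=genus_mode)
    elif level != "species":
        raise ValueError(f"unknown level {level!r}")
    results = []
    for t in cm.taxon_ids:
        res = fit_taxon_nb(cm.counts.loc[t].to_numpy(), sf, taxon_id=t,
                           level=level, covariates=covariates,
                           total_reads_mode=total_reads_mode)
        results.append(res)
    df = pd.DataFrame([{
        "taxon_id": r.taxon_id, "level": r.level, "rate_ratio": r.rate_ratio,
        "log_rr": r.log_rr, "se": r.se, "ci_low": r.ci95[0],
        "ci_high": r.ci95[1], "p_value": r.p_value,
        "dispersion": r.dispersion, "converged": r.converged,
    } for r in results])
    n_failed = int((~df["converged"]).sum())
    if n_failed:
        logger.warning("%d/%d taxa did not converge", n_failed, len(df))
    reject, p_adj = bh_adjust(df["p_value"].where(df["converged"]), q=q)
    df["p_adjusted"] = p_adj
    df["bh_significant"] = reject
    return df
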