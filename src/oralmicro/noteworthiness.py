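"""False positive report probability (FPRP) and Bayesian false discovery
probability (BFDP).

Both quantify the chance that a "significant" association is a false
positive, combining the observed evidence with a prior probability pi
that the association is real.

FPRP uses the observed two-sided p-value alpha and the power 1-beta of a
level-alpha two-sided z test at an alternative log rate ratio theta1
(|ln RR1|, RR1 = 1.5 by default):

    FPRP = alpha (1 - pi) / [ alpha (1 - pi) + (1 - beta) pi ]

BFDP compares a point null to a normal prior N(0, W) on the log rate
ratio via the approximate Bayes factor for an estimate theta_hat with
standard error SE (V = SE^2, z = theta_hat / SE):

    ABF  = sqrt((V + W) / V) * exp( -z^2 W / (2 (V + W)) )
    BFDP = ABF * PO / (1 + ABF * PO),   PO = (1 - pi) / pi

The default prior variance W places the 97.5th percentile of the prior
rate-ratio distribution at 1.5: W = (ln 1.5 / 1.96)^2.

A BH-significant taxon is flagged *noteworthy* (at pi = 0.01) when
(1) both FPRP and BFDP are < 0.5, or (2) FPRP < 0.2, or (3) BFDP < 0.2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PRIORS = (0.001, 0.01, 0.05)
DEFAULT_RR1 = 1.5
FLAG_PRIOR = 0.01


def default_prior_variance(rr1: float = DEFAULT_RR1) -> float:
    """Prior variance W with the 97.5th prior percentile of RR at ``rr1``."""
    return (np.log(rr1) / stats.norm.ppf(0.975)) ** 2


def power_at_alternative(alpha: float, se: float, theta1: float) -> float:
    """Power of a two-sided level-``alpha`` z test at alternative ``theta1``.

    1 - beta = 1 - Phi(c - theta1/SE) + Phi(-c - theta1/SE),
    c = Phi^{-1}(1 - alpha/2). Symmetric in the sign of theta1.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0,1]")
    if se <= 0:
        raise ValueError("se must be > 0")
    # isf/sf forms stay accurate for the tiny observed p-values the NB
    # screen produces (ppf(1 - a/2) and 1 - cdf both underflow there)
    c = stats.norm.isf(alpha / 2)
    shift = theta1 / se
    return float(stats.norm.sf(c - shift) + stats.norm.cdf(-c - shift))


def fprp(alpha: float, se: float, prior: float,
         rr1: float = DEFAULT_RR1) -> float:
    """FPRP at the observed p-value ``alpha`` for one association."""
    if not 0 < prior <= 1:
        raise ValueError("prior must be in (0,1]")
    if prior == 1:
        return 0.0
    power = power_at_alternative(alpha, se, abs(np.log(rr1)))
    num = alpha * (1 - prior)
    return float(num / (num + power * prior))


def bfdp(theta_hat: float, se: float, prior: float,
         w: float | None = None):
    """Approximate Bayes factor and BFDP for one log-rate-ratio estimate.

    Returns (abf, bfdp). ``w`` defaults to the 1.5-anchored prior
    variance; ``w = 0`` degenerates to ABF = 1 and BFDP = 1 - prior.
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    if not 0 < prior < 1:
        raise ValueError("prior must be in (0,1)")
    if w is None:
        w = default_prior_variance()
    if w < 0:
        raise ValueError("prior variance w must be >= 0")
    v = se ** 2
    z = theta_hat / se
    abf = float(np.sqrt((v + w) / v) * np.exp(-z ** 2 * w / (2 * (v + w))))
    po = (1 - prior) / prior
    val = abf * po
    return abf, float(val / (1 + val))


def flag_noteworthy(bh_significant: bool, fprp_value: float,
                    bfdp_value: float) -> bool:
    """Composite noteworthiness rule (evaluated at pi = 0.01)."""
    if not bh_significant:
        return False
    return bool((fprp_value < 0.5 and bfdp_value < 0.5)
                or fprp_value < 0.2 or bfdp_value < 0.2)


def annotate_noteworthiness(diffabund: pd.DataFrame,
                            priors=DEFAULT_PRIORS,
                            rr1: float = DEFAULT_RR1,
                            w: float | None = None) -> pd.DataFrame:
    """Append FPRP/BFDP columns (one per prior) and the noteworthy flag
    to a differential-abundance result table.

    Rows with NaN estimates (non-converged fits) get NaN probabilities
    and are never noteworthy.
    """
    if w is None:
        w = default_prior_variance(rr1)
    out = diffabund.copy()
    for pi in priors:
        tag = f"{pi:g}"
        fcol, bcol = [], []
        for _, row in out.iterrows():
            if not np.isfinite(row["p_value"]) or not np.isfinite(row["se"]):
                fcol.append(np.nan)
                bcol.append(np.nan)
                continue
            fcol.append(fprp(row["p_value"], row["se"], pi, rr1=rr1))
            bcol.append(bfdp(row["log_rr"], row["se"], pi, w=w)[1])
        out[f"fprp_pi{tag}"] = fcol
        out[f"bfdp_pi{tag}"] = bcol
    ftag, btag = f"fprp_pi{FLAG_PRIOR:g}", f"bfdp_pi{FLAG_PRIOR:g}"
    out["noteworthy"] = [
        flag_noteworthy(bool(r["bh_significant"]), r[ftag], r[btag])
        if np.isfinite(r[ftag]) else False
        for _, r in out.iterrows()]
    return out
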