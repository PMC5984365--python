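"""Alpha diversity and rarefaction.

Shannon index H = -sum p_i log_b p_i (base 2 by default, the QIIME
convention), Simpson index reported as 1 - D = 1 - sum p_i^2, observed
richness, and rarefaction curves using the exact hypergeometric
expectation

    E[S_n] = sum_i [ 1 - C(N - N_i, n) / C(N, n) ]

for a subsample of n of the N reads in a sample. Group comparisons use a
two-sample t test (Welch by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_model import CountMatrix, SampleFrame


def _proportions(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    return x / total


def shannon(counts, base: float = 2.0) -> float:
    """Shannon diversity of one sample's counts."""
    p = _proportions(counts)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(base))


def simpson_1_minus_d(counts) -> float:
    """Simpson diversity reported as 1 - D (in [0, 1), higher = more diverse)."""
    p = _proportions(counts)
    return float(1.0 - (p ** 2).sum())


def observed_richness(counts) -> int:
    return int((np.asarray(counts) > 0).sum())


def expected_richness(counts, n: int) -> float:
    """E[number of distinct taxa] in a random subsample of n reads.

    Exact hypergeometric expectation, computed with log-gamma to stay
    stable at amplicon depths.
    """
    x = np.asarray(counts, dtype=np.int64)
    x = x[x > 0]
    total = int(x.sum())
    if n > total:
        raise ValueError(f"subsample depth {n} exceeds sample total {total}")
    if n == 0:
        return 0.0
    # log C(N - Ni, n) - log C(N, n); term is 0 where N - Ni < n
    with np.errstate(invalid="ignore"):
        log_num = (special.gammaln(total - x + 1) - special.gammaln(n + 1)
                   - special.gammaln(total - x - n + 1))
    log_den = (special.gammaln(total + 1) - special.gammaln(n + 1)
               - special.gammaln(total - n + 1))
    miss = np.where(total - x < n, 0.0, np.exp(log_num - log_den))
    return float(np.sum(1.0 - miss))


def rarefaction_curve(counts, depths, min_total: int = 0,
                      monte_carlo: int = 0, rng=None) -> list[tuple[int, float]]:
    """Rarefaction curve [(n, E[S_n]), ...] for one sample.

    Analytic by default; ``monte_carlo > 0`` switches to averaging that
    many seeded subsamples without replacement. Samples with total below
    ``min_total`` are rejected (the curve analysis is restricted to deeply
    sequenced samples).
    """
    x = np.asarray(counts, dtype=np.int64)
    total = int(x.sum())
    if total < min_total:
        raise ValueError(f"sample total {total} < required minimum {min_total}")
    curve = []
    if monte_carlo:
        rng = np.random.default_rng(rng)
        reads = np.repeat(np.arange(len(x)), x)
    for n in depths:
        n = int(n)
        if monte_carlo:
            vals = [len(np.unique(rng.choice(reads, size=n, replace=False)))
                    for _ in range(monte_carlo)]
            curve.append((n, float(np.mean(vals))))
        else:
            curve.append((n, expected_richness(x, n)))
    return curve


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    mean_group1: float
    mean_group0: float
    test: str


def compare_groups(values, groups, group1: str = "PHIV",
                   welch: bool = True) -> GroupComparison:
    """Two-sample t test of per-sample diversity between groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    a = values[groups == group1]
    b = values[groups != group1]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(float(t), float(p), float(a.mean()), float(b.mean()),
                           "welch" if welch else "student")


def alpha_diversity_table(cm: CountMatrix, base: float = 2.0) -> pd.DataFrame:
    """Per-sample Shannon, Simpson (1-D) and observed richness."""
    rows = []
    for s in cm.samples:
        x = cm.counts[s].to_numpy()
        rows.append({"sample_id": s,
                     "shannon": shannon(x, base=base),
                     "simpson_1_minus_d": simpson_1_minus_d(x),
                     "observed_richness": observed_richness(x)})
    return pd.DataFrame(rows)


def diversity_group_tests(cm: CountMatrix, sf: SampleFrame,
                          base: float = 2.0, welch: bool = True) -> dict:
    """t tests comparing Shannon and Simpson diversity between groups."""
    tab = alpha_diversity_table(cm, base=base)
    merged = tab.merge(sf.data[["sample_id", "group"]], on="sample_id")
    out = {}
    for metric in ("shannon", "simpson_1_minus_d"):
        cmp = compare_groups(merged[metric], merged["group"], welch=welch)
        out[metric] = cmp
    return out


def cohort_rarefaction(cm: CountMatrix, depths, min_total: int = 65000) -> pd.DataFrame:
    """Rarefaction curves for every sample with >= ``min_total`` reads.

    Depths above a sample's total are skipped for that sample.
    """
    rows = []
    totals = cm.sample_totals()
    for s in cm.samples:
        if totals[s] < min_total:
            continue
        x = cm.counts[s].to_numpy()
        usable = [n for n in depths if n <= totals[s]]
        for n, es in rarefaction_curve(x, usable, min_total=min_total):
            rows.append({"sample_id": s, "depth": n, "expected_richness": es})
    return pd.DataFrame(rows, columns=["sample_id", "depth", "expected_richness"])
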