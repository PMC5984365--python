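"""Synthetic cohort generator.

Emulates the statistical structure of a cross-sectional subgingival-plaque
study of perinatally HIV-infected (PHIV) and HIV-exposed uninfected (PHEU)
youth: a taxon-by-sample count table with negative-binomial dispersion and
wide, right-skewed sequencing depths; group rate-ratio effects on selected
taxa (including strong "Corynebacterium-like" depletions); covariates; and
binary periodontitis/caries outcomes whose log-odds depend on log10 taxon
counts with group-specific slopes.

Counts for taxon j in sample i are drawn NB with mean

    mu_ij = depth_i * softmax(baseline)_j * exp(x_i beta_j + group_i theta_j)

with variance mu + mu^2/k_j (size parameter k_j > 0), matching the NB2 GLM
fitted downstream; exp(theta_j) is therefore the exact generating rate
ratio. Depths are log-uniform between the configured bounds; realized
column sums fluctuate around the drawn depth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import CountMatrix, SampleFrame


@dataclass
class DiseaseModel:
    """Logistic model generating one binary outcome.

    log-odds = intercept + group_main * 1[PHIV]
               + sum_j slope_j * t_ij + sum_j delta_j * 1[PHIV] * t_ij

    where t_ij is the log10 count of taxon j after half-minimum zero
    replacement (the same transform the analysis applies).
    """

    intercept: float = -0.5
    group_main: float = 0.0
    #: taxon index -> slope on log10 counts (reference group)
    slopes: dict = field(default_factory=dict)
    #: taxon index -> interaction log-OR delta (added slope in PHIV)
    interactions: dict = field(default_factory=dict)


@dataclass
class SimConfig:
    """Generating parameters for one synthetic cohort."""

    n_group1: int = 154          # PHIV
    n_group0: int = 100          # PHEU
    n_taxa: int = 600
    depth_range: tuple = (1330, 230039)
    #: per-taxon baseline log relative abundance (softmax-normalized);
    #: None -> drawn N(0, 2.5), giving a realistically skewed composition
    baseline_log_mean: np.ndarray | None = None
    #: per-taxon NB size parameter k (> 0); None -> lognormal around 1
    dispersion: np.ndarray | None = None
    #: per-taxon log rate ratio, group1 (PHIV) vs group0 (PHEU)
    group_log_rr: np.ndarray | None = None
    #: mapping covariate name -> per-taxon coefficient vector (or scalar)
    covariate_coefs: dict = field(default_factory=dict)
    disease_models: dict = field(default_factory=dict)  # outcome -> DiseaseModel
    antibiotic_flag_prob: tuple = (0.0, 0.0)  # (group1, group0)
    age_range: tuple = (10.0, 22.0)
    binary_covariate_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_range[0] < 1:
            raise ValueError("depth minimum must be >= 1")
        if self.dispersion is not None and np.any(np.asarray(self.dispersion) <= 0):
            raise ValueError("dispersions must be > 0")
        for p in self.antibiotic_flag_prob:
            if not 0 <= p <= 1:
                raise ValueError("antibiotic_flag_prob must be in [0,1]")


@dataclass
class SimTruth:
    """Realized generating parameters, for parameter-recovery tests."""

    config: SimConfig
    true_log_rr: np.ndarray
    true_dispersion: np.ndarray
    baseline_log_mean: np.ndarray
    true_interactions: dict
    seed: int

    def to_json(self, path) -> None:
        doc = {
            "seed": self.seed,
            "n_group1": self.config.n_group1,
            "n_group0": self.config.n_group0,
            "n_taxa": self.config.n_taxa,
            "depth_range": list(self.config.depth_range),
            "true_log_rr": np.asarray(self.true_log_rr).tolist(),
            "true_dispersion": np.asarray(self.true_dispersion).tolist(),
            "baseline_log_mean": np.asarray(self.baseline_log_mean).tolist(),
            "true_interactions": {
                outcome: {str(k): v for k, v in dm.interactions.items()}
                for outcome, dm in self.config.disease_models.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def paper_like_config(seed: int = 0) -> SimConfig:
    """Defaults matching the study dimensions this package emulates.

    254 analysis samples (154 PHIV, 100 PHEU), 600 taxa, depths log-uniform
    on 1,330–230,039; a few strongly depleted Corynebacterium-like taxa
    (rate ratio 0.15–0.25 in PHIV) and a few caries-associated taxa with a
    positive interaction log-OR on the caries outcome.
    """
    rng = np.random.default_rng(seed)
    n_taxa = 600
    log_rr = np.zeros(n_taxa)
    # taxa 0-2: strong depletions in PHIV, like oral Corynebacterium species
    log_rr[0] = np.log(0.15)
    log_rr[1] = np.log(0.20)
    log_rr[2] = np.log(0.25)
    disease = {
        "periodontitis": DiseaseModel(
            intercept=-1.4, group_main=0.3,
            slopes={10: 0.15, 11: 0.15}, interactions={}),
        "caries": DiseaseModel(
            intercept=-1.2, group_main=0.5,
            slopes={20: 0.2, 21: 0.2},
            interactions={20: np.log(2.0)}),
    }
    return SimConfig(
        n_group1=154, n_group0=100, n_taxa=n_taxa,
        depth_range=(1330, 230039),
        group_log_rr=log_rr,
        disease_models=disease,
        seed=int(rng.integers(2**31)) if seed is None else seed,
    )


def simulate_cohort(cfg: SimConfig):
    """Draw one cohort; returns (CountMatrix, SampleFrame, SimTruth).

    Deterministic given ``cfg.seed``: the same config regenerates identical
    outputs bitwise.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_group1 + cfg.n_group0
    n_taxa = cfg.n_taxa

    base = (np.asarray(cfg.baseline_log_mean, dtype=float)
            if cfg.baseline_log_mean is not None
            else rng.normal(0.0, 2.5, size=n_taxa))
    if base.shape != (n_taxa,):
        raise ValueError("baseline_log_mean length must equal n_taxa")
    if not np.any(np.isfinite(base)):
        raise ValueError("degenerate config: no finite baseline abundance")
    disp = (np.asarray(cfg.dispersion, dtype=float)
            if cfg.dispersion is not None
            else np.exp(rng.normal(0.0, 0.5, size=n_taxa)))
    log_rr = (np.asarray(cfg.group_log_rr, dtype=float)
              if cfg.group_log_rr is not None else np.zeros(n_taxa))

    group1 = np.r_[np.ones(cfg.n_group1, dtype=int),
                   np.zeros(cfg.n_group0, dtype=int)]
    age = rng.uniform(*cfg.age_range, size=n)
    p = cfg.binary_covariate_prob
    sex = rng.binomial(1, p, size=n)
    race = rng.binomial(1, p, size=n)
    eth = rng.binomial(1, p, size=n)
    dental = rng.binomial(1, p, size=n)
    abx_p = np.where(group1 == 1, cfg.antibiotic_flag_prob[0],
                     cfg.antibiotic_flag_prob[1])
    abx = rng.binomial(1, abx_p)

    depths = np.exp(rng.uniform(np.log(cfg.depth_range[0]),
                                np.log(cfg.depth_range[1]), size=n))
    depths = np.round(depths).astype(np.int64)

    # composition: softmax baseline, per-sample effect multipliers
    rel = np.exp(base - base.max())
    rel /= rel.sum()
    log_mult = np.outer(group1, log_rr)  # samples x taxa
    covs = {"age": age, "sex": sex, "race_white": race,
            "ethnicity_hispanic": eth, "dental_visit_past_year": dental}
    for name, coef in cfg.covariate_coefs.items():
        if name not in covs:
            raise ValueError(f"unknown covariate {name!r}")
        coef = np.broadcast_to(np.asarray(coef, dtype=float), (n_taxa,))
        log_mult += np.outer(covs[name], coef)
    mu = depths[:, None] * rel[None, :] * np.exp(log_mult)

    # NB2 via gamma-Poisson mixture: k = size, variance mu + mu^2/k
    lam = rng.gamma(shape=disp[None, :], scale=mu / disp[None, :])
    counts = rng.poisson(lam).astype(np.int64).T  # taxa x samples

    sample_ids = [f"S{i:04d}" for i in range(n)]
    taxon_ids = [f"T{j:04d}" for j in range(n_taxa)]
    taxonomy = pd.DataFrame(
        {"genus": [f"Genus{j // 3:03d}" for j in range(n_taxa)],
         # every third row is a genus-only (no species assignment) bucket
         "species": ["" if j % 3 == 2 else f"species{j:04d}"
                     for j in range(n_taxa)]},
        index=pd.Index(taxon_ids, name="taxon_id"))
    cm = CountMatrix(pd.DataFrame(counts,
                                  index=taxonomy.index, columns=sample_ids),
                     taxonomy)

    totals = cm.sample_totals().to_numpy()
    outcomes = {}
    transformed = _log10_halfmin_matrix(counts)
    for name, dm in cfg.disease_models.items():
        eta = np.full(n, dm.intercept, dtype=float) + dm.group_main * group1
        for j, slope in dm.slopes.items():
            eta += slope * transformed[j]
        for j, delta in dm.interactions.items():
            eta += delta * group1 * transformed[j]
        outcomes[name] = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
    for name in ("periodontitis", "caries"):
        if name not in outcomes:
            outcomes[name] = rng.binomial(1, 0.3, size=n)

    sf = SampleFrame(pd.DataFrame({
        "sample_id": sample_ids,
        "group": np.where(group1 == 1, "PHIV", "PHEU"),
        "age": age,
        "sex": sex,
        "race_white": race,
        "ethnicity_hispanic": eth,
        "dental_visit_past_year": dental,
        "antibiotic_past_3mo": abx,
        "periodontitis": outcomes["periodontitis"],
        "caries": outcomes["caries"],
        "total_reads": totals,
    }))
    truth = SimTruth(config=cfg, true_log_rr=log_rr, true_dispersion=disp,
                     baseline_log_mean=base,
                     true_interactions={k: dict(v.interactions)
                                        for k, v in cfg.disease_models.items()},
                     seed=cfg.seed)
    return cm, sf, truth


def _log10_halfmin_matrix(counts: np.ndarray) -> np.ndarray:
    """Row-wise log10 with zeros replaced by half the row minimum nonzero.

    Rows that are entirely zero transform to 0 (they carry no signal and
    never enter a disease model with a nonzero slope in practice).
    """
    out = np.zeros_like(counts, dtype=float)
    for j in range(counts.shape[0]):
        row = counts[j].astype(float)
        nz = row[row > 0]
        if nz.size == 0:
            continue
        row = np.where(row == 0, nz.min() / 2.0, row)
        out[j] = np.log10(row)
    return out


# ---------------------------------------------------------------------------
# Printed-roster reconstruction (deterministic, no randomness)
# ---------------------------------------------------------------------------

def reference_cohort_frame(seed: int = 0) -> SampleFrame:
    """The 279-sample enrollment roster of the PHACS oral-health sub-study,
    reconstructed from its published margins.

    173 PHIV (19 flagged for antibiotic use in the prior 3 months) and 106
    PHEU (6 flagged); among the 254 unflagged samples the periodontitis ×
    caries cross-tabulation matches the reported cells:

    ==========  =========  =========  =========  =========
    group       no/no      no/caries  perio/no   perio/car
    PHEU (100)  38         32         17         13
    PHIV (154)  34         68         24         28
    ==========  =========  =========  =========  =========

    Covariates not determined by the cross-tabulation (age, sex, ...) are
    filled with fixed placeholder values; they play no role in the
    tabulations this frame supports.
    """
    rows = []
    cells = {
        "PHEU": [(0, 0, 38), (0, 1, 32), (1, 0, 17), (1, 1, 13)],
        "PHIV": [(0, 0, 34), (0, 1, 68), (1, 0, 24), (1, 1, 28)],
    }
    flagged = {"PHIV": 19, "PHEU": 6}
    i = 0
    for group in ("PHIV", "PHEU"):
        for perio, caries, k in cells[group]:
            for _ in range(k):
                rows.append((f"R{i:04d}", group, 0, perio, caries))
                i += 1
        for _ in range(flagged[group]):
            rows.append((f"R{i:04d}", group, 1, 0, 0))
            i += 1
    df = pd.DataFrame(rows, columns=["sample_id", "group", "antibiotic_past_3mo",
                                     "periodontitis", "caries"])
    df["age"] = 16.0
    df["sex"] = 0
    df["race_white"] = 0
    df["ethnicity_hispanic"] = 0
    df["dental_visit_past_year"] = 0
    df["total_reads"] = 1
    return SampleFrame(df)
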