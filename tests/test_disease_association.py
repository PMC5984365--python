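import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oralmicro.disease_association import (combined_set_model,
                                           fit_interaction_model,
                                           group_prevalence,
                                           log10_halfmin_transform,
                                           prevalence_table)
from oralmicro.synthetic_cohort import (DiseaseModel, SimConfig,
                                        reference_cohort_frame,
                                        simulate_cohort)
from .conftest import make_count_matrix, make_sample_frame


def test_transform_worked_example():
    out = log10_halfmin_transform([0, 10, 1000])
    assert out == pytest.approx([np.log10(5), 1.0, 3.0])


def test_transform_identity_without_zeros():
    x = [3, 30, 300]
    assert log10_halfmin_transform(x) == pytest.approx(np.log10(x))


def test_transform_all_zero_rejected():
    with pytest.raises(ValueError):
        log10_halfmin_transform([0, 0, 0])


@settings(deadline=None, max_examples=200)
@given(st.lists(st.integers(0, 10 ** 6), min_size=2, max_size=30))
def test_transform_rank_preserving(xs):
    if not any(xs):
        return
    t = log10_halfmin_transform(xs)
    order = np.argsort(np.asarray(xs), kind="stable")
    assert (np.diff(t[order]) >= -1e-12).all()


def _cohort_with_interaction(seed, delta):
    dm = {"caries": DiseaseModel(intercept=-1.0, group_main=0.2,
                                 slopes={0: 0.3}, interactions={0: delta})}
    cfg = SimConfig(n_taxa=30, baseline_log_mean=np.zeros(30),
                    dispersion=np.ones(30), disease_models=dm, seed=seed)
    return simulate_cohort(cfg)


def test_interaction_model_reports_both_group_ors():
    cm, sf, _ = _cohort_with_interaction(3, np.log(2))
    r = fit_interaction_model("caries", cm.counts.iloc[0].to_numpy(), sf,
                              taxon_id="t0")
    assert not r.degenerate
    assert r.or_group0 > 0 and r.or_group1 > 0
    assert r.ci_group0[0] < r.or_group0 < r.ci_group0[1]
    # OR(PHIV) = OR(PHEU) * exp(delta_hat)
    assert r.or_group1 == pytest.approx(
        r.or_group0 * np.exp(r.interaction_log_or), rel=1e-9)


def test_interaction_reference_swap_consistent():
    cm, sf, _ = _cohort_with_interaction(5, np.log(2))
    swapped = sf.data.copy()
    swapped["group"] = np.where(swapped["group"] == "PHIV", "PHEU", "PHIV")
    sf_sw = type(sf)(swapped)
    y = cm.counts.iloc[0].to_numpy()
    r1 = fit_interaction_model("caries", y, sf)
    r2 = fit_interaction_model("caries", y, sf_sw)
    assert r1.or_group0 == pytest.approx(r2.or_group1, rel=1e-6)
    assert r1.or_group1 == pytest.approx(r2.or_group0, rel=1e-6)
    assert r1.interaction_p == pytest.approx(r2.interaction_p, rel=1e-6)


def test_separation_flagged_not_raised():
    n = 40
    sf = make_sample_frame(
        ["PHIV"] * 20 + ["PHEU"] * 20,
        periodontitis=[0] * 10 + [1] * 10 + [0] * 10 + [1] * 10)
    x = np.array([100] * 10 + [0] * 10 + [1] * 20)
    r = fit_interaction_model("periodontitis", x, sf, taxon_id="t")
    assert r.degenerate
    assert r.or_group0 is None


def test_single_class_outcome_rejected():
    sf = make_sample_frame(["PHIV"] * 5 + ["PHEU"] * 5, caries=0)
    with pytest.raises(ValueError, match="single class"):
        fit_interaction_model("caries", np.arange(1, 11), sf)


def test_combined_set_singleton_equals_single_taxon():
    cm, sf, _ = _cohort_with_interaction(7, 0.0)
    single = fit_interaction_model("caries", cm.counts.iloc[0].to_numpy(),
                                   sf, taxon_id="T0000")
    combo = combined_set_model("caries", cm, ["T0000"], sf)
    assert combo.or_group0 == pytest.approx(single.or_group0, rel=1e-9)
    assert combo.interaction_p == pytest.approx(single.interaction_p, rel=1e-9)


def test_combined_set_sums_counts():
    cm, sf, _ = _cohort_with_interaction(9, 0.0)
    summed = (cm.counts.loc["T0000"] + cm.counts.loc["T0001"]).to_numpy()
    direct = fit_interaction_model("caries", summed, sf)
    combo = combined_set_model("caries", cm, ["T0000", "T0001"], sf)
    assert combo.or_group0 == pytest.approx(direct.or_group0, rel=1e-9)


def test_combined_set_missing_taxa_warned(caplog):
    cm, sf, _ = _cohort_with_interaction(9, 0.0)
    with caplog.at_level("WARNING"):
        combined_set_model("caries", cm, ["T0000", "NOT_A_TAXON"], sf)
    assert "missing" in caplog.text
    with pytest.raises(ValueError):
        combined_set_model("caries", cm, ["NOPE"], sf)


def test_prevalence_table_printed_cohort():
    sf = reference_cohort_frame()
    analysis = sf.select_samples(
        sf.data.loc[sf.data["antibiotic_past_3mo"] == 0, "sample_id"])
    tab = prevalence_table(analysis)
    cell = tab[(tab.group == "PHIV") & (tab.periodontitis == 1)
               & (tab.caries == 0)]
    assert int(cell["n"].iloc[0]) == 24
    assert float(cell["percent"].iloc[0]) == pytest.approx(15.6, abs=0.05)
    assert group_prevalence(analysis, "caries")["PHEU"] == pytest.approx(45.0)


def test_prevalence_table_degenerate_single_cell():
    sf = make_sample_frame(["PHIV"] * 4, periodontitis=1, caries=1)
    tab = prevalence_table(sf)
    full = tab[(tab.periodontitis == 1) & (tab.caries == 1)]
    assert float(full["percent"].iloc[0]) == 100.0
    assert tab["n"].sum() == 4


def test_prevalence_table_matches_brute_force_pivot(small_cohort):
    _, sf, _ = small_cohort
    tab = prevalence_table(sf)
    df = sf.data
    for row in tab.itertuples():
        brute = ((df["group"] == row.group)
                 & (df["periodontitis"] == row.periodontitis)
                 & (df["caries"] == row.caries)).sum()
        assert row.n == brute
    assert tab.groupby("group")["n"].sum().to_dict() == \
        df.groupby("group").size().to_dict()
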