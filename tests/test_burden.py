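"""Carrier aggregation and 2x2 statistics."""

import math
import warnings

import numpy as np
import pytest

from panelburden.burden import (
    AadComparison,
    ControlCohortCounts,
    PatientPhenotype,
    aad_compare,
    aggregate_carriers,
    fisher_exact_two_sided,
    odds_ratio_2x2,
    read_control_counts_tsv,
    read_phenotypes_tsv,
    render_burden_table,
    round2,
    stratified_scan,
    summarize_vus,
    burden_scan,
    write_control_counts_tsv,
    write_phenotypes_tsv,
)


def brute_force_fisher(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: enumerate all tables with the fixed margins and
    sum hypergeometric point probabilities <= that of the observed table."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point(x: int) -> float:
        return (
            math.comb(c1, x) * math.comb(n - c1, r1 - x) / math.comb(n, r1)
        )

    p_obs = point(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = point(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


# ---- odds_ratio_2x2 --------------------------------------------------------


@pytest.mark.parametrize(
    "cells,expected",
    [
        ((71, 5589, 96, 27173), (3.63, 2.67, 4.94)),  # case-control, large panel study
        ((5, 629, 12, 4960), (3.30, 1.16, 9.41)),  # bilateral case-case comparison
        ((10, 110, 10, 110), (1.00, None, None)),  # identical proportions
    ],
)
def test_odds_ratio_known_tables(cells, expected):
    orr, lo, hi, defined = odds_ratio_2x2(*cells)
    assert defined
    assert round2(orr) == expected[0]
    if expected[1] is not None:
        assert (round2(lo), round2(hi)) == expected[1:]
    assert lo <= orr <= hi


def test_odds_ratio_zero_cell_is_undefined():
    assert odds_ratio_2x2(0, 100, 5, 100) == (None, None, None, False)
    assert odds_ratio_2x2(5, 100, 100, 100)[3] is False  # saturated cell
    with pytest.raises(ValueError):
        odds_ratio_2x2(1, 0, 1, 10)


def test_odds_ratio_equals_logistic_slope(rng):
    """The closed-form OR is the exponentiated univariate logistic slope."""
    import statsmodels.api as sm

    for _ in range(10):
        a_n, b_n = int(rng.integers(40, 400)), int(rng.integers(40, 400))
        a = int(rng.integers(1, a_n))
        b = int(rng.integers(1, b_n))
        orr, *_ , defined = odds_ratio_2x2(a, a_n, b, b_n)
        if not defined:
            continue
        X = sm.add_constant(np.array([1.0, 1.0, 0.0, 0.0]))
        y = np.array([1.0, 0.0, 1.0, 0.0])
        w = np.array([a, a_n - a, b, b_n - b], dtype=float)
        fit = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
        assert math.exp(fit.params[1]) == pytest.approx(orr, rel=1e-6)


# ---- Fisher exact ----------------------------------------------------------


def test_fisher_symmetric_table_is_one():
    assert fisher_exact_two_sided(1, 1, 1, 1) == pytest.approx(1.0)


def test_fisher_matches_enumeration_oracle():
    assert fisher_exact_two_sided(2, 3, 4, 5) == pytest.approx(
        brute_force_fisher(2, 3, 4, 5), rel=1e-9
    )


def test_fisher_large_table_extreme():
    assert fisher_exact_two_sided(71, 5518, 96, 27077) < 0.0001


def test_fisher_degenerate_margin_warns():
    with pytest.warns(UserWarning):
        assert fisher_exact_two_sided(0, 0, 3, 4) == 1.0


def test_fisher_row_and_column_swap_invariance(rng):
    for _ in range(25):
        a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            continue
        p = fisher_exact_two_sided(a, b, c, d)
        assert fisher_exact_two_sided(c, d, a, b) == pytest.approx(p, rel=1e-9)
        assert fisher_exact_two_sided(b, a, d, c) == pytest.approx(p, rel=1e-9)


# ---- carrier aggregation ---------------------------------------------------


def test_multi_variant_patient_counts_once(fixture):
    """Patient-level dedup: 274 PTVs but 272 carriers (two dual carriers),
    and a patient with two variants in one gene counts once for that gene."""
    carriers, n = aggregate_carriers(fixture.classified, fixture.patients, "ALL", "ptv_only")
    assert (carriers, n) == (272, 5589)
    per_gene = sum(
        aggregate_carriers(fixture.classified, fixture.patients, g, "ptv_only")[0]
        for g in ("ATM", "CDH1", "CHEK2", "NBN", "PALB2", "RAD51C", "RAD51D", "TP53")
    )
    assert per_gene == 274  # conservation: gene sum exceeds ALL by the dual carriers


def test_carrier_conservation_on_simulated_cohort(fixture):
    genes = sorted({cv.variant.gene_symbol for cv in fixture.classified})
    gene_sum = sum(
        aggregate_carriers(fixture.classified, fixture.patients, g, "class45")[0]
        for g in genes
    )
    all_carriers, _ = aggregate_carriers(fixture.classified, fixture.patients, "ALL", "class45")
    assert gene_sum >= all_carriers


def test_subgroup_counts_match_linear_scan_oracle(fixture):
    """Subgroup aggregation agrees with an independent scan over the patient
    table joined to the variant carrier lists."""
    carrier_set = set()
    for cv in fixture.classified:
        if cv.iarc_class >= 4:
            carrier_set.update(cv.carriers)
    expected = sum(
        1 for p in fixture.patients if p.bilateral and p.patient_id in carrier_set
    )
    got, n = aggregate_carriers(
        fixture.classified, fixture.patients, "ALL", "class45", subgroup=lambda p: p.bilateral
    )
    assert got == expected == 52
    assert n == sum(p.bilateral for p in fixture.patients)


def test_unknown_patient_id_raises(fixture):
    with pytest.raises(KeyError, match="unknown patient"):
        aggregate_carriers(fixture.classified, fixture.patients[:100], "ALL", "class45")


# ---- age comparison --------------------------------------------------------


def test_identical_age_lists_give_t_zero():
    res = aad_compare([40, 45, 50], [40, 45, 50], mode="vs_overall")
    assert res.t == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_single_carrier_age_returns_means_without_p():
    res = aad_compare([44], [40, 45, 50, 60], mode="vs_overall")
    assert res.p is None and res.t is None
    assert res.mean_a == 44


def test_vs_rest_removes_carriers_from_reference():
    res = aad_compare([30, 30], [30, 30, 50, 50], mode="vs_rest")
    assert res.mean_b == pytest.approx(50.0)
    assert res.n_b == 2


def test_young_carrier_group_detected_at_study_scale(rng):
    """Power: carriers ~N(40, 9), n=17 vs the study-size remainder ~N(47, 11)
    rejects at alpha=.05 in the large majority of replicates."""
    hits = 0
    reps = 60
    for _ in range(reps):
        carriers = rng.normal(40, 9, size=17)
        rest = rng.normal(47, 11, size=5523)
        res = aad_compare(list(carriers), list(rest), mode="vs_overall")
        hits += res.p < 0.05
    assert hits / reps > 0.6


# ---- scans and rendering ---------------------------------------------------


def test_stratified_scan_bilateral_reproduces_counts(fixture):
    results, prevalence = stratified_scan(
        fixture.classified, fixture.patients, strata=["bilateral_vs_unilateral"]
    )
    by_gene = {r.gene: r for r in results}
    palb2 = by_gene["PALB2"]
    assert (palb2.a_carriers, palb2.a_n, palb2.b_carriers, palb2.b_n) == (14, 629, 54, 4960)
    assert round2(palb2.odds_ratio) == 2.07
    nbn = by_gene["NBN"]
    assert not nbn.defined and nbn.p_fisher == pytest.approx(0.3830, abs=5e-5)
    cell = prevalence.query("gene == 'PALB2' and group == 'bilateral'")
    assert float(cell["percent"].iloc[0]) == pytest.approx(100 * 14 / 629)


def test_receptor_strata_match_published_margins(fixture):
    results, _ = stratified_scan(
        fixture.classified, fixture.patients, strata=["er", "her2", "tnbc"]
    )
    atm_er = next(r for r in results if r.gene == "ATM" and r.group_a_label == "ER-positive")
    assert (atm_er.a_carriers, atm_er.a_n, atm_er.b_carriers, atm_er.b_n) == (43, 2355, 4, 749)
    chek2_her2 = next(
        r for r in results if r.gene == "CHEK2" and r.group_a_label == "HER2-positive"
    )
    assert (chek2_her2.a_carriers, chek2_her2.b_carriers) == (34, 56)
    all_tnbc = next(r for r in results if r.gene == "ALL" and r.group_a_label == "non-TNBC")
    assert (all_tnbc.a_carriers, all_tnbc.a_n, all_tnbc.b_carriers, all_tnbc.b_n) == (
        186, 2622, 20, 482,
    )


def test_unknown_stratum_rejected(fixture):
    with pytest.raises(ValueError, match="unknown stratum"):
        stratified_scan(fixture.classified, fixture.patients, strata=["laterality"])


def test_vus_summary(fixture):
    v = summarize_vus(fixture.classified, fixture.patients)
    assert v.patients_with_vus == 827
    assert v.distinct_vus == 421
    assert v.fraction_single_vus == pytest.approx(761 / 827)
    assert v.per_gene_vus_patient_counts["ATM"] == 322
    assert v.per_gene_vus_patient_counts["CHEK2"] == 196
    assert v.per_gene_vus_patient_counts["PALB2"] == 76


def test_render_table_formats_na_and_two_decimals(fixture):
    results = burden_scan(fixture.classified, fixture.patients, fixture.controls)
    df = render_burden_table(results)
    chek2_flossies = df.query("gene == 'CDH1' and group_b == 'FLOSSIES'")
    assert chek2_flossies["OR"].iloc[0] == "n.a."
    atm = df.query("gene == 'ATM' and group_b == 'ExAC'").iloc[0]
    assert atm["OR"] == "3.63" and atm["CI95"] == "2.67-4.94"
    assert atm["p_fisher"] == "<0.0001"
    assert "p_bh" in df.columns


def test_round2_half_away_from_zero():
    assert round2(1.165) == 1.17
    assert round2(2.025) == 2.03
    assert round2(-1.165) == -1.17


def test_phenotype_and_control_tsv_roundtrip(tmp_path, fixture):
    ppath = tmp_path / "phen.tsv"
    write_phenotypes_tsv(fixture.patients[:50], str(ppath))
    back = read_phenotypes_tsv(str(ppath))
    assert back == fixture.patients[:50]
    cpath = tmp_path / "controls.tsv"
    write_control_counts_tsv(fixture.controls, str(cpath))
    back_c = read_control_counts_tsv(str(cpath))
    assert {c.cohort_name: c.n_total for c in back_c} == {
        "ExAC": 27173, "FLOSSIES": 7325, "GMC": 2189,
    }
    assert back_c[0].per_gene_carriers["ATM"] == 96
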