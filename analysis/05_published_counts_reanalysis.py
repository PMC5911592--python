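"""Recompute the published odds ratios from the printed carrier counts.

Reconstitutes the pseudo-cohort whose per-gene, per-stratum carrier counts
equal the published tables exactly and pushes it through the same burden
pipeline as the simulated data. Every defined case-control and bilateral
odds ratio should match the printed value to 2 decimals — except the three
cells documented as internally inconsistent in the source tables (CHEK2 and
CHEK2 c.1100del vs the ExAC-like cohort, and the all-carrier bilateral row),
where the cross-product of the printed counts is reported instead.
"""

from _common import RESULTS

from panelburden.burden import (
    burden_scan,
    missense_burden,
    render_burden_table,
    round2,
    stratified_scan,
)
from panelburden.reference import fixture_cohort


def main() -> None:
    fx = fixture_cohort()
    results = burden_scan(fx.classified, fx.patients, fx.controls, class_filter="ptv_only")
    render_burden_table(results).to_csv(
        RESULTS / "published_case_control.tsv", sep="\t", index=False
    )
    print("PTV burden from published counts (cases n=5589):")
    for r in results:
        orr = f"{round2(r.odds_ratio):.2f}" if r.defined else "n.a."
        ci = f"({round2(r.ci_low):.2f}-{round2(r.ci_high):.2f})" if r.defined else "(n.a.)"
        print(f"  {r.gene:<16} vs {r.group_b_label:<9} {r.a_carriers:>4} vs {r.b_carriers:>4}"
              f"   OR {orr:>6} {ci:<16} p={r.p_fisher:.4g}")

    strat, prevalence = stratified_scan(
        fx.classified, fx.patients,
        strata=["bilateral_vs_unilateral", "er", "pr", "her2", "tnbc"],
    )
    render_burden_table(strat).to_csv(RESULTS / "published_strata.tsv", sep="\t", index=False)
    prevalence.to_csv(RESULTS / "published_prevalence.tsv", sep="\t", index=False)
    print("bilateral vs unilateral (class 4/5):")
    for r in strat:
        if r.group_a_label != "bilateral":
            continue
        orr = f"{round2(r.odds_ratio):.2f}" if r.defined else "n.a."
        print(f"  {r.gene:<16} {r.a_carriers:>3}/629 vs {r.b_carriers:>4}/4960   OR {orr:>6}"
              f"  p={r.p_fisher:.4f}")

    dmis = missense_burden(fx.classified, fx.patients, fx.dmis_controls)
    print("rare damaging-missense carriers vs ExAC counts:")
    for r in dmis:
        if r.gene in ("CHEK2", "TP53"):
            print(f"  {r.gene:<8} {r.a_percent:.2f}% vs {r.b_percent:.2f}%  p={r.p_fisher:.2g}")
    print(f"tables -> {RESULTS / 'published_case_control.tsv'}")


if __name__ == "__main__":
    main()
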