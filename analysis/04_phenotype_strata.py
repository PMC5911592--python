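"""Phenotype-stratified analyses of the simulated cohort.

Case-case comparisons (bilateral vs unilateral, ER/PR/HER2, TNBC, OC family
history), age-at-first-diagnosis t-tests per gene, the rare damaging-
missense burden vs controls, and the VUS summary. Outputs under results/.
"""

import json

from _common import RESULTS, ensure_classified, ensure_simulation

from panelburden.burden import (
    aad_compare,
    carrier_ids,
    missense_burden,
    read_control_counts_tsv,
    read_phenotypes_tsv,
    render_burden_table,
    round2,
    stratified_scan,
    summarize_vus,
)
from panelburden.classification import read_classified_tsv


def main() -> None:
    paths = ensure_simulation()
    classified = read_classified_tsv(str(ensure_classified()))
    patients = read_phenotypes_tsv(str(paths["phenotypes"]))

    strata = ["bilateral_vs_unilateral", "er", "pr", "her2", "tnbc", "oc_family_history"]
    results, prevalence = stratified_scan(classified, patients, strata=strata)
    render_burden_table(results).to_csv(RESULTS / "burden_strata.tsv", sep="\t", index=False)
    prevalence.to_csv(RESULTS / "prevalence_strata.tsv", sep="\t", index=False)
    print("bilateral vs unilateral (class 4/5 carriers):")
    for r in results:
        if r.group_a_label == "bilateral" and r.gene in ("CHEK2", "PALB2", "TP53", "ALL"):
            orr = f"{round2(r.odds_ratio):.2f}" if r.defined else "n.a."
            print(f"  {r.gene:<8} {r.a_carriers}/{r.a_n} vs {r.b_carriers}/{r.b_n}"
                  f"  OR {orr}  p={r.p_fisher:.3f}")

    # age at first diagnosis per gene, carriers vs non-carrier remainder
    overall = [p.aad_years for p in patients if p.aad_years is not None]
    by_id = {p.patient_id: p for p in patients}
    aad_rows = []
    genes = sorted({cv.variant.gene_symbol for cv in classified if cv.iarc_class >= 4})
    print("age at first diagnosis (carriers vs rest):")
    for gene in genes:
        ids = carrier_ids(classified, gene, "class45")
        ages = [by_id[i].aad_years for i in ids if by_id[i].aad_years is not None]
        if not ages:
            continue
        res = aad_compare(ages, overall, mode="vs_rest")
        aad_rows.append({"gene": gene, "n": res.n_a, "mean_carriers": res.mean_a,
                         "mean_rest": res.mean_b, "t": res.t, "p": res.p})
        flag = " *" if res.p is not None and res.p < 0.05 else ""
        print(f"  {gene:<8} n={res.n_a:<4} mean {res.mean_a:.1f} vs {res.mean_b:.1f}"
              f"  p={res.p:.3g}{flag}" if res.p is not None else f"  {gene}: n too small")
    with open(RESULTS / "aad_by_gene.json", "w") as fh:
        json.dump(aad_rows, fh, indent=2)

    dmis_controls = read_control_counts_tsv(str(paths["dmis_controls"]))
    dmis = missense_burden(classified, patients, dmis_controls)
    render_burden_table(dmis).to_csv(RESULTS / "burden_damaging_missense.tsv", sep="\t", index=False)
    print("rare damaging-missense burden vs ExAC-sized controls:")
    for r in dmis:
        if r.gene in ("CHEK2", "TP53") and r.group_b_label == "ExAC":
            print(f"  {r.gene:<8} {r.a_percent:.2f}% vs {r.b_percent:.2f}%  p={r.p_fisher:.2g}")

    vus = summarize_vus(classified, patients)
    print(f"VUS: {vus.patients_with_vus} patients carry {vus.distinct_vus} distinct VUS; "
          f"{100 * vus.fraction_single_vus:.1f}% carry a single one")
    with open(RESULTS / "vus_summary.json", "w") as fh:
        json.dump(
            {"patients_with_vus": vus.patients_with_vus, "distinct_vus": vus.distinct_vus,
             "fraction_single_vus": vus.fraction_single_vus,
             "per_gene": dict(vus.per_gene_vus_patient_counts)},
            fh, indent=2,
        )


if __name__ == "__main__":
    main()
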