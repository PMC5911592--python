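"""Gene-level carrier-burden case-control and case-case statistics.

Carrier counting is per patient (a patient with several qualifying variants
in a gene — or, for the all-gene row, in several genes — counts once).
Association is summarised per 2x2 carrier table with the Wald odds ratio

    OR = [a/(a_n-a)] / [b/(b_n-b)],
    95% CI = exp(ln OR +/- z * sqrt(1/a + 1/(a_n-a) + 1/b + 1/(b_n-b))),

which equals the exponentiated slope of a univariate logistic regression on
the same table, plus a two-sided Fisher exact p-value. Tables with any zero
cell are reported as undefined ("n.a.") with no continuity correction.
Age-at-diagnosis comparisons use the pooled-variance Student t-test
(Welch available behind a flag).
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classification import ClassifiedVariant

logger = logging.getLogger(__name__)

__all__ = [
    "PatientPhenotype",
    "ControlCohortCounts",
    "BurdenResult",
    "Z_975",
    "aggregate_carriers",
    "odds_ratio_2x2",
    "fisher_exact_two_sided",
    "aad_compare",
    "burden_scan",
    "stratified_scan",
    "missense_burden",
    "summarize_vus",
    "render_burden_table",
    "read_phenotypes_tsv",
    "write_phenotypes_tsv",
    "read_control_counts_tsv",
    "write_control_counts_tsv",
    "ALL_GENES_KEY",
    "FOUNDER_KEY",
    "STRATA",
]

#: standard-normal 97.5% quantile used for the Wald 95% CI
Z_975 = 1.959963984540054

ALL_GENES_KEY = "ALL"
FOUNDER_KEY = "CHEK2_c1100del"

_RECEPTOR_VALUES = {"positive", "negative", "unknown"}


@dataclass(frozen=True)
class PatientPhenotype:
    patient_id: str
    aad_years: int | None  # age at first BC diagnosis; None = not recorded
    bilateral: bool
    oc_family_history: bool
    er: str = "unknown"
    pr: str = "unknown"
    her2: str = "unknown"

    def __post_init__(self) -> None:
        if self.aad_years is not None and not 10 <= self.aad_years <= 110:
            raise ValueError(f"{self.patient_id}: AAD {self.aad_years} outside [10,110]")
        for name, val in (("er", self.er), ("pr", self.pr), ("her2", self.her2)):
            if val not in _RECEPTOR_VALUES:
                raise ValueError(f"{self.patient_id}: {name}={val!r} invalid")

    @property
    def receptor_known(self) -> bool:
        return "unknown" not in (self.er, self.pr, self.her2)

    @property
    def tnbc(self) -> bool | None:
        """Triple-negative status; None when any receptor is unknown."""
        if not self.receptor_known:
            return None
        return self.er == "negative" and self.pr == "negative" and self.her2 == "negative"


@dataclass(frozen=True)
class ControlCohortCounts:
    cohort_name: str
    n_total: int
    per_gene_carriers: Mapping[str, int]

    def __post_init__(self) -> None:
        for gene, count in self.per_gene_carriers.items():
            if not 0 <= count <= self.n_total:
                raise ValueError(
                    f"{self.cohort_name}: {gene} carrier count {count} exceeds n={self.n_total}"
                )


@dataclass(frozen=True)
class BurdenResult:
    gene: str
    group_a_label: str
    group_b_label: str
    a_carriers: int
    a_n: int
    b_carriers: int
    b_n: int
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_fisher: float
    defined: bool

    @property
    def a_percent(self) -> float:
        return 100.0 * self.a_carriers / self.a_n if self.a_n else float("nan")

    @property
    def b_percent(self) -> float:
        return 100.0 * self.b_carriers / self.b_n if self.b_n else float("nan")


# ---- core statistics -------------------------------------------------------


def odds_ratio_2x2(
    a_carriers: int, a_n: int, b_carriers: int, b_n: int, z: float = Z_975
) -> tuple[float | None, float | None, float | None, bool]:
    """Wald odds ratio and 95% CI on a carrier/non-carrier 2x2 table.

    Any zero cell makes the estimate undefined (reported "n.a.", matching
    the convention of diagnostic-panel reports; no continuity correction).
    """
    if a_n <= 0 or b_n <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= a_carriers <= a_n and 0 <= b_carriers <= b_n):
        raise ValueError("carrier counts exceed group sizes")
    cells = (a_carriers, a_n - a_carriers, b_carriers, b_n - b_carriers)
    if any(c == 0 for c in cells):
        return None, None, None, False
    a, b, c, d = cells
    orr = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(orr) - z * se)
    hi = math.exp(math.log(orr) + z * se)
    return orr, lo, hi, True


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p (point-probability method) on [[a,b],[c,d]].

    Degenerate margins (an empty row or column) carry no information:
    p = 1 with a warning.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        warnings.warn("degenerate 2x2 margin; Fisher p set to 1", stacklevel=2)
        return 1.0
    p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


@dataclass(frozen=True)
class AadComparison:
    mean_a: float
    mean_b: float
    t: float | None
    p: float | None
    n_a: int
    n_b: int


def aad_compare(
    carrier_ages: Sequence[float],
    reference_ages: Sequence[float],
    mode: str = "vs_rest",
    welch: bool = False,
) -> AadComparison:
    """Compare carriers' age at first diagnosis against a reference group.

    ``mode='vs_overall'`` uses ``reference_ages`` as given; ``'vs_rest'``
    removes one occurrence of each carrier age from the reference first
    (carriers vs the non-carrier remainder). Pooled-variance Student t by
    default; Welch with ``welch=True``. Groups of fewer than two ages yield
    an undefined p (means still returned).
    """
    if not carrier_ages or not reference_ages:
        raise ValueError("both age lists must be non-empty")
    if mode == "vs_rest":
        rest = Counter(reference_ages)
        rest.subtract(Counter(carrier_ages))
        if any(v < 0 for v in rest.values()):
            raise ValueError("carrier ages not a sub-multiset of the reference ages")
        reference = list(rest.elements())
        if not reference:
            raise ValueError("reference is empty after removing carriers")
    elif mode == "vs_overall":
        reference = list(reference_ages)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mean_a = float(np.mean(carrier_ages))
    mean_b = float(np.mean(reference))
    if len(carrier_ages) < 2 or len(reference) < 2:
        return AadComparison(mean_a, mean_b, None, None, len(carrier_ages), len(reference))
    t, p = stats.ttest_ind(carrier_ages, reference, equal_var=not welch)
    return AadComparison(mean_a, mean_b, float(t), float(p), len(carrier_ages), len(reference))


# ---- carrier aggregation ---------------------------------------------------


def _qualifies(cv: ClassifiedVariant, class_filter: str) -> bool:
    if class_filter == "ptv_only":
        return cv.is_ptv and cv.iarc_class >= 4
    if class_filter == "class45":
        return cv.iarc_class >= 4
    if class_filter == "damaging_missense":
        return cv.damaging_missense
    if class_filter == "vus":
        return cv.iarc_class == 3
    raise ValueError(f"unknown class_filter {class_filter!r}")


def carrier_ids(
    classified: Iterable[ClassifiedVariant],
    gene: str,
    class_filter: str,
    variant_predicate: Callable[[ClassifiedVariant], bool] | None = None,
) -> set[str]:
    """Patient ids carrying >=1 qualifying variant (deduplicated)."""
    out: set[str] = set()
    for cv in classified:
        if not _qualifies(cv, class_filter):
            continue
        if variant_predicate is not None:
            if not variant_predicate(cv):
                continue
        elif gene != ALL_GENES_KEY and cv.variant.gene_symbol != gene:
            continue
        out.update(cv.carriers)
    return out


def aggregate_carriers(
    classified: Iterable[ClassifiedVariant],
    patients: Sequence[PatientPhenotype],
    gene: str,
    class_filter: str = "class45",
    subgroup: Callable[[PatientPhenotype], bool] | None = None,
    variant_predicate: Callable[[ClassifiedVariant], bool] | None = None,
) -> tuple[int, int]:
    """(carriers, n) for one gene (or ALL) within an optional subgroup.

    A patient with multiple qualifying variants counts once; every carrier
    id must resolve to a known patient.
    """
    by_id = {p.patient_id: p for p in patients}
    ids = carrier_ids(classified, gene, class_filter, variant_predicate)
    unknown = ids - by_id.keys()
    if unknown:
        raise KeyError(f"variants reference unknown patient ids: {sorted(unknown)[:5]}")
    if subgroup is None:
        return len(ids), len(patients)
    members = {p.patient_id for p in patients if subgroup(p)}
    return len(ids & members), len(members)


def _founder_predicate(cv: ClassifiedVariant) -> bool:
    return cv.variant.variant_id == FOUNDER_KEY


def _result(
    gene: str,
    label_a: str,
    label_b: str,
    a: int,
    a_n: int,
    b: int,
    b_n: int,
) -> BurdenResult:
    orr, lo, hi, defined = odds_ratio_2x2(a, a_n, b, b_n)
    p = fisher_exact_two_sided(a, a_n - a, b, b_n - b)
    return BurdenResult(gene, label_a, label_b, a, a_n, b, b_n, orr, lo, hi, p, defined)


def burden_scan(
    classified: Sequence[ClassifiedVariant],
    patients: Sequence[PatientPhenotype],
    controls: Sequence[ControlCohortCounts],
    genes: Sequence[str] | None = None,
    class_filter: str = "ptv_only",
    case_label: str = "cases",
    include_founder: bool = True,
) -> list[BurdenResult]:
    """Per-gene case-vs-control carrier comparisons.

    One row per gene x control cohort (genes alphabetical, cohorts in input
    order), plus the recurrent-founder row (CHEK2 c.1100del, keyed by
    variant) and the all-gene carrier row. Genes absent from a control table
    yield an undefined comparison and a logged warning.
    """
    if genes is None:
        genes = sorted({cv.variant.gene_symbol for cv in classified if _qualifies(cv, class_filter)})
    rows: list[tuple[str, Callable | None]] = [(g, None) for g in sorted(genes)]
    if include_founder:
        rows.append((FOUNDER_KEY, _founder_predicate))
    rows.append((ALL_GENES_KEY, None))
    out: list[BurdenResult] = []
    for gene, predicate in rows:
        a, a_n = aggregate_carriers(
            classified, patients, gene, class_filter, variant_predicate=predicate
        )
        for cohort in controls:
            if gene not in cohort.per_gene_carriers:
                logger.warning("gene %s absent from control cohort %s", gene, cohort.cohort_name)
                out.append(
                    BurdenResult(
                        gene, case_label, cohort.cohort_name, a, a_n, 0, cohort.n_total,
                        None, None, None, 1.0, False,
                    )
                )
                continue
            b = cohort.per_gene_carriers[gene]
            out.append(_result(gene, case_label, cohort.cohort_name, a, a_n, b, cohort.n_total))
    return out


#: stratum name -> (label_a, label_b, predicate_a, predicate_b); patients with
#: the relevant attribute unknown are excluded from both denominators,
#: mirroring the "receptor status available" subgroup convention.
STRATA: dict[str, tuple[str, str, Callable, Callable]] = {
    "bilateral_vs_unilateral": (
        "bilateral", "unilateral",
        lambda p: p.bilateral, lambda p: not p.bilateral,
    ),
    "er": (
        "ER-positive", "ER-negative",
        lambda p: p.er == "positive", lambda p: p.er == "negative",
    ),
    "pr": (
        "PR-positive", "PR-negative",
        lambda p: p.pr == "positive", lambda p: p.pr == "negative",
    ),
    "her2": (
        "HER2-positive", "HER2-negative",
        lambda p: p.her2 == "positive", lambda p: p.her2 == "negative",
    ),
    "tnbc": (
        "non-TNBC", "TNBC",
        lambda p: p.tnbc is False, lambda p: p.tnbc is True,
    ),
    "oc_family_history": (
        "with OC family history", "without OC family history",
        lambda p: p.oc_family_history, lambda p: not p.oc_family_history,
    ),
}


def stratified_scan(
    classified: Sequence[ClassifiedVariant],
    patients: Sequence[PatientPhenotype],
    strata: Sequence[str] = ("bilateral_vs_unilateral",),
    class_filter: str = "class45",
    genes: Sequence[str] | None = None,
    include_founder: bool = True,
) -> tuple[list[BurdenResult], pd.DataFrame]:
    """Case-case comparisons across phenotype strata.

    Returns one :class:`BurdenResult` per gene x stratum (group A vs
    group B within cases) plus a long-format prevalence table with per-cell
    carrier counts and percentages.
    """
    if genes is None:
        genes = sorted({cv.variant.gene_symbol for cv in classified if _qualifies(cv, class_filter)})
    rows: list[tuple[str, Callable | None]] = [(g, None) for g in sorted(genes)]
    if include_founder:
        rows.append((FOUNDER_KEY, _founder_predicate))
    rows.append((ALL_GENES_KEY, None))
    results: list[BurdenResult] = []
    prev_rows = []
    for name in strata:
        if name not in STRATA:
            raise ValueError(f"unknown stratum {name!r}; expected one of {sorted(STRATA)}")
        label_a, label_b, pred_a, pred_b = STRATA[name]
        for gene, predicate in rows:
            a, a_n = aggregate_carriers(
                classified, patients, gene, class_filter,
                subgroup=pred_a, variant_predicate=predicate,
            )
            b, b_n = aggregate_carriers(
                classified, patients, gene, class_filter,
                subgroup=pred_b, variant_predicate=predicate,
            )
            if a_n == 0 or b_n == 0:
                res = BurdenResult(
                    gene, label_a, label_b, a, max(a_n, 0), b, max(b_n, 0),
                    None, None, None, 1.0, False,
                )
            else:
                res = _result(gene, label_a, label_b, a, a_n, b, b_n)
            results.append(res)
            for label, carriers, n in ((label_a, a, a_n), (label_b, b, b_n)):
                prev_rows.append(
                    {
                        "stratum": name,
                        "group": label,
                        "gene": gene,
                        "carriers": carriers,
                        "n": n,
                        "percent": 100.0 * carriers / n if n else float("nan"),
                    }
                )
    return results, pd.DataFrame(prev_rows)


def missense_burden(
    classified: Sequence[ClassifiedVariant],
    patients: Sequence[PatientPhenotype],
    controls: Sequence[ControlCohortCounts],
    genes: Sequence[str] | None = None,
) -> list[BurdenResult]:
    """Case-vs-control burden of rare damaging-missense carriers.

    Control tables must hold damaging-missense carrier counts.
    """
    if genes is None:
        genes = sorted(
            {cv.variant.gene_symbol for cv in classified if cv.damaging_missense}
        )
    return burden_scan(
        classified, patients, controls, genes=genes,
        class_filter="damaging_missense", include_founder=False,
    )


@dataclass(frozen=True)
class VusSummary:
    patients_with_vus: int
    distinct_vus: int
    fraction_single_vus: float
    per_gene_vus_patient_counts: Mapping[str, int]


def summarize_vus(
    classified: Sequence[ClassifiedVariant],
    patients: Sequence[PatientPhenotype],
) -> VusSummary:
    """Counts over class-3 assignments (distinctness by gene+coordinates)."""
    per_patient: Counter[str] = Counter()
    distinct: set[tuple[str, str, int, str, str]] = set()
    per_gene: dict[str, set[str]] = {}
    for cv in classified:
        if cv.iarc_class != 3:
            continue
        v = cv.variant
        distinct.add((v.gene_symbol, v.chrom, v.pos, v.ref, v.alt))
        for pid in cv.carriers:
            per_patient[pid] += 1
        per_gene.setdefault(v.gene_symbol, set()).update(cv.carriers)
    n_with = len(per_patient)
    n_single = sum(1 for v in per_patient.values() if v == 1)
    return VusSummary(
        patients_with_vus=n_with,
        distinct_vus=len(distinct),
        fraction_single_vus=n_single / n_with if n_with else float("nan"),
        per_gene_vus_patient_counts={g: len(s) for g, s in sorted(per_gene.items())},
    )


# ---- rendering & IO --------------------------------------------------------


def round2(x: float) -> float:
    """Round half away from zero to 2 decimals (print convention of the tables)."""
    return math.copysign(math.floor(abs(x) * 100 + 0.5) / 100, x)


def render_burden_table(results: Sequence[BurdenResult], bh_column: bool = True) -> pd.DataFrame:
    """Human-readable table: 2-decimal ORs/CIs/prevalences, 'n.a.' for
    undefined cells, optional Benjamini-Hochberg column (supplementary only —
    significance statements follow the raw Fisher p)."""
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene,
                "group_a": r.group_a_label,
                "group_b": r.group_b_label,
                "a_carriers": r.a_carriers,
                "a_n": r.a_n,
                "a_percent": f"{round2(r.a_percent):.2f}",
                "b_carriers": r.b_carriers,
                "b_n": r.b_n,
                "b_percent": f"{round2(r.b_percent):.2f}",
                "OR": f"{round2(r.odds_ratio):.2f}" if r.defined else "n.a.",
                "CI95": (
                    f"{round2(r.ci_low):.2f}-{round2(r.ci_high):.2f}" if r.defined else "n.a."
                ),
                "p_fisher": f"{r.p_fisher:.4f}" if r.p_fisher >= 1e-4 else "<0.0001",
            }
        )
    df = pd.DataFrame(rows)
    if bh_column and len(df):
        from statsmodels.stats.multitest import multipletests

        pvals = np.array([r.p_fisher for r in results])
        df["p_bh"] = [f"{q:.4f}" for q in multipletests(pvals, method="fdr_bh")[1]]
    return df


def write_phenotypes_tsv(patients: Sequence[PatientPhenotype], path: str) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "aad_years": "" if p.aad_years is None else p.aad_years,
            "bilateral": int(p.bilateral),
            "oc_family_history": int(p.oc_family_history),
            "er": {"positive": "pos", "negative": "neg", "unknown": "unknown"}[p.er],
            "pr": {"positive": "pos", "negative": "neg", "unknown": "unknown"}[p.pr],
            "her2": {"positive": "pos", "negative": "neg", "unknown": "unknown"}[p.her2],
        }
        for p in patients
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_RECEPTOR_DECODE = {"pos": "positive", "neg": "negative", "unknown": "unknown"}


def read_phenotypes_tsv(path: str) -> list[PatientPhenotype]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = {"patient_id", "aad_years", "bilateral", "oc_family_history", "er", "pr", "her2"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        aad = None if pd.isna(row.aad_years) else int(row.aad_years)
        out.append(
            PatientPhenotype(
                patient_id=row.patient_id,
                aad_years=aad,
                bilateral=bool(int(row.bilateral)),
                oc_family_history=bool(int(row.oc_family_history)),
                er=_RECEPTOR_DECODE[str(row.er)],
                pr=_RECEPTOR_DECODE[str(row.pr)],
                her2=_RECEPTOR_DECODE[str(row.her2)],
            )
        )
    return out


def write_control_counts_tsv(controls: Sequence[ControlCohortCounts], path: str) -> None:
    rows = []
    for c in controls:
        for gene, count in sorted(c.per_gene_carriers.items()):
            rows.append(
                {"cohort": c.cohort_name, "n_total": c.n_total, "gene": gene, "carriers": count}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_control_counts_tsv(path: str) -> list[ControlCohortCounts]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (cohort, n_total), grp in df.groupby(["cohort", "n_total"], sort=False):
        out.append(
            ControlCohortCounts(
                cohort_name=str(cohort),
                n_total=int(n_total),
                per_gene_carriers={str(r.gene): int(r.carriers) for r in grp.itertuples()},
            )
        )
    return out
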