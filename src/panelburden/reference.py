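"""Published carrier-count tables and a deterministic pseudo-cohort.

The underlying study — gene-panel testing of 5589 BRCA1/2-negative breast
cancer index patients against three control cohorts (ExAC non-Finnish
Europeans excluding TCGA, the FLOSSIES hypernormal controls, and 2189
geographically matched German controls) — did not release patient-level
data, but its report prints per-gene carrier counts for every comparison.
This module encodes those printed counts and reconstitutes a pseudo-cohort
of individual patients whose per-gene, per-stratum carrier counts equal the
printed ones exactly: the two dual-PTV carriers (ATM+CHEK2, NBN+RAD51C),
the CHEK2 c.1100del founder split, the bilateral margins (including the
NBN-bilateral zero), and the ER/PR/HER2/TNBC margins of the 3104-patient
receptor subgroup. Running the real burden pipeline over this pseudo-cohort
therefore reproduces every defined published odds ratio from first
principles, which is the package's primary regression surface.

All patient-level attributes beyond the printed margins (which particular
patient carries which variant, joint receptor combinations, individual
ages) are synthetic reconstructions; only the margins are data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .burden import ALL_GENES_KEY, FOUNDER_KEY, ControlCohortCounts, PatientPhenotype
from .classification import ClassifiedVariant, ConsequenceCall, VariantRecord

__all__ = [
    "N_CASES",
    "GENES",
    "PTV_CASE_COUNTS",
    "CLASS45_CASE_COUNTS",
    "BILATERAL_N",
    "CONTROL_TABLES",
    "DMIS_CASE_COUNTS",
    "DMIS_CONTROL_TABLES",
    "AAD_TABLE",
    "control_cohorts",
    "dmis_control_cohorts",
    "fixture_cohort",
    "FixtureCohort",
]

N_CASES = 5589
BILATERAL_N = 629
RECEPTOR_SUBSET_N = 3104
OC_FH_N = 934
AAD_MISSING_N = 49

GENES = ("ATM", "CDH1", "CHEK2", "NBN", "PALB2", "RAD51C", "RAD51D", "TP53")

#: deleterious PTV carriers among the 5589 cases (case-control comparison)
PTV_CASE_COUNTS = {
    "ATM": 71, "CDH1": 7, "CHEK2": 103, "NBN": 12,
    "PALB2": 64, "RAD51C": 9, "RAD51D": 5, "TP53": 3,
    FOUNDER_KEY: 79, ALL_GENES_KEY: 272,
}

#: class 4/5 carriers among the 5589 cases (case-case comparisons)
CLASS45_CASE_COUNTS = {
    "ATM": 81, "CDH1": 8, "CHEK2": 138, "NBN": 12,
    "PALB2": 68, "RAD51C": 11, "RAD51D": 6, "TP53": 17,
    FOUNDER_KEY: 79, ALL_GENES_KEY: 339,
}

#: control cohort sizes and per-gene deleterious-PTV carrier counts
CONTROL_TABLES = {
    "ExAC": {
        "n": 27173,
        "ATM": 96, "CDH1": 2, "CHEK2": 172, "NBN": 42,
        "PALB2": 33, "RAD51C": 34, "RAD51D": 8, "TP53": 2,
        FOUNDER_KEY: 127, ALL_GENES_KEY: 389,
    },
    "FLOSSIES": {
        "n": 7325,
        "ATM": 14, "CDH1": 0, "CHEK2": 28, "NBN": 14,
        "PALB2": 7, "RAD51C": 2, "RAD51D": 2, "TP53": 0,
        FOUNDER_KEY: 22, ALL_GENES_KEY: 67,
    },
    "GMC": {
        "n": 2189,
        "ATM": 9, "CDH1": 0, "CHEK2": 11, "NBN": 9,
        "PALB2": 2, "RAD51C": 2, "RAD51D": 0, "TP53": 0,
        FOUNDER_KEY: 8, ALL_GENES_KEY: 33,
    },
}

#: rare damaging-missense carriers (consensus of both in-silico predictors)
DMIS_CASE_COUNTS = {"CHEK2": 80, "TP53": 23}
DMIS_CONTROL_TABLES = {"ExAC": {"n": 27173, "CHEK2": 193, "TP53": 49}}

#: per-gene age at first diagnosis of the class-4/5 carriers: (n, mean, lo, hi)
AAD_TABLE = {
    "overall": (5540, 46.7, 17, 92),
    "ATM": (81, 45.0, 27, 80),
    "CDH1": (8, 45.1, 33, 59),
    "CHEK2": (138, 47.1, 29, 75),
    "NBN": (12, 46.3, 33, 74),
    "PALB2": (68, 45.8, 28, 78),
    "RAD51C": (11, 44.9, 33, 53),
    "RAD51D": (6, 46.8, 33, 60),
    "TP53": (17, 39.7, 23, 71),
}

# Carrier groups used to build the pseudo-cohort. CHEK2 is split into the
# c.1100del founder carriers and the remaining deleterious carriers so the
# founder margins of the bilateral and receptor tables can be honoured.
# Per group: total carriers, PTV carriers among them, bilateral carriers,
# and receptor-subgroup margins (subset_n, er_neg, pr_neg, her2_neg, tnbc).
@dataclass(frozen=True)
class _Group:
    name: str
    gene: str
    n: int
    n_ptv: int
    n_bilateral: int
    subset: tuple[int, int, int, int, int]
    founder: bool = False


_GROUPS = (
    _Group("ATM", "ATM", 81, 71, 10, (47, 4, 8, 40, 2)),
    _Group("CHEK2_founder", "CHEK2", 79, 79, 16, (52, 9, 10, 32, 3), founder=True),
    _Group("CHEK2_other", "CHEK2", 59, 24, 4, (38, 5, 10, 24, 1)),
    _Group("CDH1", "CDH1", 8, 7, 1, (7, 1, 3, 6, 1)),
    _Group("NBN", "NBN", 12, 12, 0, (5, 1, 2, 5, 1)),
    _Group("RAD51C", "RAD51C", 11, 9, 1, (4, 1, 2, 3, 1)),
    _Group("RAD51D", "RAD51D", 6, 5, 1, (3, 2, 2, 3, 2)),
    _Group("PALB2", "PALB2", 68, 64, 14, (40, 9, 11, 36, 8)),
    _Group("TP53", "TP53", 17, 3, 5, (10, 3, 2, 5, 1)),
)

# VUS layout consistent with the reported totals: 421 distinct VUS across
# 827 patients, 761 of whom carry a single VUS; per-gene patient counts for
# ATM/CHEK2/PALB2 as printed, remainder spread over the other genes.
_VUS_PATIENTS = {
    "ATM": 322, "CHEK2": 196, "PALB2": 76, "CDH1": 50,
    "NBN": 70, "RAD51C": 60, "RAD51D": 50, "TP53": 69,
}
_VUS_DISTINCT = {
    "ATM": 150, "CHEK2": 60, "PALB2": 40, "CDH1": 30,
    "NBN": 40, "RAD51C": 35, "RAD51D": 30, "TP53": 36,
}


def control_cohorts() -> list[ControlCohortCounts]:
    """The three control cohorts as :class:`ControlCohortCounts` (PTV counts)."""
    out = []
    for name, table in CONTROL_TABLES.items():
        counts = {k: v for k, v in table.items() if k != "n"}
        out.append(ControlCohortCounts(name, table["n"], counts))
    return out


def dmis_control_cohorts() -> list[ControlCohortCounts]:
    out = []
    for name, table in DMIS_CONTROL_TABLES.items():
        counts = {k: v for k, v in table.items() if k != "n"}
        out.append(ControlCohortCounts(name, table["n"], counts))
    return out


# ---- pseudo-cohort construction -------------------------------------------


def _receptor_triples(n: int, er_neg: int, pr_neg: int, her2_neg: int, tnbc: int):
    """Joint ER/PR/HER2 assignment matching four margins without excess TNBC.

    The first ``tnbc`` members are triple-negative; remaining negative calls
    are laid out as wrapped consecutive blocks so no additional member
    collects all three negatives. Feasibility is asserted.
    """
    assert tnbc <= min(er_neg, pr_neg, her2_neg) and n >= tnbc
    rest = n - tnbc
    a, b, c = er_neg - tnbc, pr_neg - tnbc, her2_neg - tnbc
    assert a + b + c <= 2 * rest if rest else (a == b == c == 0)
    triples = [("negative", "negative", "negative")] * tnbc
    er = [False] * rest
    pr = [False] * rest
    her2 = [False] * rest
    for i in range(a):
        er[i] = True
    for i in range(a, a + b):
        pr[i % rest] = True
    for i in range(a + b, a + b + c):
        her2[i % rest] = True
    for i in range(rest):
        assert not (er[i] and pr[i] and her2[i]), "unintended TNBC"
        triples.append(
            (
                "negative" if er[i] else "positive",
                "negative" if pr[i] else "positive",
                "negative" if her2[i] else "positive",
            )
        )
    assert sum(t[0] == "negative" for t in triples) == er_neg
    assert sum(t[1] == "negative" for t in triples) == pr_neg
    assert sum(t[2] == "negative" for t in triples) == her2_neg
    return triples


def _ages(n: int, mean: float, lo: int, hi: int) -> list[int]:
    """Deterministic integer ages spanning [lo, hi] with the requested mean."""
    if n == 0:
        return []
    target = round(mean * n)
    if n == 1:
        return [min(max(target, lo), hi)]
    ages = [lo + ((hi - lo) * i) // (n - 1) for i in range(n)]
    diff = target - sum(ages)
    guard = 2 * n * (hi - lo) + abs(diff) + 1
    k = 0
    idx = list(range(1, n - 1)) or [0]
    while diff != 0 and guard:
        i = idx[k % len(idx)]
        if diff > 0 and ages[i] < hi:
            ages[i] += 1
            diff -= 1
        elif diff < 0 and ages[i] > lo:
            ages[i] -= 1
            diff += 1
        k += 1
        guard -= 1
    assert diff == 0, "age list cannot reach target mean within bounds"
    return ages


@dataclass
class FixtureCohort:
    classified: list[ClassifiedVariant]
    patients: list[PatientPhenotype]
    controls: list[ControlCohortCounts]
    dmis_controls: list[ControlCohortCounts]


def _pid(i: int) -> str:
    return f"P{i:04d}"


def fixture_cohort() -> FixtureCohort:
    """Deterministic pseudo-cohort reproducing every printed carrier margin."""
    # --- carrier membership --------------------------------------------------
    # Patient indices 0..338 are deleterious carriers. The dual carriers are
    # index 0 (ATM PTV + CHEK2 non-founder PTV) and index 226 (NBN PTV +
    # RAD51C PTV); all other group blocks are disjoint.
    members: dict[str, list[int]] = {}
    cursor = 0

    def block(size: int) -> list[int]:
        nonlocal cursor
        ids = list(range(cursor, cursor + size))
        cursor += size
        return ids

    members["ATM"] = block(81)  # 0..80, index 0 dual
    members["CHEK2_founder"] = block(79)  # 81..159
    members["CHEK2_other"] = [0] + block(58)  # dual + 160..217
    members["CDH1"] = block(8)  # 218..225
    members["NBN"] = block(12)  # 226..237, index 226 dual
    members["RAD51C"] = [226] + block(10)  # dual + 238..247
    members["RAD51D"] = block(6)  # 248..253
    members["PALB2"] = block(68)  # 254..321
    members["TP53"] = block(17)  # 322..338
    n_carriers = cursor
    assert n_carriers == 339
    groups = {g.name: g for g in _GROUPS}
    for name, ids in members.items():
        assert len(ids) == groups[name].n, name

    ptv_members = {name: ids[: groups[name].n_ptv] for name, ids in members.items()}
    distinct_ptv = set().union(*ptv_members.values())
    assert len(distinct_ptv) == PTV_CASE_COUNTS[ALL_GENES_KEY] == 272
    assert sum(len(v) for v in ptv_members.values()) == 274  # two dual-PTV patients

    # --- phenotype margins ---------------------------------------------------
    duals = {0, 226}
    bilateral: set[int] = set()
    for name, ids in members.items():
        chosen = [i for i in ids if i not in duals][-groups[name].n_bilateral or len(ids):]
        chosen = chosen[: groups[name].n_bilateral]
        bilateral.update(chosen)
    assert len(bilateral) == 52
    bilateral.update(range(n_carriers, n_carriers + (BILATERAL_N - 52)))  # 339..915
    assert len(bilateral) == BILATERAL_N

    receptor: dict[int, tuple[str, str, str]] = {}
    for name, ids in members.items():
        g = groups[name]
        subset_n, er_neg, pr_neg, her2_neg, tnbc = g.subset
        eligible = [i for i in ids if i not in duals][:subset_n]
        assert len(eligible) == subset_n, name
        for i, triple in zip(eligible, _receptor_triples(subset_n, er_neg, pr_neg, her2_neg, tnbc)):
            receptor[i] = triple
    carrier_subset = len(receptor)
    assert carrier_subset == 206
    nc_subset_n = RECEPTOR_SUBSET_N - carrier_subset
    nc_er = (749 - 35, 916 - 50, 2447 - 154, 482 - 20)
    nc_ids = list(range(916, 916 + nc_subset_n))
    for i, triple in zip(nc_ids, _receptor_triples(nc_subset_n, *nc_er)):
        receptor[i] = triple
    assert len(receptor) == RECEPTOR_SUBSET_N

    # --- ages ----------------------------------------------------------------
    aad: dict[int, int] = {}
    # per-gene carrier ages; dual patients keep the age of their first gene
    chek2_ids = [i for i in members["CHEK2_founder"] + members["CHEK2_other"] if i not in duals]
    age_plan = [
        ("ATM", members["ATM"]),
        ("CHEK2", chek2_ids),
        ("CDH1", members["CDH1"]),
        ("NBN", members["NBN"]),
        ("RAD51C", [i for i in members["RAD51C"] if i not in duals]),
        ("RAD51D", members["RAD51D"]),
        ("PALB2", members["PALB2"]),
        ("TP53", members["TP53"]),
    ]
    for gene, ids in age_plan:
        _, mean, lo, hi = AAD_TABLE[gene]
        for i, age in zip(ids, _ages(len(ids), mean, lo, hi)):
            aad[i] = age
    carrier_sum = sum(aad.values())
    n_overall, mean_overall, lo_all, hi_all = AAD_TABLE["overall"]
    n_nc_aged = n_overall - len(aad)
    nc_mean = (round(mean_overall * n_overall) - carrier_sum) / n_nc_aged
    nc_aged = list(range(n_carriers, n_carriers + n_nc_aged))
    for i, age in zip(nc_aged, _ages(n_nc_aged, nc_mean, lo_all, hi_all)):
        aad[i] = age
    assert len(aad) == n_overall  # the remaining 49 patients lack an AAD

    oc_fh = {i for i in range(N_CASES) if (i + 1) * OC_FH_N // N_CASES != i * OC_FH_N // N_CASES}
    assert len(oc_fh) == OC_FH_N

    patients = []
    for i in range(N_CASES):
        er, pr, her2 = receptor.get(i, ("unknown", "unknown", "unknown"))
        patients.append(
            PatientPhenotype(
                patient_id=_pid(i),
                aad_years=aad.get(i),
                bilateral=i in bilateral,
                oc_family_history=i in oc_fh,
                er=er,
                pr=pr,
                her2=her2,
            )
        )

    # --- classified deleterious variants ------------------------------------
    classified: list[ClassifiedVariant] = []
    pos_counter: dict[str, int] = {}

    def next_pos(gene: str) -> int:
        pos_counter[gene] = pos_counter.get(gene, 10_000) + 10
        return pos_counter[gene]

    def add_variant(gene, patient_ids, category, cls, rationale, variant_id="",
                    dmis=False, mafs=None, verdicts=None, pos=None):
        anchor = 100 if category in ("nonsense", "frameshift", "missense") else None
        variant = VariantRecord(
            chrom=f"chr{gene}",
            pos=pos if pos is not None else next_pos(gene),
            ref="AG" if category == "frameshift" else "G",
            alt="A" if category == "frameshift" else "T",
            gene_symbol=gene,
            transcript_id=f"TX_{gene}",
            mafs=mafs or {},
            predictor_verdicts=verdicts or {},
            variant_id=variant_id,
        )
        classified.append(
            ClassifiedVariant(
                variant=variant,
                consequence=ConsequenceCall(category, cds_anchor=anchor),
                is_ptv=category in ("nonsense", "frameshift", "essential_splice"),
                iarc_class=cls,
                rationale=rationale,
                damaging_missense=dmis,
                carriers=tuple(_pid(i) for i in patient_ids),
            )
        )

    for name, ids in members.items():
        g = groups[name]
        ptv_ids = ptv_members[name]
        if g.founder:
            add_variant(
                g.gene, ptv_ids, "frameshift", 5, ("ptv_class5",),
                variant_id=FOUNDER_KEY, pos=1100,
            )
        else:
            for i in ptv_ids:
                add_variant(g.gene, [i], "nonsense", 5, ("ptv_class5",))
        for i in ids[g.n_ptv:]:
            # non-truncating deleterious variants (established pathogenic
            # missense), representable only through the override pathway
            add_variant(g.gene, [i], "missense", 5, ("override",))

    # --- VUS and damaging-missense layer -------------------------------------
    vus_pool = list(range(3300, 3300 + 827))
    slots: list[tuple[str, int]] = []  # (gene, patient index)
    k = 0
    for gene in GENES:
        for _ in range(_VUS_PATIENTS[gene]):
            patient = vus_pool[k] if k < 827 else vus_pool[k - 827]
            slots.append((gene, patient))
            k += 1
    by_gene: dict[str, list[int]] = {}
    for gene, patient in slots:
        by_gene.setdefault(gene, []).append(patient)
    for gene in GENES:
        carriers = by_gene[gene]
        n_distinct = _VUS_DISTINCT[gene]
        dmis_n = DMIS_CASE_COUNTS.get(gene, 0)
        dmis_carriers, rest = carriers[:dmis_n], carriers[dmis_n:]
        n_dmis_var = max(1, dmis_n // 4) if dmis_n else 0
        n_rest_var = n_distinct - n_dmis_var
        assert n_rest_var >= 1 and len(rest) >= n_rest_var
        for j in range(n_dmis_var):
            ids = dmis_carriers[j::n_dmis_var]
            add_variant(
                gene, ids, "missense", 3,
                ("default_vus", "missense_vus", "damaging_missense_flag"),
                dmis=True, mafs={"MAF_EXAC": 0.0005},
                verdicts={"PRED1": "damaging", "PRED2": "damaging"},
            )
        for j in range(n_rest_var):
            ids = rest[j::n_rest_var]
            add_variant(
                gene, ids, "missense", 3, ("default_vus", "missense_vus"),
                verdicts={"PRED1": "damaging", "PRED2": "tolerated"},
            )

    _check_margins(classified, patients)
    return FixtureCohort(
        classified=classified,
        patients=patients,
        controls=control_cohorts(),
        dmis_controls=dmis_control_cohorts(),
    )


def _check_margins(classified, patients) -> None:
    """Construction-time audit: the pseudo-cohort must hit every printed margin."""
    from .burden import aggregate_carriers

    for gene in GENES:
        c45, _ = aggregate_carriers(classified, patients, gene, "class45")
        assert c45 == CLASS45_CASE_COUNTS[gene], (gene, c45)
        ptv, _ = aggregate_carriers(classified, patients, gene, "ptv_only")
        assert ptv == PTV_CASE_COUNTS[gene], (gene, ptv)
    all45, _ = aggregate_carriers(classified, patients, ALL_GENES_KEY, "class45")
    assert all45 == CLASS45_CASE_COUNTS[ALL_GENES_KEY]
    allptv, _ = aggregate_carriers(classified, patients, ALL_GENES_KEY, "ptv_only")
    assert allptv == PTV_CASE_COUNTS[ALL_GENES_KEY]
    founder, _ = aggregate_carriers(
        classified, patients, "CHEK2", "ptv_only",
        variant_predicate=lambda cv: cv.variant.variant_id == FOUNDER_KEY,
    )
    assert founder == PTV_CASE_COUNTS[FOUNDER_KEY]
    n_bilat = sum(p.bilateral for p in patients)
    assert n_bilat == BILATERAL_N
    n_subset = sum(p.receptor_known for p in patients)
    assert n_subset == RECEPTOR_SUBSET_N
    assert sum(p.er == "negative" for p in patients) == 749
    assert sum(p.pr == "negative" for p in patients) == 916
    assert sum(p.her2 == "negative" for p in patients) == 2447
    assert sum(p.tnbc is True for p in patients) == 482
    assert sum(p.aad_years is not None for p in patients) == AAD_TABLE["overall"][0]
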