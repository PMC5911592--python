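"""Synthetic cohort generator.

Emulates the statistical structure of a germline panel-testing study of
BRCA1/2-negative breast-cancer index patients: eight cancer-predisposition
genes with realistic transcript geometry, per-gene deleterious-variant
carrier probabilities at the published case and control prevalences,
phenotype-dependent carrier enrichment (bilateral disease, receptor
subtypes), a recurrent founder frameshift (CHEK2 c.1100del-like), an
NMD-escape-zone mixture with domain rescue, a VUS/damaging-missense layer,
and three control cohorts drawn at their published sizes.

Every artifact (VCF, GFF3, coding-sequence FASTA, phenotype and control
tables, truth table) is reproducible byte-for-byte from the single config
seed. The truth table records the latent per-patient carrier states so
estimator-recovery tests can compare pipeline output against the simulated
truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from . import reference as ref
from .burden import ALL_GENES_KEY, FOUNDER_KEY, ControlCohortCounts, PatientPhenotype
from .transcripts import Domain, TranscriptModel, cds_to_genomic, genomic_to_cds, nmd_escape_zone, write_gff3

__all__ = [
    "GeneSimConfig",
    "GeneEffects",
    "PhenotypeModel",
    "SimulationConfig",
    "SimulatedCohort",
    "default_config",
    "make_transcript",
    "make_cds_sequence",
    "simulate_cohort",
    "draw_phenotype_arrays",
    "draw_case_carrier_matrix",
    "draw_control_counts",
]

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# codon -> [(offset, alt_base)] substitutions that create a stop codon
_NONSENSE_ROUTES: dict[str, list[tuple[int, str]]] = {}
for _codon in _SENSE_CODONS:
    routes = []
    for _i in range(3):
        for _b in "ACGT":
            if _b != _codon[_i] and _codon[:_i] + _b + _codon[_i + 1 :] in _STOPS:
                routes.append((_i, _b))
    if routes:
        _NONSENSE_ROUTES[_codon] = routes


# ---- configuration ---------------------------------------------------------

#: canonical-transcript-like geometry: (n_exons, cds_length)
_DEFAULT_GEOMETRY = {
    "ATM": (63, 9171),
    "CDH1": (16, 2649),
    "CHEK2": (15, 1632),
    "NBN": (16, 2265),
    "PALB2": (13, 3561),
    "RAD51C": (9, 1131),
    "RAD51D": (10, 987),
    "TP53": (11, 1182),
}


@dataclass(frozen=True)
class GeneSimConfig:
    gene_symbol: str
    case_carrier_prob: float  # deleterious (counted) PTV carrier probability
    control_carrier_probs: Mapping[str, float]  # cohort -> PTV carrier prob
    class45_extra_prob: float = 0.0  # non-PTV deleterious (pathogenic missense)
    fraction_ptv_in_escape_zone: float = 0.10  # of case PTVs; rescued by a domain
    vus_ptv_prob: float = 0.0005  # escape-zone PTVs without domain rescue -> VUS
    missense_vus_prob: float = 0.005
    damaging_missense_prob: float = 0.0  # rare missense, both predictors damaging
    control_dmis_probs: Mapping[str, float] = field(default_factory=dict)
    founder_fraction: float = 0.0  # of case PTV carriers with the founder allele
    control_founder_fractions: Mapping[str, float] = field(default_factory=dict)
    common_benign_prob: float = 0.01  # carrier prob of one MAF>=1% benign variant
    n_exons: int = 12
    cds_length: int = 1800
    domain_layout: str | Sequence[tuple[str, int, int]] = "auto"

    def __post_init__(self) -> None:
        probs = [
            self.case_carrier_prob, self.class45_extra_prob,
            self.fraction_ptv_in_escape_zone, self.vus_ptv_prob,
            self.missense_vus_prob, self.damaging_missense_prob,
            self.founder_fraction, self.common_benign_prob,
            *self.control_carrier_probs.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError(f"{self.gene_symbol}: probability outside [0,1]")


@dataclass(frozen=True)
class GeneEffects:
    """Per-gene phenotype effects on the carrier log-odds and on AAD (years)."""

    bilateral_log_or: float = 0.0
    er_neg_log_or: float = 0.0
    her2_pos_log_or: float = 0.0
    aad_shift: float = 0.0


@dataclass(frozen=True)
class PhenotypeModel:
    aad_mean: float = 46.7
    aad_sd: float = 11.0
    aad_range: tuple[int, int] = (17, 92)
    aad_missing_prob: float = 49 / 5589
    bilateral_prob: float = 629 / 5589
    oc_fh_prob: float = 934 / 5589
    receptor_known_prob: float = 3104 / 5589
    er_pos_prob: float = 2355 / 3104
    pr_pos_prob: float = 2188 / 3104
    her2_pos_prob: float = 657 / 3104

    def __post_init__(self) -> None:
        lo, hi = self.aad_range
        if not 10 <= lo < hi <= 110:
            raise ValueError("aad_range must lie within [10,110]")
        for p in (
            self.aad_missing_prob, self.bilateral_prob, self.oc_fh_prob,
            self.receptor_known_prob, self.er_pos_prob, self.pr_pos_prob,
            self.her2_pos_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("phenotype probability outside [0,1]")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_cases: int = 5589
    control_cohort_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"ExAC": 27173, "FLOSSIES": 7325, "GMC": 2189}
    )
    genes: tuple[GeneSimConfig, ...] = ()
    phenotype_model: PhenotypeModel = field(default_factory=PhenotypeModel)
    effects: Mapping[str, GeneEffects] = field(default_factory=dict)
    dual_carrier_count: int | None = None  # None = independent per-gene draws


def default_config(seed: int, n_cases: int = ref.N_CASES) -> SimulationConfig:
    """Study-scale defaults: published per-gene carrier prevalences and
    phenotype margins; effect sizes from the published case-case tables."""
    n = ref.N_CASES
    dmis_case = {"ATM": 0.006, "CDH1": 0.001, "NBN": 0.001, "PALB2": 0.002,
                 "RAD51C": 0.001, "RAD51D": 0.0008,
                 "CHEK2": ref.DMIS_CASE_COUNTS["CHEK2"] / n,
                 "TP53": ref.DMIS_CASE_COUNTS["TP53"] / n}
    dmis_exac = {"ATM": 0.0055, "CDH1": 0.0009, "NBN": 0.0009, "PALB2": 0.0018,
                 "RAD51C": 0.0009, "RAD51D": 0.0007,
                 "CHEK2": ref.DMIS_CONTROL_TABLES["ExAC"]["CHEK2"] / 27173,
                 "TP53": ref.DMIS_CONTROL_TABLES["ExAC"]["TP53"] / 27173}
    vus = {"ATM": 322 / n, "CHEK2": 196 / n, "PALB2": 76 / n, "CDH1": 0.008,
           "NBN": 0.009, "RAD51C": 0.009, "RAD51D": 0.008, "TP53": 69 / n}
    genes = []
    for g in ref.GENES:
        n_ex, cds_len = _DEFAULT_GEOMETRY[g]
        founder_frac = (
            ref.PTV_CASE_COUNTS[FOUNDER_KEY] / ref.PTV_CASE_COUNTS["CHEK2"]
            if g == "CHEK2" else 0.0
        )
        control_probs = {
            name: table[g] / table["n"] for name, table in ref.CONTROL_TABLES.items()
        }
        founder_fracs = (
            {
                name: table[FOUNDER_KEY] / table["CHEK2"]
                for name, table in ref.CONTROL_TABLES.items()
            }
            if g == "CHEK2" else {}
        )
        genes.append(
            GeneSimConfig(
                gene_symbol=g,
                case_carrier_prob=ref.PTV_CASE_COUNTS[g] / n,
                control_carrier_probs=control_probs,
                class45_extra_prob=(ref.CLASS45_CASE_COUNTS[g] - ref.PTV_CASE_COUNTS[g]) / n,
                missense_vus_prob=max(vus[g] - dmis_case[g], 0.0),
                damaging_missense_prob=dmis_case[g],
                control_dmis_probs={"ExAC": dmis_exac[g]},
                founder_fraction=founder_frac,
                control_founder_fractions=founder_fracs,
                n_exons=n_ex,
                cds_length=cds_len,
            )
        )
    effects = {
        "ATM": GeneEffects(math.log(1.11), math.log(1 / 3.46), 0.0, -1.7),
        "CDH1": GeneEffects(math.log(1.13), 0.0, 0.0, -1.6),
        "CHEK2": GeneEffects(math.log(1.35), math.log(1 / 1.75), math.log(2.33), 0.4),
        "NBN": GeneEffects(0.0, 0.0, 0.0, -0.4),
        "PALB2": GeneEffects(math.log(2.07), 0.0, 0.0, -0.9),
        "RAD51C": GeneEffects(math.log(0.79), 0.0, 0.0, -1.8),
        "RAD51D": GeneEffects(math.log(1.58), 0.0, 0.0, 0.1),
        "TP53": GeneEffects(math.log(3.30), 0.0, 0.0, -7.0),
    }
    return SimulationConfig(seed=seed, n_cases=n_cases, genes=tuple(genes), effects=effects)


# ---- transcript fabrication ------------------------------------------------


def _genomic_of_tpos(exons: Sequence[tuple[int, int]], strand: str, tpos: int) -> int:
    t = 0
    for s, e in exons:
        length = e - s + 1
        if tpos <= t + length:
            off = tpos - t - 1
            return s + off if strand == "+" else e - off
        t += length
    raise ValueError("tpos beyond transcript")


def make_transcript(
    gene_symbol: str,
    n_exons: int,
    cds_length: int,
    domain_layout: str | Sequence[tuple[str, int, int]] = "auto",
    seed: int = 0,
    strand: str | None = None,
    chrom: str | None = None,
) -> TranscriptModel:
    """Fabricate a valid random transcript model, reproducible per seed.

    Exon sizes are a random composition of the total exonic length (each
    exon >=30 nt), intron sizes 80-2000 nt. With ``domain_layout='auto'``
    two domains are placed: one mid-protein and one straddling the start of
    the NMD-escape zone (so both domain-rescued and unrescued escape-zone
    truncations are constructible).
    """
    if cds_length % 3 != 0 or cds_length < 90:
        raise ValueError(f"{gene_symbol}: cds_length must be a multiple of 3 and >=90")
    if n_exons < 1:
        raise ValueError("n_exons must be >=1")
    rng = np.random.default_rng(seed)
    strand = strand or ("+" if rng.integers(2) else "-")
    chrom = chrom or f"chr{gene_symbol}"
    utr5 = int(rng.integers(100, 300))
    utr3 = int(rng.integers(150, 500))
    total = utr5 + cds_length + utr3
    if total < 30 * n_exons:
        raise ValueError(f"{gene_symbol}: geometry infeasible for {n_exons} exons")
    extra = rng.multinomial(total - 30 * n_exons, np.full(n_exons, 1 / n_exons))
    sizes = 30 + extra
    introns = rng.integers(80, 2001, size=max(n_exons - 1, 1))
    gstart = int(rng.integers(10_000, 1_000_000))
    intervals = []
    pos = gstart
    for i, size in enumerate(sizes):
        intervals.append((pos, pos + int(size) - 1))
        if i < n_exons - 1:
            pos += int(size) + int(introns[i])
    exons = tuple(intervals) if strand == "+" else tuple(intervals[::-1])
    cds_start_g = _genomic_of_tpos(exons, strand, utr5 + 1)
    cds_end_g = _genomic_of_tpos(exons, strand, utr5 + cds_length)
    tx = TranscriptModel(
        gene_symbol=gene_symbol,
        transcript_id=f"TX_{gene_symbol}",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start_genomic=cds_start_g,
        cds_end_genomic=cds_end_g,
    )
    if domain_layout == "auto":
        plen = tx.protein_length
        zone_start, _ = nmd_escape_zone(tx)
        zone_aa = (zone_start + 2) // 3
        d1 = Domain("DOM_mid", max(1, round(0.2 * plen)), max(2, round(0.3 * plen)))
        d2 = Domain(
            "DOM_tail",
            max(1, min(zone_aa - 10, plen - 1)),
            max(2, min(zone_aa + 5, plen)),
        )
        domains = (d1, d2) if d2.aa_start > d1.aa_end else (d1,)
    else:
        domains = tuple(Domain(n, a, b) for n, a, b in domain_layout)
    return tx.with_domains(domains)


def make_cds_sequence(cds_length: int, rng: np.random.Generator) -> str:
    """Random coding sequence: ATG, sense codons, terminal TAA."""
    n_mid = cds_length // 3 - 2
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_mid)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in idx) + "TAA"


# ---- phenotype and carrier draws ------------------------------------------


def draw_phenotype_arrays(config: SimulationConfig, rng: np.random.Generator) -> dict:
    """Vectorised phenotype draws (independent margins; receptor status only
    for the fraction with status available)."""
    n = config.n_cases
    pm = config.phenotype_model
    bilateral = rng.random(n) < pm.bilateral_prob
    oc_fh = rng.random(n) < pm.oc_fh_prob
    known = rng.random(n) < pm.receptor_known_prob
    er_pos = rng.random(n) < pm.er_pos_prob
    pr_pos = rng.random(n) < pm.pr_pos_prob
    her2_pos = rng.random(n) < pm.her2_pos_prob
    return {
        "bilateral": bilateral,
        "oc_fh": oc_fh,
        "receptor_known": known,
        "er_pos": er_pos & known,
        "er_neg": ~er_pos & known,
        "pr_pos": pr_pos & known,
        "her2_pos": her2_pos & known,
        "her2_neg": ~her2_pos & known,
    }


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept b0 with mean(expit(b0 + eta)) = target (bisection)."""
    if target <= 0:
        return -math.inf
    lo, hi = logit(target) - 8.0, logit(target) + 8.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if float(np.mean(expit(mid + eta))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _gene_eta(effects: GeneEffects, phen: dict) -> np.ndarray:
    return (
        effects.bilateral_log_or * phen["bilateral"]
        + effects.er_neg_log_or * phen["er_neg"]
        + effects.her2_pos_log_or * phen["her2_pos"]
    ).astype(float)


def draw_case_carrier_matrix(
    config: SimulationConfig,
    rng: np.random.Generator,
    phen: dict,
    prob_attr: str = "case_carrier_prob",
) -> np.ndarray:
    """Bernoulli carrier matrix (n_cases x genes) with phenotype-dependent
    odds, intercept-calibrated so each gene's marginal prevalence equals its
    configured probability."""
    n = config.n_cases
    cols = []
    for gene_cfg in config.genes:
        p = getattr(gene_cfg, prob_attr)
        eff = config.effects.get(gene_cfg.gene_symbol, GeneEffects())
        eta = _gene_eta(eff, phen)
        b0 = _calibrate_intercept(eta, p)
        probs = expit(b0 + eta) if np.isfinite(b0) else np.zeros(n)
        cols.append(rng.random(n) < probs)
    return np.column_stack(cols)


def _adjust_dual_carriers(matrix: np.ndarray, target: int) -> np.ndarray:
    """Deterministically move carrierships between patients until exactly
    ``target`` patients carry >=2 variants; per-gene marginals preserved."""
    m = matrix.copy()
    while True:
        rowsum = m.sum(axis=1)
        duals = np.flatnonzero(rowsum >= 2)
        if len(duals) == target:
            return m
        if len(duals) > target:
            patient = duals[-1]
            gene = np.flatnonzero(m[patient])[-1]
            free = np.flatnonzero(rowsum == 0)
            if len(free) == 0:
                return m  # cohort saturated; cannot reduce further
            m[patient, gene] = False
            m[free[0], gene] = True
        else:
            singles = np.flatnonzero(rowsum == 1)
            if len(singles) < 2:
                return m
            p = singles[0]
            gene_p = np.flatnonzero(m[p])[0]
            q = next((s for s in singles[1:] if np.flatnonzero(m[s])[0] != gene_p), None)
            if q is None:
                return m
            gene_q = np.flatnonzero(m[q])[0]
            m[q, gene_q] = False
            m[p, gene_q] = True


def draw_control_counts(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[ControlCohortCounts], list[ControlCohortCounts]]:
    """Per-cohort control carrier counts from per-individual Bernoulli draws
    (so the deduplicated all-gene and founder-subset counts are coherent)."""
    controls, dmis_controls = [], []
    for cohort, n_total in config.control_cohort_sizes.items():
        counts: dict[str, int] = {}
        matrix = np.zeros((n_total, len(config.genes)), dtype=bool)
        founder_count = 0
        for j, gene_cfg in enumerate(config.genes):
            p = gene_cfg.control_carrier_probs.get(cohort, 0.0)
            matrix[:, j] = rng.random(n_total) < p
            counts[gene_cfg.gene_symbol] = int(matrix[:, j].sum())
            frac = gene_cfg.control_founder_fractions.get(cohort, 0.0)
            if frac > 0:
                founder_count = int(rng.binomial(counts[gene_cfg.gene_symbol], frac))
        counts[FOUNDER_KEY] = founder_count
        counts[ALL_GENES_KEY] = int((matrix.any(axis=1)).sum())
        controls.append(ControlCohortCounts(cohort, n_total, counts))
        dcounts = {
            g.gene_symbol: int(rng.binomial(n_total, g.control_dmis_probs.get(cohort, 0.0)))
            for g in config.genes
            if cohort in g.control_dmis_probs
        }
        if dcounts:
            dmis_controls.append(ControlCohortCounts(cohort, n_total, dcounts))
    return controls, dmis_controls


# ---- variant fabrication ---------------------------------------------------


def _tx_base_to_genomic(tx: TranscriptModel, base: str) -> str:
    return base if tx.strand == "+" else base.translate(_COMPLEMENT)


def _near_exon_boundary(tx: TranscriptModel, gpos: int, margin: int = 2) -> bool:
    for s, e in tx.exons:
        if abs(gpos - s) <= margin or abs(gpos - e) <= margin:
            return True
    return False


class _VariantFactory:
    """Concrete ref/alt/position construction on one fabricated transcript."""

    def __init__(self, tx: TranscriptModel, cds_seq: str, rng: np.random.Generator):
        self.tx = tx
        self.seq = cds_seq
        self.rng = rng
        self.zone = nmd_escape_zone(tx)
        self.counter = 0
        # donor-exon last bases are essential splice positions, not nonsense
        self._donor_last = {
            (e if tx.strand == "+" else s) for s, e in tx.exons[:-1]
        }

    def _vid(self, kind: str) -> str:
        self.counter += 1
        return f"{self.tx.gene_symbol}:{kind}:{self.counter}"

    def _codon(self, aa: int) -> str:
        return self.seq[3 * aa - 3 : 3 * aa]

    def nonsense(self, aa_lo: int, aa_hi: int):
        """SNV creating a stop codon with anchor codon in [aa_lo, aa_hi]."""
        aa_hi = min(aa_hi, self.tx.protein_length)
        aa_lo = max(aa_lo, 2)
        candidates = [
            aa for aa in range(aa_lo, aa_hi + 1) if self._codon(aa) in _NONSENSE_ROUTES
        ]
        if not candidates:
            return None
        for _ in range(60):
            aa = int(self.rng.choice(candidates))
            routes = _NONSENSE_ROUTES[self._codon(aa)]
            off, alt_t = routes[int(self.rng.integers(len(routes)))]
            cds_pos = 3 * (aa - 1) + 1 + off
            gpos = cds_to_genomic(self.tx, cds_pos)
            if gpos in self._donor_last:
                continue
            ref = _tx_base_to_genomic(self.tx, self.seq[cds_pos - 1])
            alt = _tx_base_to_genomic(self.tx, alt_t)
            return dict(pos=gpos, ref=ref, alt=alt, vid=self._vid("non"))
        return None

    def missense(self, aa_lo: int = 5, aa_hi: int | None = None):
        aa_hi = aa_hi or self.tx.protein_length - 1
        from Bio.Seq import Seq

        for _ in range(80):
            aa = int(self.rng.integers(aa_lo, aa_hi + 1))
            codon = self._codon(aa)
            off = int(self.rng.integers(3))
            choices = [b for b in "ACGT" if b != codon[off]]
            alt_t = choices[int(self.rng.integers(3))]
            new = codon[:off] + alt_t + codon[off + 1 :]
            if new in _STOPS or str(Seq(new).translate()) == str(Seq(codon).translate()):
                continue
            cds_pos = 3 * (aa - 1) + 1 + off
            gpos = cds_to_genomic(self.tx, cds_pos)
            return dict(
                pos=gpos,
                ref=_tx_base_to_genomic(self.tx, codon[off]),
                alt=_tx_base_to_genomic(self.tx, alt_t),
                vid=self._vid("mis"),
            )
        return None

    def frameshift(self, cds_lo: int, cds_hi: int, vid: str | None = None):
        """Single-base deletion, VCF-anchored, away from splice boundaries."""
        for _ in range(60):
            p = int(self.rng.integers(max(cds_lo, 4), cds_hi + 1))
            gpos = cds_to_genomic(self.tx, p)
            anchor = gpos - 1
            if self._contiguous(gpos) and not _near_exon_boundary(self.tx, gpos) \
                    and not _near_exon_boundary(self.tx, anchor):
                anchor_locus = genomic_to_cds(self.tx, anchor)
                if anchor_locus.kind == "coding":
                    base = _tx_base_to_genomic(self.tx, self.seq[anchor_locus.cds_pos - 1])
                else:
                    base = "A"
                deleted = _tx_base_to_genomic(self.tx, self.seq[p - 1])
                return dict(
                    pos=anchor,
                    ref=base + deleted,
                    alt=base,
                    vid=vid or self._vid("fs"),
                )
        return None

    def _contiguous(self, gpos: int) -> bool:
        return any(s < gpos <= e for s, e in self.tx.exons)

    def splice(self):
        """Essential splice SNV at a junction upstream of the final coding
        junction (guaranteed class 5 under the escape-zone rule)."""
        coding = self.tx.coding_exon_spans()
        if len(coding) < 3:
            return None
        donor_choices = [idx for idx, _ in coding[:-2]]
        donor_idx = int(self.rng.choice(donor_choices))
        exon = self.tx.exons[donor_idx - 1]
        sign = 1 if self.tx.strand == "+" else -1
        donor_end = exon[1] if self.tx.strand == "+" else exon[0]
        detail = int(self.rng.integers(4))
        if detail < 2:
            gpos = donor_end + (detail + 1) * sign
        else:
            nxt = self.tx.exons[donor_idx]
            acceptor_start = nxt[0] if self.tx.strand == "+" else nxt[1]
            gpos = acceptor_start - (detail - 1) * sign
        return dict(pos=gpos, ref="G", alt="T", vid=self._vid("spl"))


# ---- cohort assembly -------------------------------------------------------


@dataclass
class _VcfRow:
    chrom: str
    pos: int
    ref: str
    alt: str
    info: dict


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    transcripts: dict[str, TranscriptModel]
    cds_sequences: dict[str, str]
    rows: list[_VcfRow]
    patients: list[PatientPhenotype]
    controls: list[ControlCohortCounts]
    dmis_controls: list[ControlCohortCounts]
    override_entries: list[tuple[str, str, int, str]]
    truth: "object"  # pandas.DataFrame
    manifest: dict

    def vcf_text(self) -> str:
        header = ["##fileformat=VCFv4.2"]
        for tx in sorted(self.transcripts.values(), key=lambda t: t.chrom):
            span = max(e for _, e in tx.exons) + 10_000
            header.append(f"##contig=<ID={tx.chrom},length={span}>")
        for key, typ, desc in [
            ("GENE", "String", "Gene symbol"),
            ("TX", "String", "Transcript id"),
            ("MAF_EXAC", "Float", "Reference-population MAF"),
            ("MAF_FLOSSIES", "Float", "Reference-population MAF"),
            ("MAF_GMC", "Float", "Reference-population MAF"),
            ("PRED1", "String", "In-silico predictor 1 verdict"),
            ("PRED2", "String", "In-silico predictor 2 verdict"),
            ("HGVSP", "String", "Protein-level annotation"),
            ("CARRIERS", "String", "Pipe-separated carrier patient ids"),
            ("VID", "String", "Variant label"),
        ]:
            header.append(
                f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">'
            )
        header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        body = []
        for row in sorted(self.rows, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            info = ";".join(f"{k}={v}" for k, v in row.info.items() if v not in (None, ""))
            body.append(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}"
            )
        return "\n".join(header + body) + "\n"

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .burden import write_control_counts_tsv, write_phenotypes_tsv

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {name: out / fname for name, fname in [
            ("vcf", "cases.vcf"), ("gff3", "transcripts.gff3"),
            ("domains", "domains.tsv"), ("cds_fasta", "cds.fasta"),
            ("phenotypes", "phenotypes.tsv"), ("controls", "controls.tsv"),
            ("dmis_controls", "controls_damaging_missense.tsv"),
            ("overrides", "overrides.tsv"), ("truth", "truth.tsv"),
            ("manifest", "manifest.json"),
        ]}
        paths["vcf"].write_text(self.vcf_text())
        write_gff3(sorted(self.transcripts.values(), key=lambda t: t.chrom), str(paths["gff3"]))
        with open(paths["domains"], "w") as fh:
            fh.write("transcript_id\tdomain_name\taa_start\taa_end\n")
            for tx in sorted(self.transcripts.values(), key=lambda t: t.transcript_id):
                for d in tx.domains:
                    fh.write(f"{tx.transcript_id}\t{d.name}\t{d.aa_start}\t{d.aa_end}\n")
        with open(paths["cds_fasta"], "w") as fh:
            for tid in sorted(self.cds_sequences):
                fh.write(f">{tid}\n")
                seq = self.cds_sequences[tid]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        write_phenotypes_tsv(self.patients, str(paths["phenotypes"]))
        write_control_counts_tsv(self.controls, str(paths["controls"]))
        write_control_counts_tsv(self.dmis_controls, str(paths["dmis_controls"]))
        with open(paths["overrides"], "w") as fh:
            fh.write("gene\tkey\tforced_class\treason\n")
            for gene, key, cls, reason in self.override_entries:
                fh.write(f"{gene}\t{key}\t{cls}\t{reason}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)
        return paths


def _pid(i: int) -> str:
    return f"S{i:05d}"


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a full case cohort plus control count tables under ``config``."""
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=8)
    rng_tx = np.random.default_rng(seeds[0])
    rng_phen = np.random.default_rng(seeds[1])
    rng_carrier = np.random.default_rng(seeds[2])
    rng_variant = np.random.default_rng(seeds[3])
    rng_control = np.random.default_rng(seeds[4])
    rng_aad = np.random.default_rng(seeds[5])
    rng_misc = np.random.default_rng(seeds[6])

    # transcripts + coding sequences
    transcripts: dict[str, TranscriptModel] = {}
    cds_sequences: dict[str, str] = {}
    factories: dict[str, _VariantFactory] = {}
    for gene_cfg in config.genes:
        tx = make_transcript(
            gene_cfg.gene_symbol,
            gene_cfg.n_exons,
            gene_cfg.cds_length,
            gene_cfg.domain_layout,
            seed=int(rng_tx.integers(2**31 - 1)),
        )
        seq = make_cds_sequence(tx.cds_length, rng_tx)
        transcripts[tx.transcript_id] = tx
        cds_sequences[tx.transcript_id] = seq
        factories[gene_cfg.gene_symbol] = _VariantFactory(tx, seq, rng_variant)

    # phenotypes and carrier structure
    phen = draw_phenotype_arrays(config, rng_phen)
    ptv_matrix = draw_case_carrier_matrix(config, rng_carrier, phen)
    if config.dual_carrier_count is not None:
        ptv_matrix = _adjust_dual_carriers(ptv_matrix, config.dual_carrier_count)
    extra_matrix = draw_case_carrier_matrix(
        config, rng_carrier, phen, prob_attr="class45_extra_prob"
    )

    # ages: truncated normal, gene-specific shift for deleterious carriers
    pm = config.phenotype_model
    lo, hi = pm.aad_range
    a = (lo - pm.aad_mean) / pm.aad_sd
    b = (hi - pm.aad_mean) / pm.aad_sd
    base_age = stats.truncnorm.rvs(
        a, b, loc=pm.aad_mean, scale=pm.aad_sd, size=config.n_cases, random_state=rng_aad
    )
    shift = np.zeros(config.n_cases)
    for j, gene_cfg in enumerate(config.genes):
        eff = config.effects.get(gene_cfg.gene_symbol, GeneEffects())
        carried = ptv_matrix[:, j] | extra_matrix[:, j]
        bigger = np.abs(eff.aad_shift) > np.abs(shift)
        shift = np.where(carried & bigger, eff.aad_shift, shift)
    age = np.clip(np.round(base_age + shift), lo, hi).astype(int)
    missing = rng_aad.random(config.n_cases) < pm.aad_missing_prob

    patients = [
        PatientPhenotype(
            patient_id=_pid(i),
            aad_years=None if missing[i] else int(age[i]),
            bilateral=bool(phen["bilateral"][i]),
            oc_family_history=bool(phen["oc_fh"][i]),
            er=("positive" if phen["er_pos"][i] else "negative") if phen["receptor_known"][i] else "unknown",
            pr=("positive" if phen["pr_pos"][i] else "negative") if phen["receptor_known"][i] else "unknown",
            her2=("positive" if phen["her2_pos"][i] else "negative") if phen["receptor_known"][i] else "unknown",
        )
        for i in range(config.n_cases)
    ]

    # case variants
    rows: list[_VcfRow] = []
    override_entries: list[tuple[str, str, int, str]] = []
    truth_rows = []

    def add_row(gene_cfg, allele, carriers, mafs=None, preds=None):
        info = {
            "GENE": gene_cfg.gene_symbol,
            "TX": f"TX_{gene_cfg.gene_symbol}",
            "VID": allele["vid"],
            "CARRIERS": "|".join(carriers),
        }
        for k, v in (mafs or {}).items():
            info[k] = f"{v:.6g}"
        for k, v in (preds or {}).items():
            info[k] = v
        rows.append(
            _VcfRow(
                chrom=transcripts[f"TX_{gene_cfg.gene_symbol}"].chrom,
                pos=allele["pos"],
                ref=allele["ref"],
                alt=allele["alt"],
                info=info,
            )
        )

    for j, gene_cfg in enumerate(config.genes):
        gene = gene_cfg.gene_symbol
        fac = factories[gene]
        tx = fac.tx
        zone_aa_start = (fac.zone[0] + 2) // 3
        tail_dom = next((d for d in tx.domains if d.aa_end >= zone_aa_start), None)
        carriers = [_pid(i) for i in np.flatnonzero(ptv_matrix[:, j])]
        # founder allele: one shared recurrent frameshift upstream of the zone
        founder_ids: list[str] = []
        if gene_cfg.founder_fraction > 0 and carriers:
            k = int(round(gene_cfg.founder_fraction * len(carriers)))
            founder_ids, carriers = carriers[:k], carriers[k:]
            founder_cds = min(1100, fac.zone[0] - 100)
            allele = fac.frameshift(founder_cds, founder_cds + 30, vid=FOUNDER_KEY)
            if allele is None:
                allele = fac.frameshift(10, fac.zone[0] - 10, vid=FOUNDER_KEY)
            add_row(gene_cfg, allele, founder_ids)
        for pid in carriers:
            u = rng_variant.random()
            allele = None
            if u < gene_cfg.fraction_ptv_in_escape_zone and tail_dom is not None:
                allele = fac.nonsense(zone_aa_start, tail_dom.aa_end)
            if allele is None:
                v = rng_variant.random()
                upstream_aa_hi = max(2, zone_aa_start - 2)
                if v < 0.15:
                    allele = fac.splice()
                if allele is None and v < 0.5:
                    allele = fac.frameshift(4, fac.zone[0] - 5)
                if allele is None:
                    allele = fac.nonsense(2, upstream_aa_hi)
                if allele is None:
                    allele = fac.frameshift(4, fac.zone[0] - 5)
            add_row(gene_cfg, allele, [pid])
        # established pathogenic missense (class 4/5 via override list)
        for i in np.flatnonzero(extra_matrix[:, j]):
            allele = fac.missense()
            if allele is None:
                continue
            # verdicts deliberately non-consensus: pathogenicity is asserted
            # by the override list, not by the in-silico predictors, and the
            # rare-damaging-missense layer should not absorb these carriers
            add_row(gene_cfg, allele, [_pid(i)],
                    preds={"PRED1": "damaging", "PRED2": "unknown"})
            override_entries.append(
                (gene, allele["vid"], 5, "established pathogenic missense")
            )
        # escape-zone PTVs without domain rescue -> VUS
        if tail_dom is not None and tail_dom.aa_end + 3 <= tx.protein_length:
            n_vus_ptv = rng_misc.binomial(config.n_cases, gene_cfg.vus_ptv_prob)
            for i in rng_misc.choice(config.n_cases, size=n_vus_ptv, replace=False):
                allele = fac.nonsense(tail_dom.aa_end + 1, tx.protein_length)
                if allele is not None:
                    add_row(gene_cfg, allele, [_pid(i)])
        # missense VUS and rare damaging-missense layer
        n_dmis = rng_misc.binomial(config.n_cases, gene_cfg.damaging_missense_prob)
        n_vus = rng_misc.binomial(config.n_cases, gene_cfg.missense_vus_prob)
        picks = rng_misc.choice(config.n_cases, size=min(n_dmis + n_vus, config.n_cases), replace=False)
        for rank, i in enumerate(picks):
            allele = fac.missense()
            if allele is None:
                continue
            if rank < n_dmis:
                add_row(
                    gene_cfg, allele, [_pid(i)],
                    mafs={"MAF_EXAC": float(rng_misc.uniform(0, 0.0008))},
                    preds={"PRED1": "damaging", "PRED2": "damaging"},
                )
            else:
                preds = ["damaging", "tolerated", "unknown"]
                add_row(
                    gene_cfg, allele, [_pid(i)],
                    preds={
                        "PRED1": preds[int(rng_misc.integers(3))],
                        "PRED2": "tolerated",
                    },
                )
        # one common (MAF >= 1%) variant per gene -> benign class 1
        if gene_cfg.common_benign_prob > 0:
            allele = fac.missense()
            if allele is not None:
                n_car = rng_misc.binomial(config.n_cases, gene_cfg.common_benign_prob)
                ids = [_pid(i) for i in rng_misc.choice(config.n_cases, size=n_car, replace=False)]
                add_row(
                    gene_cfg, allele, ids,
                    mafs={"MAF_EXAC": 0.02, "MAF_FLOSSIES": 0.018},
                    preds={"PRED1": "tolerated", "PRED2": "tolerated"},
                )
        for i in range(config.n_cases):
            if ptv_matrix[i, j] or extra_matrix[i, j]:
                truth_rows.append(
                    {
                        "patient_id": _pid(i),
                        "gene": gene,
                        "ptv_carrier": int(ptv_matrix[i, j]),
                        "class45_extra_carrier": int(extra_matrix[i, j]),
                    }
                )

    controls, dmis_controls = draw_control_counts(config, rng_control)

    import pandas as pd

    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "gene", "ptv_carrier", "class45_extra_carrier"]
    )
    manifest = {
        "seed": config.seed,
        "n_cases": config.n_cases,
        "control_cohort_sizes": dict(config.control_cohort_sizes),
        "genes": [asdict(g) for g in config.genes],
        "effects": {k: asdict(v) for k, v in config.effects.items()},
        "phenotype_model": asdict(config.phenotype_model),
        "dual_carrier_count": config.dual_carrier_count,
    }
    return SimulatedCohort(
        config=config,
        transcripts=transcripts,
        cds_sequences=cds_sequences,
        rows=rows,
        patients=patients,
        controls=controls,
        dmis_controls=dmis_controls,
        override_entries=override_entries,
        truth=truth,
        manifest=manifest,
    )
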