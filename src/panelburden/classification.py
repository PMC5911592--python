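"""Rule-based germline variant classification.

Implements the classification scheme used in diagnostic hereditary
breast/ovarian cancer panel testing (ENIGMA-style rules on the IARC
five-tier scale):

* protein-truncating variants (PTVs) — nonsense, frameshift, or essential
  splice-site variants hitting the invariant +/-1,2 intronic dinucleotides
  or the last nucleotide of a donor exon — are pathogenic (class 5),
* unless the truncation lands in the NMD-escape zone (last coding exon or
  final 55 coding bases of the penultimate coding exon), in which case the
  variant is a VUS (class 3) — except when the truncated region removes a
  known functional domain, which restores class 5,
* any variant with minor allele frequency >=1% in a control reference
  population is benign (class 1), taking precedence over everything but an
  explicit per-variant override,
* everything else is a VUS (class 3).

Rare missense variants (all MAFs < 0.1%) called damaging by both of two
configured in-silico predictors are additionally flagged
(``damaging_missense``) for the missense burden analysis; the flag does not
change the five-tier class.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .transcripts import TranscriptModel, genomic_to_cds, nmd_escape_zone

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "ConsequenceCall",
    "ClassifiedVariant",
    "OverrideList",
    "ClassifyConfig",
    "RefMismatchError",
    "call_consequence",
    "is_ptv",
    "assign_class",
    "flag_damaging_missense",
    "classify_vcf",
    "write_classified_tsv",
    "read_classified_tsv",
]

PTV_CATEGORIES = frozenset({"nonsense", "frameshift", "essential_splice"})
ANCHORED = frozenset({"nonsense", "frameshift", "missense", "synonymous", "inframe_indel"})
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class RefMismatchError(ValueError):
    """REF allele disagrees with the supplied coding sequence."""


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based, VCF convention (indels anchored on a shared base)
    ref: str
    alt: str
    gene_symbol: str
    transcript_id: str
    mafs: Mapping[str, float] = field(default_factory=dict)
    predictor_verdicts: Mapping[str, str] = field(default_factory=dict)
    variant_id: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt or not self.ref or not self.alt:
            raise ValueError(f"{self.variant_id or self.key}: ref/alt invalid")
        for allele in (self.ref, self.alt):
            if set(allele) - set("ACGT"):
                raise ValueError(f"{self.key}: allele {allele} not over ACGT")
        for name, maf in self.mafs.items():
            if not 0.0 <= maf <= 1.0:
                raise ValueError(f"{self.key}: MAF {name}={maf} outside [0,1]")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class ConsequenceCall:
    category: str  # nonsense|frameshift|essential_splice|missense|synonymous|inframe_indel|other
    cds_anchor: int | None = None
    splice_detail: str | None = None
    intron_index: int | None = None  # 1-based donor-exon index of the affected junction

    def __post_init__(self) -> None:
        if (self.category in ANCHORED) != (self.cds_anchor is not None):
            raise ValueError(
                f"cds_anchor presence inconsistent with category {self.category}"
            )


@dataclass(frozen=True)
class ClassifiedVariant:
    variant: VariantRecord
    consequence: ConsequenceCall
    is_ptv: bool
    iarc_class: int
    rationale: tuple[str, ...]
    damaging_missense: bool = False
    notes: tuple[str, ...] = ()  # audit flags, e.g. final-intron zone evaluation
    carriers: tuple[str, ...] = ()  # patient ids carrying this variant (cases)

    def __post_init__(self) -> None:
        if self.iarc_class not in (1, 2, 3, 4, 5):
            raise ValueError(f"iarc_class {self.iarc_class} outside 1..5")
        if self.iarc_class >= 4 and not (
            {"ptv_class5", "domain_rescue", "override"} & set(self.rationale)
        ):
            raise ValueError("class 4/5 requires ptv_class5, domain_rescue or override")
        if self.is_ptv and self.consequence.category not in PTV_CATEGORIES:
            raise ValueError("is_ptv set for a non-truncating consequence")


class OverrideList:
    """Per-variant forced classifications (e.g. the CHEK2 p.I157T demotion).

    Entries are keyed by gene plus either a c.-notation label (matched
    against ``variant_id``) or a ``chrom:pos:ref:alt`` key.
    """

    def __init__(self, entries: Mapping[tuple[str, str], tuple[int, str]] | None = None):
        self.entries: dict[tuple[str, str], tuple[int, str]] = {}
        for (gene, key), (cls, reason) in (entries or {}).items():
            self.add(gene, key, cls, reason)

    def add(self, gene: str, key: str, forced_class: int, reason: str) -> None:
        if forced_class not in (1, 2, 3, 4, 5):
            raise ValueError(f"override class {forced_class} outside 1..5")
        self.entries[(gene, key)] = (int(forced_class), reason)

    def lookup(self, variant: VariantRecord) -> tuple[int, str] | None:
        for key in (variant.variant_id, variant.key):
            if key and (variant.gene_symbol, key) in self.entries:
                return self.entries[(variant.gene_symbol, key)]
        return None

    @classmethod
    def from_tsv(cls, path: str) -> "OverrideList":
        import csv

        ov = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                ov.add(row["gene"], row["key"], int(row["forced_class"]), row["reason"])
        return ov


# ---- consequence calling --------------------------------------------------


def _essential_splice_sites(tx: TranscriptModel) -> list[tuple[int, str, int]]:
    """(genomic position, detail, junction index) of all essential splice bases.

    Junctions are considered when either flanking exon carries coding
    sequence; the donor-exon last base counts as an essential (exonic) site.
    """
    coding_exons = {idx for idx, _ in tx.coding_exon_spans()}
    sites: list[tuple[int, str, int]] = []
    sign = 1 if tx.strand == "+" else -1
    for i in range(tx.n_exons - 1):
        donor_idx, acceptor_idx = i + 1, i + 2
        if donor_idx not in coding_exons and acceptor_idx not in coding_exons:
            continue
        donor_exon = tx.exons[i]
        acceptor_exon = tx.exons[i + 1]
        donor_end = donor_exon[1] if tx.strand == "+" else donor_exon[0]
        acceptor_start = acceptor_exon[0] if tx.strand == "+" else acceptor_exon[1]
        sites.append((donor_end, "exon_last_base", donor_idx))
        sites.append((donor_end + sign, "donor_plus1", donor_idx))
        sites.append((donor_end + 2 * sign, "donor_plus2", donor_idx))
        sites.append((acceptor_start - sign, "acceptor_minus1", donor_idx))
        sites.append((acceptor_start - 2 * sign, "acceptor_minus2", donor_idx))
    return sites


_DETAIL_PRIORITY = {
    "donor_plus1": 0,
    "donor_plus2": 1,
    "acceptor_minus1": 2,
    "acceptor_minus2": 3,
    "exon_last_base": 4,
}

_HGVSP_RE = re.compile(
    r"p\.\(?([A-Za-z]{3}|[A-Z*])(\d+)((?:[A-Za-z]{3}|[A-Z*=])(?:fs.*)?|fs.*|\*|=)?\)?$"
)


def _consequence_from_hgvsp(hgvsp: str) -> ConsequenceCall | None:
    m = _HGVSP_RE.match(hgvsp.strip())
    if not m:
        return None
    aa_pos = int(m.group(2))
    anchor = 3 * aa_pos - 2
    tail = m.group(3) or ""
    if "fs" in tail:
        return ConsequenceCall("frameshift", cds_anchor=anchor)
    if tail in ("Ter", "*"):
        return ConsequenceCall("nonsense", cds_anchor=anchor)
    if tail in ("=", "") or tail == m.group(1):
        return ConsequenceCall("synonymous", cds_anchor=anchor)
    return ConsequenceCall("missense", cds_anchor=anchor)


def _transcript_base(tx: TranscriptModel, base: str) -> str:
    return base if tx.strand == "+" else base.translate(_COMPLEMENT)


def _check_ref(tx: TranscriptModel, cds_sequence: str, cds_pos: int, ref_base: str) -> None:
    expected = cds_sequence[cds_pos - 1]
    if _transcript_base(tx, ref_base) != expected:
        raise RefMismatchError(
            f"{tx.transcript_id}: REF base {ref_base} at cds position {cds_pos} "
            f"conflicts with coding sequence base {expected}"
        )


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def call_consequence(
    variant: VariantRecord,
    tx: TranscriptModel,
    cds_sequence: str | None = None,
    hgvsp: str | None = None,
) -> ConsequenceCall:
    """Assign a molecular consequence category to one variant allele.

    Essential splice sites take precedence (the invariant +/-1,2 intronic
    bases and the donor-exon last base, per the PTV definition used in
    diagnostic panels). Coding SNVs/MNVs are translated against
    ``cds_sequence`` when available, else interpreted from ``hgvsp``;
    indels are frameshift or in-frame by length.
    """
    ref, alt = variant.ref, variant.alt
    span = (variant.pos, variant.pos + len(ref) - 1)

    hits = [
        (g, detail, jidx)
        for g, detail, jidx in _essential_splice_sites(tx)
        if span[0] <= g <= span[1]
    ]
    # pure insertions between two bases do not change either flanking base
    is_insertion = len(ref) == 1 and len(alt) > 1
    if hits and not is_insertion:
        hits.sort(key=lambda h: _DETAIL_PRIORITY[h[1]])
        _, detail, jidx = hits[0]
        return ConsequenceCall("essential_splice", splice_detail=detail, intron_index=jidx)

    if len(ref) == len(alt):  # SNV or MNV
        loci = [genomic_to_cds(tx, variant.pos + i) for i in range(len(ref))]
        coding = [
            (lc.cds_pos, ref[i], alt[i])
            for i, lc in enumerate(loci)
            if lc.kind == "coding" and ref[i] != alt[i]
        ]
        if not coding:
            return ConsequenceCall("other")
        if cds_sequence is None:
            if hgvsp:
                call = _consequence_from_hgvsp(hgvsp)
                if call is not None:
                    return call
            return ConsequenceCall("other")
        seq = list(cds_sequence)
        for cds_pos, r, a in coding:
            _check_ref(tx, cds_sequence, cds_pos, r)
            seq[cds_pos - 1] = _transcript_base(tx, a)
        changed_codons = sorted({(p - 1) // 3 for p, _, _ in coding})
        for ci in changed_codons:
            old = cds_sequence[3 * ci : 3 * ci + 3]
            new = "".join(seq[3 * ci : 3 * ci + 3])
            old_aa, new_aa = _translate(old), _translate(new)
            if old_aa != new_aa:
                anchor = 3 * ci + 1
                cat = "nonsense" if new_aa == "*" else "missense"
                return ConsequenceCall(cat, cds_anchor=anchor)
        return ConsequenceCall("synonymous", cds_anchor=3 * changed_codons[0] + 1)

    # indel (VCF-anchored)
    net = len(alt) - len(ref)
    if net < 0:  # deletion: changed bases are pos+1 .. pos+len(ref)-1
        changed = [variant.pos + i for i in range(1, len(ref))]
    else:  # insertion after pos (possibly with substituted bases for complex alleles)
        changed = [variant.pos, variant.pos + len(ref) - 1] if len(ref) > 1 else [variant.pos]
    loci = [genomic_to_cds(tx, g) for g in changed]
    coding_loci = [lc for lc in loci if lc.kind == "coding"]
    if net > 0 and len(ref) == 1:
        # insertion point must fall strictly inside the CDS to disturb it
        here = genomic_to_cds(tx, variant.pos)
        neighbour = genomic_to_cds(tx, variant.pos + (1 if tx.strand == "+" else -1))
        if here.kind != "coding" or neighbour.kind != "coding":
            coding_loci = []
        else:
            coding_loci = [here if tx.strand == "+" else neighbour]
    if not coding_loci:
        return ConsequenceCall("other")
    if cds_sequence is not None and net < 0:
        for g in changed:
            lc = genomic_to_cds(tx, g)
            if lc.kind == "coding":
                _check_ref(
                    tx, cds_sequence, lc.cds_pos, ref[g - variant.pos]
                )
    if net < 0:
        anchor = min(lc.cds_pos for lc in coding_loci)
    else:
        anchor = min(lc.cds_pos for lc in coding_loci) + (1 if tx.strand == "+" else 0)
        anchor = min(anchor, tx.cds_length)
    category = "frameshift" if net % 3 != 0 else "inframe_indel"
    return ConsequenceCall(category, cds_anchor=anchor)


def is_ptv(consequence: ConsequenceCall, tx: TranscriptModel | None = None) -> bool:
    """Protein-truncating: nonsense, frameshift, or essential splice."""
    return consequence.category in PTV_CATEGORIES


# ---- five-tier class assignment -------------------------------------------


def flag_damaging_missense(
    variant: VariantRecord,
    consequence: ConsequenceCall,
    rare_threshold: float = 0.001,
) -> bool:
    """Rare missense with a unanimous 'damaging' verdict from both predictors.

    Absent MAFs count as rare (novel variants are frequency-unobserved);
    an 'unknown' verdict from either predictor fails the consensus.
    """
    if consequence.category != "missense":
        return False
    if any(maf >= rare_threshold for maf in variant.mafs.values()):
        return False
    verdicts = list(variant.predictor_verdicts.values())
    return len(verdicts) == 2 and all(v == "damaging" for v in verdicts)


def _zone_anchor(
    consequence: ConsequenceCall, tx: TranscriptModel
) -> tuple[int | None, tuple[str, ...]]:
    """CDS position against which the NMD-escape rule is evaluated.

    Essential-splice variants of non-final introns truncate upstream of the
    last junction and are never demoted; a final-intron splice variant is
    evaluated via the first coding base of the last coding exon (flagged in
    the output notes for audit).
    """
    notes: tuple[str, ...] = ()
    if consequence.category in ("nonsense", "frameshift"):
        return consequence.cds_anchor, notes
    # essential splice
    coding = tx.coding_exon_spans()
    if len(coding) == 1:
        return 1, ("single_coding_exon",)
    final_junction_donor = coding[-2][0]  # exon index of penultimate coding exon
    if consequence.intron_index is not None and consequence.intron_index >= final_junction_donor:
        return coding[-1][1][0], ("final_intron_zone_eval",)
    return None, notes  # upstream junction: truncation precedes the zone


def assign_class(
    variant: VariantRecord,
    consequence: ConsequenceCall,
    tx: TranscriptModel,
    maf_threshold: float = 0.01,
    overrides: OverrideList | None = None,
    rare_threshold: float = 0.001,
    domain_mode: str = "intersect",
    carriers: Sequence[str] = (),
) -> ClassifiedVariant:
    """Apply the five-tier rules in precedence order and record the rationale.

    Precedence: per-variant override > MAF>=threshold benign > PTV rules
    (class 5 outside the NMD-escape zone; inside the zone VUS unless the
    truncated tail intersects a functional domain) > default VUS.
    """
    ptv = is_ptv(consequence)
    dmis = flag_damaging_missense(variant, consequence, rare_threshold)
    rationale: list[str] = []
    notes: tuple[str, ...] = ()

    forced = overrides.lookup(variant) if overrides is not None else None
    if forced is not None:
        cls = forced[0]
        rationale.append("override")
    elif variant.mafs and max(variant.mafs.values()) >= maf_threshold:
        cls = 1
        rationale.append("maf_benign")
    elif ptv:
        anchor, notes = _zone_anchor(consequence, tx)
        zone = nmd_escape_zone(tx)
        if anchor is None or anchor < zone[0]:
            cls = 5
            rationale.append("ptv_class5")
        else:
            tail = (anchor, tx.cds_length)
            rescued = False
            for dom in tx.domains:
                lo, hi = dom.cds_span()
                if domain_mode == "intersect":
                    rescued = lo <= tail[1] and hi >= tail[0]
                else:  # full_loss: domain entirely within the truncated tail
                    rescued = lo >= tail[0] and hi <= tail[1]
                if rescued:
                    break
            if rescued:
                cls = 5
                rationale += ["ptv_class5", "domain_rescue"]
            else:
                cls = 3
                rationale.append("nmd_escape_vus")
    else:
        cls = 3
        rationale.append("default_vus")
        if consequence.category == "missense":
            rationale.append("missense_vus")
    if dmis:
        rationale.append("damaging_missense_flag")

    return ClassifiedVariant(
        variant=variant,
        consequence=consequence,
        is_ptv=ptv,
        iarc_class=cls,
        rationale=tuple(rationale),
        damaging_missense=dmis,
        notes=notes,
        carriers=tuple(carriers),
    )


# ---- VCF-level driver ------------------------------------------------------


@dataclass
class ClassifyConfig:
    gene_key: str = "GENE"
    tx_key: str = "TX"
    maf_keys: tuple[str, ...] = ("MAF_EXAC", "MAF_FLOSSIES", "MAF_GMC")
    predictor_keys: tuple[str, str] = ("PRED1", "PRED2")
    hgvsp_key: str = "HGVSP"
    carriers_key: str = "CARRIERS"
    variant_id_key: str = "VID"
    maf_threshold: float = 0.01
    rare_threshold: float = 0.001
    domain_mode: str = "intersect"
    cds_sequences: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.maf_threshold < 1 or not 0 < self.rare_threshold < 1:
            raise ValueError("thresholds must lie in (0,1)")


def _info_str(rec, key):
    val = rec.INFO.get(key)
    if val is None:
        return None
    return val.decode() if isinstance(val, bytes) else str(val)


def classify_vcf(
    vcf_path: str,
    transcripts: Mapping[str, TranscriptModel],
    overrides: OverrideList | None = None,
    config: ClassifyConfig | None = None,
) -> tuple[list[ClassifiedVariant], dict]:
    """Classify every record-alt of a VCF; returns (variants, summary).

    Multi-allelic records are decomposed per alt. Records whose transcript
    id is unknown are skipped with a logged warning and counted in the
    summary.
    """
    from cyvcf2 import VCF

    cfg = config or ClassifyConfig()
    out: list[ClassifiedVariant] = []
    n_records = n_skipped = 0
    for rec in VCF(vcf_path):
        n_records += 1
        tx_id = _info_str(rec, cfg.tx_key)
        gene = _info_str(rec, cfg.gene_key)
        if tx_id is None or tx_id not in transcripts:
            logger.warning("record %s:%s: unknown transcript %r, skipped", rec.CHROM, rec.POS, tx_id)
            n_skipped += 1
            continue
        tx = transcripts[tx_id]
        mafs = {}
        for key in cfg.maf_keys:
            val = rec.INFO.get(key)
            if val is not None:
                mafs[key] = float(val)
        verdicts = {}
        for key in cfg.predictor_keys:
            verdicts[key] = _info_str(rec, key) or "unknown"
        carriers_raw = _info_str(rec, cfg.carriers_key)
        carriers = tuple(carriers_raw.split("|")) if carriers_raw else ()
        hgvsp = _info_str(rec, cfg.hgvsp_key)
        vid = _info_str(rec, cfg.variant_id_key) or ""
        for alt in rec.ALT:
            variant = VariantRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                gene_symbol=gene or tx.gene_symbol,
                transcript_id=tx_id,
                mafs=mafs,
                predictor_verdicts=verdicts,
                variant_id=vid,
            )
            consequence = call_consequence(
                variant, tx, cds_sequence=cfg.cds_sequences.get(tx_id), hgvsp=hgvsp
            )
            out.append(
                assign_class(
                    variant,
                    consequence,
                    tx,
                    maf_threshold=cfg.maf_threshold,
                    overrides=overrides,
                    rare_threshold=cfg.rare_threshold,
                    domain_mode=cfg.domain_mode,
                    carriers=carriers,
                )
            )
    summary = summarize_classification(out)
    summary["n_records"] = n_records
    summary["n_skipped_unknown_transcript"] = n_skipped
    return out, summary


def summarize_classification(classified: Iterable[ClassifiedVariant]) -> dict:
    class_counts = {c: 0 for c in (1, 2, 3, 4, 5)}
    per_gene: dict[str, dict[int, int]] = {}
    n_ptv = n_dmis = n_total = 0
    for cv in classified:
        n_total += 1
        class_counts[cv.iarc_class] += 1
        per_gene.setdefault(cv.variant.gene_symbol, {c: 0 for c in (1, 2, 3, 4, 5)})[
            cv.iarc_class
        ] += 1
        n_ptv += cv.is_ptv
        n_dmis += cv.damaging_missense
    return {
        "n_classified": n_total,
        "class_counts": class_counts,
        "per_gene": per_gene,
        "n_ptv": n_ptv,
        "n_damaging_missense": n_dmis,
    }


_TSV_COLUMNS = [
    "variant_id",
    "gene",
    "transcript",
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
    "splice_detail",
    "cds_anchor",
    "is_ptv",
    "iarc_class",
    "rationale",
    "damaging_missense",
    "notes",
    "carriers",
]


def write_classified_tsv(classified: Sequence[ClassifiedVariant], path: str) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLUMNS)
        for cv in classified:
            v, c = cv.variant, cv.consequence
            w.writerow(
                [
                    v.variant_id,
                    v.gene_symbol,
                    v.transcript_id,
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    c.category,
                    c.splice_detail or "",
                    c.cds_anchor if c.cds_anchor is not None else "",
                    int(cv.is_ptv),
                    cv.iarc_class,
                    ";".join(cv.rationale),
                    int(cv.damaging_missense),
                    ";".join(cv.notes),
                    "|".join(cv.carriers),
                ]
            )


def read_classified_tsv(path: str) -> list[ClassifiedVariant]:
    import csv

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            variant = VariantRecord(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                gene_symbol=row["gene"],
                transcript_id=row["transcript"],
                variant_id=row["variant_id"],
            )
            consequence = ConsequenceCall(
                category=row["consequence"],
                cds_anchor=int(row["cds_anchor"]) if row["cds_anchor"] else None,
                splice_detail=row["splice_detail"] or None,
            )
            out.append(
                ClassifiedVariant(
                    variant=variant,
                    consequence=consequence,
                    is_ptv=bool(int(row["is_ptv"])),
                    iarc_class=int(row["iarc_class"]),
                    rationale=tuple(row["rationale"].split(";")) if row["rationale"] else (),
                    damaging_missense=bool(int(row["damaging_missense"])),
                    notes=tuple(row["notes"].split(";")) if row["notes"] else (),
                    carriers=tuple(row["carriers"].split("|")) if row["carriers"] else (),
                )
            )
    return out
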