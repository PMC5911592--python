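"""Transcript models and coordinate arithmetic.

A :class:`TranscriptModel` holds the exon/CDS geometry of one canonical
transcript (e.g. CHEK2 NM_007194) plus optional protein-domain intervals.
The classification rules need two pieces of coordinate arithmetic on top of
it: mapping a genomic position into CDS coordinates (1-based from the A of
the ATG, HGVS c.-style intron offsets) and locating the NMD-escape zone —
the last coding exon plus the final 55 coding nucleotides of the penultimate
coding exon, where a premature stop codon is expected to evade
nonsense-mediated decay.

Conventions: all genomic and CDS coordinates are 1-based closed intervals,
matching VCF and GFF3. Exons are stored 5'->3' in transcript orientation,
so on the minus strand exon genomic coordinates decrease along the list.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import gffutils
import yaml

__all__ = [
    "TranscriptError",
    "Domain",
    "CdsLocus",
    "TranscriptModel",
    "genomic_to_cds",
    "cds_to_genomic",
    "nmd_escape_zone",
    "load_transcripts",
    "load_domain_table",
    "write_gff3",
]


class TranscriptError(ValueError):
    """Raised for malformed transcript geometry; message names the transcript."""


@dataclass(frozen=True)
class Domain:
    """Protein domain in 1-based amino-acid coordinates (closed interval)."""

    name: str
    aa_start: int
    aa_end: int

    def cds_span(self) -> tuple[int, int]:
        """Coding-nucleotide interval covered by the domain (aa i <-> [3i-2, 3i])."""
        return 3 * self.aa_start - 2, 3 * self.aa_end


@dataclass(frozen=True)
class CdsLocus:
    """Position of one genomic base relative to a transcript's CDS.

    ``kind`` is one of ``coding``, ``intronic``, ``utr``, ``outside``.
    ``intron_offset`` follows HGVS: +1 is the first intronic base after a
    donor exon, -1 the last intronic base before an acceptor exon.
    ``exon_index`` is 1-based in transcript orientation (for intronic
    positions, the exon whose boundary the offset is counted from).
    """

    kind: str
    cds_pos: int | None = None
    exon_index: int | None = None
    intron_offset: int | None = None

    def __post_init__(self) -> None:
        if (self.kind == "coding") != (self.cds_pos is not None):
            raise ValueError("cds_pos must be present iff kind is coding")
        if (self.kind == "intronic") != (
            self.intron_offset is not None and self.intron_offset != 0
        ):
            raise ValueError("non-zero intron_offset must be present iff kind is intronic")


@dataclass(frozen=True)
class TranscriptModel:
    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]  # genomic, 1-based closed, 5'->3' transcript order
    cds_start_genomic: int  # genomic coordinate of the first coding base (A of ATG)
    cds_end_genomic: int  # genomic coordinate of the last coding base (end of stop codon)
    domains: tuple[Domain, ...] = ()

    # ---- derived geometry -------------------------------------------------

    def __post_init__(self) -> None:
        self._validate()

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def _exon_tspans(self) -> list[tuple[int, int]]:
        """Transcript-coordinate span (1-based closed) of each exon, 5'->3'."""
        spans = []
        t = 0
        for s, e in self.exons:
            length = e - s + 1
            spans.append((t + 1, t + length))
            t += length
        return spans

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def _tpos(self, gpos: int) -> int | None:
        """Transcript coordinate of a genomic position, or None if not exonic."""
        t = 0
        for s, e in self.exons:
            if s <= gpos <= e:
                return t + (gpos - s + 1) if self.strand == "+" else t + (e - gpos + 1)
            t += e - s + 1
        return None

    @property
    def t_cds_start(self) -> int:
        tp = self._tpos(self.cds_start_genomic)
        assert tp is not None
        return tp

    @property
    def t_cds_end(self) -> int:
        tp = self._tpos(self.cds_end_genomic)
        assert tp is not None
        return tp

    @property
    def cds_length(self) -> int:
        return self.t_cds_end - self.t_cds_start + 1

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3 - 1

    def coding_exon_spans(self) -> list[tuple[int, tuple[int, int]]]:
        """(1-based exon index, (cds_start, cds_end)) for exons with coding bases."""
        out = []
        for idx, (ts, te) in enumerate(self._exon_tspans(), start=1):
            lo = max(ts, self.t_cds_start)
            hi = min(te, self.t_cds_end)
            if lo <= hi:
                out.append((idx, (lo - self.t_cds_start + 1, hi - self.t_cds_start + 1)))
        return out

    def _validate(self) -> None:
        tid = self.transcript_id
        if self.strand not in ("+", "-"):
            raise TranscriptError(f"{tid}: strand must be '+' or '-'")
        if not self.exons:
            raise TranscriptError(f"{tid}: transcript has no exons")
        for s, e in self.exons:
            if s > e:
                raise TranscriptError(f"{tid}: invalid exon interval {s}-{e}")
        # pairwise non-overlap + consistent transcript-orientation ordering
        ordered = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise TranscriptError(f"{tid}: overlapping exons {s1}-{e1} and {s2}-{e2}")
        expect = ordered if self.strand == "+" else ordered[::-1]
        if tuple(expect) != self.exons:
            raise TranscriptError(f"{tid}: exons not ordered 5'->3' for strand {self.strand}")
        if self._tpos(self.cds_start_genomic) is None:
            raise TranscriptError(f"{tid}: CDS start {self.cds_start_genomic} not inside an exon")
        if self._tpos(self.cds_end_genomic) is None:
            raise TranscriptError(f"{tid}: CDS end {self.cds_end_genomic} not inside an exon")
        if self.t_cds_start > self.t_cds_end:
            raise TranscriptError(f"{tid}: CDS start downstream of CDS end")
        if self.cds_length % 3 != 0:
            raise TranscriptError(
                f"{tid}: CDS length {self.cds_length} is not a multiple of 3"
            )
        if self.cds_length < 6:
            raise TranscriptError(f"{tid}: CDS too short ({self.cds_length} nt)")
        plen = self.protein_length
        for d in self.domains:
            if not (1 <= d.aa_start <= d.aa_end <= plen):
                raise TranscriptError(
                    f"{tid}: domain {d.name} [{d.aa_start},{d.aa_end}] outside protein 1..{plen}"
                )

    def with_domains(self, domains: Iterable[Domain]) -> "TranscriptModel":
        return replace(self, domains=tuple(domains))


# ---- coordinate mapping ---------------------------------------------------


def genomic_to_cds(tx: TranscriptModel, gpos: int) -> CdsLocus:
    """Map a genomic position to a :class:`CdsLocus`, honoring strand.

    Exonic positions are classified as coding or UTR; intronic positions get
    the HGVS-style signed offset from the nearest exon boundary (ties go to
    the donor side). Positions outside the transcript span are ``outside``.
    """
    t = 0
    tspans = tx._exon_tspans()
    for idx, (s, e) in enumerate(tx.exons, start=1):
        if s <= gpos <= e:
            tpos = (
                tspans[idx - 1][0] + (gpos - s)
                if tx.strand == "+"
                else tspans[idx - 1][0] + (e - gpos)
            )
            if tx.t_cds_start <= tpos <= tx.t_cds_end:
                return CdsLocus(
                    kind="coding", cds_pos=tpos - tx.t_cds_start + 1, exon_index=idx
                )
            return CdsLocus(kind="utr", exon_index=idx)
        t += e - s + 1
    # intron search: between consecutive exons in transcript order
    for i in range(len(tx.exons) - 1):
        up = tx.exons[i]
        down = tx.exons[i + 1]
        if tx.strand == "+":
            lo, hi = up[1] + 1, down[0] - 1
            if lo <= gpos <= hi:
                d_donor = gpos - up[1]
                d_accept = down[0] - gpos
        else:
            lo, hi = down[1] + 1, up[0] - 1
            if lo <= gpos <= hi:
                d_donor = up[0] - gpos
                d_accept = gpos - down[1]
        if lo <= gpos <= hi:
            if d_donor <= d_accept:
                return CdsLocus(kind="intronic", intron_offset=d_donor, exon_index=i + 1)
            return CdsLocus(kind="intronic", intron_offset=-d_accept, exon_index=i + 2)
    return CdsLocus(kind="outside")


def cds_to_genomic(tx: TranscriptModel, cds_pos: int) -> int:
    """Genomic coordinate of a 1-based coding position (inverse of the mapping)."""
    if not 1 <= cds_pos <= tx.cds_length:
        raise ValueError(f"cds_pos {cds_pos} outside CDS 1..{tx.cds_length}")
    tpos = tx.t_cds_start + cds_pos - 1
    for (s, e), (ts, te) in zip(tx.exons, tx._exon_tspans()):
        if ts <= tpos <= te:
            return s + (tpos - ts) if tx.strand == "+" else e - (tpos - ts)
    raise AssertionError("unreachable: tpos within transcript must fall in an exon")


def nmd_escape_zone(tx: TranscriptModel, window: int = 55) -> tuple[int, int]:
    """CDS interval whose premature stops are expected to escape NMD.

    Union of the last coding exon and the final ``window`` coding
    nucleotides of the penultimate coding exon (capped at that exon's coding
    start). Single-coding-exon transcripts have no downstream exon-exon
    junction, so the whole CDS escapes.
    """
    coding = tx.coding_exon_spans()
    if len(coding) == 1:
        return (1, tx.cds_length)
    pen_span = coding[-2][1]
    start = max(pen_span[0], pen_span[1] - window + 1)
    return (start, tx.cds_length)


# ---- loading --------------------------------------------------------------


def load_domain_table(path: str) -> dict[str, list[Domain]]:
    """Read the domain sidecar TSV (transcript_id, domain_name, aa_start, aa_end)."""
    out: dict[str, list[Domain]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(row["transcript_id"], []).append(
                Domain(row["domain_name"], int(row["aa_start"]), int(row["aa_end"]))
            )
    return out


def _from_gff3(path: str) -> list[TranscriptModel]:
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        force=True,
    )
    models = []
    for mrna in db.features_of_type(("mRNA", "transcript"), order_by="start"):
        tid = mrna.attributes.get("transcript_id", [mrna.id])[0]
        gene = mrna.attributes.get("gene", mrna.attributes.get("gene_name", [None]))[0]
        if gene is None:
            for parent in db.parents(mrna, featuretype="gene"):
                gene = parent.attributes.get("Name", [parent.id])[0]
                break
        if gene is None:
            gene = mrna.id
        exons = sorted(
            ((f.start, f.end) for f in db.children(mrna, featuretype="exon")),
        )
        cds = sorted(
            ((f.start, f.end) for f in db.children(mrna, featuretype="CDS")),
        )
        if not exons or not cds:
            raise TranscriptError(f"{tid}: mRNA lacks exon or CDS features")
        strand = mrna.strand
        if strand not in ("+", "-"):
            raise TranscriptError(f"{tid}: missing strand")
        if strand == "-":
            exons = exons[::-1]
        cds_start = cds[0][0] if strand == "+" else cds[-1][1]
        cds_end = cds[-1][1] if strand == "+" else cds[0][0]
        model = TranscriptModel(
            gene_symbol=gene,
            transcript_id=tid,
            chrom=mrna.seqid,
            strand=strand,
            exons=tuple(exons),
            cds_start_genomic=cds_start,
            cds_end_genomic=cds_end,
        )
        declared = sum(e - s + 1 for s, e in cds)
        if declared != model.cds_length:
            raise TranscriptError(
                f"{tid}: CDS features sum to {declared} nt but exon geometry implies "
                f"{model.cds_length} nt"
            )
        models.append(model)
    return models


def _from_yaml(path: str) -> list[TranscriptModel]:
    """Structured-text alternative to GFF3; schema documented in docs/methods.md."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    models = []
    for entry in doc["transcripts"]:
        domains = tuple(
            Domain(d["name"], int(d["aa_start"]), int(d["aa_end"]))
            for d in entry.get("domains", [])
        )
        models.append(
            TranscriptModel(
                gene_symbol=entry["gene"],
                transcript_id=entry["transcript_id"],
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=tuple((int(s), int(e)) for s, e in entry["exons"]),
                cds_start_genomic=int(entry["cds"][0]),
                cds_end_genomic=int(entry["cds"][1]),
                domains=domains,
            )
        )
    return models


def load_transcripts(
    path: str,
    format: str = "gff3",
    domains: str | Mapping[str, Sequence[Domain]] | None = None,
) -> list[TranscriptModel]:
    """Load validated transcript models from GFF3 or the YAML schema.

    ``domains`` may be a sidecar TSV path or a pre-parsed mapping
    transcript_id -> domains. All :class:`TranscriptModel` invariants are
    enforced; violations raise :class:`TranscriptError` naming the
    offending transcript.
    """
    if format == "gff3":
        models = _from_gff3(path)
    elif format in ("yaml", "structured-text"):
        models = _from_yaml(path)
    else:
        raise ValueError(f"unknown transcript format: {format}")
    if domains is not None:
        table = load_domain_table(domains) if isinstance(domains, str) else domains
        models = [
            m.with_domains(tuple(table.get(m.transcript_id, ()))) for m in models
        ]
    return models


def write_gff3(transcripts: Sequence[TranscriptModel], path: str) -> None:
    """Write transcripts as a minimal gene->mRNA->exon/CDS GFF3 document."""
    lines = ["##gff-version 3"]
    for tx in transcripts:
        g_lo = min(s for s, _ in tx.exons)
        g_hi = max(e for _, e in tx.exons)
        gid = f"gene:{tx.gene_symbol}"
        mid = tx.transcript_id
        lines.append(
            f"{tx.chrom}\tpanelburden\tgene\t{g_lo}\t{g_hi}\t.\t{tx.strand}\t.\t"
            f"ID={gid};Name={tx.gene_symbol}"
        )
        lines.append(
            f"{tx.chrom}\tpanelburden\tmRNA\t{g_lo}\t{g_hi}\t.\t{tx.strand}\t.\t"
            f"ID={mid};Parent={gid};gene={tx.gene_symbol};transcript_id={mid}"
        )
        for i, (s, e) in enumerate(sorted(tx.exons), start=1):
            lines.append(
                f"{tx.chrom}\tpanelburden\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t"
                f"ID={mid}.exon{i};Parent={mid}"
            )
        c_lo = min(tx.cds_start_genomic, tx.cds_end_genomic)
        c_hi = max(tx.cds_start_genomic, tx.cds_end_genomic)
        for i, (s, e) in enumerate(sorted(tx.exons), start=1):
            lo, hi = max(s, c_lo), min(e, c_hi)
            if lo <= hi:
                lines.append(
                    f"{tx.chrom}\tpanelburden\tCDS\t{lo}\t{hi}\t.\t{tx.strand}\t0\t"
                    f"ID={mid}.cds{i};Parent={mid}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
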