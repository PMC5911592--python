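"""Transcript geometry, coordinate mapping and the NMD-escape zone."""

import pytest

from panelburden.simulate import make_transcript
from panelburden.transcripts import (
    Domain,
    TranscriptError,
    TranscriptModel,
    cds_to_genomic,
    genomic_to_cds,
    load_transcripts,
    nmd_escape_zone,
    write_gff3,
)


def brute_force_cds_map(tx: TranscriptModel) -> dict[int, int]:
    """Independent oracle: walk the spliced transcript base by base and
    number the coding stretch 1..cds_length."""
    spliced = []
    for s, e in tx.exons:
        gs = range(s, e + 1) if tx.strand == "+" else range(e, s - 1, -1)
        spliced.extend(gs)
    out = {}
    cds_pos = 0
    started = False
    for g in spliced:
        if g == tx.cds_start_genomic:
            started = True
        if started:
            cds_pos += 1
            out[g] = cds_pos
        if g == tx.cds_end_genomic:
            break
    return out


# ---- construction and loading ---------------------------------------------


def test_gff3_roundtrip_preserves_geometry(toy_tx, tmp_path):
    path = tmp_path / "toy.gff3"
    write_gff3([toy_tx], str(path))
    (loaded,) = load_transcripts(str(path))
    assert loaded.cds_length == 300
    assert loaded.protein_length == 99
    assert loaded.exons == toy_tx.exons
    assert loaded.gene_symbol == "GENE1"


def test_gff3_minus_strand_orders_exons_five_prime_first(tmp_path):
    tx = make_transcript("G", 4, 600, seed=5, strand="-")
    path = tmp_path / "minus.gff3"
    write_gff3([tx], str(path))
    (loaded,) = load_transcripts(str(path))
    assert loaded.strand == "-"
    assert loaded.exons == tx.exons  # 5'->3', genomically decreasing
    assert loaded.cds_length == 600


def test_gff3_cds_not_multiple_of_three_rejected(toy_tx, tmp_path):
    path = tmp_path / "bad.gff3"
    write_gff3([toy_tx], str(path))
    text = path.read_text()
    # extend the last CDS feature by one base: 301 nt total
    path.write_text(text.replace("CDS\t521\t630", "CDS\t521\t631"))
    with pytest.raises(TranscriptError, match="TX1"):
        load_transcripts(str(path))


def test_overlapping_exons_rejected():
    with pytest.raises(TranscriptError, match="overlap"):
        TranscriptModel(
            "G", "TBAD", "chr1", "+", ((100, 200), (150, 300)), 100, 291
        )


def test_domain_outside_protein_rejected(toy_tx):
    with pytest.raises(TranscriptError, match="DOMX"):
        toy_tx.with_domains([Domain("DOMX", 90, 120)])


def test_domain_sidecar_table(toy_tx, tmp_path):
    gff = tmp_path / "toy.gff3"
    write_gff3([toy_tx], str(gff))
    sidecar = tmp_path / "domains.tsv"
    sidecar.write_text(
        "transcript_id\tdomain_name\taa_start\taa_end\nTX1\tKINASE\t10\t40\n"
    )
    (loaded,) = load_transcripts(str(gff), domains=str(sidecar))
    assert loaded.domains == (Domain("KINASE", 10, 40),)


def test_yaml_format_loads(tmp_path):
    doc = """
transcripts:
  - gene: GENE1
    transcript_id: TY1
    chrom: chr2
    strand: "+"
    exons: [[101, 200], [301, 420], [521, 640]]
    cds: [131, 630]
    domains: [{name: D1, aa_start: 5, aa_end: 20}]
"""
    path = tmp_path / "tx.yaml"
    path.write_text(doc)
    (loaded,) = load_transcripts(str(path), format="yaml")
    assert loaded.cds_length == 300
    assert loaded.domains[0].name == "D1"


# ---- genomic <-> CDS mapping -----------------------------------------------


def test_first_coding_base_and_intron_offsets(toy_tx):
    first = genomic_to_cds(toy_tx, 131)
    assert (first.kind, first.cds_pos, first.exon_index) == ("coding", 1, 1)
    donor1 = genomic_to_cds(toy_tx, 201)
    assert (donor1.kind, donor1.intron_offset, donor1.exon_index) == ("intronic", 1, 1)
    acceptor = genomic_to_cds(toy_tx, 300)
    assert (acceptor.kind, acceptor.intron_offset, acceptor.exon_index) == ("intronic", -1, 2)
    assert genomic_to_cds(toy_tx, 105).kind == "utr"
    assert genomic_to_cds(toy_tx, 50).kind == "outside"


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("strand", ["+", "-"])
def test_mapping_matches_spliced_walk_everywhere(seed, strand):
    """Exhaustive agreement with the brute-force spliced-sequence oracle."""
    tx = make_transcript("G", n_exons=3 + seed % 4, cds_length=300 + 3 * seed, seed=seed, strand=strand)
    oracle = brute_force_cds_map(tx)
    for g, expected in oracle.items():
        locus = genomic_to_cds(tx, g)
        assert locus.kind == "coding" and locus.cds_pos == expected, g
    for p in range(1, tx.cds_length + 1):
        assert oracle[cds_to_genomic(tx, p)] == p


def test_mapping_is_strand_mirror_consistent():
    """Reflecting the genomic layout onto the opposite strand leaves every
    CdsLocus unchanged (positions mapped through the reflection)."""
    tx = make_transcript("G", 4, 450, seed=3, strand="+")
    c = max(e for _, e in tx.exons) + min(s for s, _ in tx.exons)  # reflection constant
    mirror = TranscriptModel(
        gene_symbol=tx.gene_symbol,
        transcript_id=tx.transcript_id + "_m",
        chrom=tx.chrom,
        strand="-",
        exons=tuple((c - e, c - s) for s, e in tx.exons),
        cds_start_genomic=c - tx.cds_start_genomic,
        cds_end_genomic=c - tx.cds_end_genomic,
        domains=tx.domains,
    )
    span = range(min(s for s, _ in tx.exons) - 5, max(e for _, e in tx.exons) + 6)
    for g in span:
        a = genomic_to_cds(tx, g)
        b = genomic_to_cds(mirror, c - g)
        assert (a.kind, a.cds_pos, a.exon_index, a.intron_offset) == (
            b.kind, b.cds_pos, b.exon_index, b.intron_offset,
        )
    assert nmd_escape_zone(tx) == nmd_escape_zone(mirror)


# ---- NMD-escape zone -------------------------------------------------------


def _tx_with_coding_spans(sizes: list[int]) -> TranscriptModel:
    """UTR-less transcript whose exon coding lengths equal ``sizes``."""
    exons = []
    pos = 1000
    for size in sizes:
        exons.append((pos, pos + size - 1))
        pos += size + 500
    return TranscriptModel(
        "G", "TZ", "chr1", "+", tuple(exons), exons[0][0], exons[-1][1]
    )


def test_zone_penultimate_window():
    tx = _tx_with_coding_spans([100, 150, 50])  # penultimate cds 101-250, last 251-300
    assert nmd_escape_zone(tx) == (196, 300)  # 250 - 55 + 1


def test_zone_capped_at_short_penultimate_exon():
    tx = _tx_with_coding_spans([210, 40, 50])  # penultimate cds 211-250 (40 nt)
    assert nmd_escape_zone(tx) == (211, 300)


def test_zone_single_coding_exon_is_whole_cds():
    tx = _tx_with_coding_spans([300])
    assert nmd_escape_zone(tx) == (1, 300)


@pytest.mark.parametrize("seed", range(10))
def test_zone_length_formula(seed):
    """zone length == len(last coding exon) + min(55, len(penultimate))."""
    tx = make_transcript("G", 2 + seed % 6, 300 + 30 * seed, seed=seed)
    coding = tx.coding_exon_spans()
    zone = nmd_escape_zone(tx)
    if len(coding) == 1:
        assert zone == (1, tx.cds_length)
        return
    last_len = coding[-1][1][1] - coding[-1][1][0] + 1
    pen_len = coding[-2][1][1] - coding[-2][1][0] + 1
    assert zone[1] == tx.cds_length
    assert zone[1] - zone[0] + 1 == last_len + min(55, pen_len)
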