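"""Consequence calling and five-tier class assignment rules."""

import pytest

from panelburden.classification import (
    ClassifyConfig,
    OverrideList,
    RefMismatchError,
    VariantRecord,
    assign_class,
    call_consequence,
    classify_vcf,
    flag_damaging_missense,
    is_ptv,
    write_classified_tsv,
)
from panelburden.transcripts import Domain, nmd_escape_zone


def _var(toy_tx, pos, ref, alt, mafs=None, verdicts=None, vid=""):
    return VariantRecord(
        chrom=toy_tx.chrom, pos=pos, ref=ref, alt=alt,
        gene_symbol=toy_tx.gene_symbol, transcript_id=toy_tx.transcript_id,
        mafs=mafs or {}, predictor_verdicts=verdicts or {}, variant_id=vid,
    )


# ---- consequence calling ---------------------------------------------------
# toy geometry: CDS starts at genomic 131; exon1 covers cds 1-70.


def test_nonsense_by_codon_translation(toy_tx, toy_cds):
    # codon 17 = TGG at cds 49-51 (genomic 179-181); G>A at cds 51 makes TGA
    call = call_consequence(_var(toy_tx, 181, "G", "A"), toy_tx, toy_cds)
    assert (call.category, call.cds_anchor) == ("nonsense", 49)
    assert is_ptv(call, toy_tx)


def test_missense_and_synonymous_by_translation(toy_tx, toy_cds):
    # codon 2 = GAA (Glu) at cds 4-6; G>A at cds 4 -> AAA (Lys) missense
    mis = call_consequence(_var(toy_tx, 134, "G", "A"), toy_tx, toy_cds)
    assert (mis.category, mis.cds_anchor) == ("missense", 4)
    assert not is_ptv(mis, toy_tx)
    # GAA -> GAG is still Glu
    syn = call_consequence(_var(toy_tx, 136, "A", "G"), toy_tx, toy_cds)
    assert (syn.category, syn.cds_anchor) == ("synonymous", 4)


def test_single_base_deletion_is_frameshift_at_cds120(toy_tx, toy_cds):
    # cds 120 lies in exon 2: genomic = 301 + (120 - 71) = 350
    ref_base = toy_cds[118]  # cds 119, the VCF anchor
    del_base = toy_cds[119]
    call = call_consequence(_var(toy_tx, 349, ref_base + del_base, ref_base), toy_tx, toy_cds)
    assert (call.category, call.cds_anchor) == ("frameshift", 120)
    assert is_ptv(call, toy_tx)


def test_inframe_deletion_by_length_rule(toy_tx, toy_cds):
    ref = toy_cds[118:122]  # anchor cds 119 + three deleted bases
    call = call_consequence(_var(toy_tx, 349, ref, ref[0]), toy_tx, toy_cds)
    assert (call.category, call.cds_anchor) == ("inframe_indel", 120)


@pytest.mark.parametrize(
    "pos,detail",
    [
        (201, "donor_plus1"),
        (202, "donor_plus2"),
        (299, "acceptor_minus2"),
        (300, "acceptor_minus1"),
        (200, "exon_last_base"),
    ],
)
def test_essential_splice_sites(toy_tx, toy_cds, pos, detail):
    call = call_consequence(_var(toy_tx, pos, "G", "T"), toy_tx, toy_cds)
    assert call.category == "essential_splice"
    assert call.splice_detail == detail
    assert call.intron_index == 1
    assert is_ptv(call, toy_tx)


def test_deep_intronic_and_utr_are_other(toy_tx, toy_cds):
    assert call_consequence(_var(toy_tx, 250, "G", "T"), toy_tx, toy_cds).category == "other"
    assert call_consequence(_var(toy_tx, 110, "G", "T"), toy_tx, toy_cds).category == "other"


def test_ref_mismatch_names_position(toy_tx, toy_cds):
    # cds 10 is within codon 4 (GAA); claiming REF=T there is inconsistent
    with pytest.raises(RefMismatchError, match="cds position 10"):
        call_consequence(_var(toy_tx, 140, "T", "C"), toy_tx, toy_cds)


def test_hgvsp_fallback_without_sequence(toy_tx):
    call = call_consequence(_var(toy_tx, 181, "G", "A"), toy_tx, None, hgvsp="p.Trp17Ter")
    assert (call.category, call.cds_anchor) == ("nonsense", 49)
    fs = call_consequence(_var(toy_tx, 181, "G", "A"), toy_tx, None, hgvsp="p.Trp17fs")
    assert fs.category == "frameshift"
    assert call_consequence(_var(toy_tx, 181, "G", "A"), toy_tx, None).category == "other"


# ---- class assignment ------------------------------------------------------
# toy zone is [136, 300]; domain DOM1 at aa 60-70 = cds 178-210.


def _nonsense_at(toy_tx, toy_cds, anchor):
    """Fabricate a nonsense call anchored at a given codon start."""
    from panelburden.classification import ConsequenceCall

    return ConsequenceCall("nonsense", cds_anchor=anchor)


def test_ptv_upstream_of_zone_is_class5(toy_tx, toy_cds):
    cv = assign_class(_var(toy_tx, 181, "G", "A"), _nonsense_at(toy_tx, toy_cds, 49), toy_tx)
    assert (cv.iarc_class, cv.rationale) == (5, ("ptv_class5",))
    assert cv.is_ptv


def test_ptv_in_zone_without_domain_is_vus(toy_tx, toy_cds):
    # anchor 260: tail [260, 300] misses DOM1 (cds 178-210)
    cv = assign_class(_var(toy_tx, 181, "G", "A"), _nonsense_at(toy_tx, toy_cds, 260), toy_tx)
    assert (cv.iarc_class, cv.rationale) == (3, ("nmd_escape_vus",))


def test_ptv_in_zone_with_domain_disruption_is_class5(toy_tx, toy_cds):
    # anchor 200: tail [200, 300] intersects DOM1 (cds 178-210)
    cv = assign_class(_var(toy_tx, 181, "G", "A"), _nonsense_at(toy_tx, toy_cds, 200), toy_tx)
    assert cv.iarc_class == 5
    assert cv.rationale == ("ptv_class5", "domain_rescue")


def test_domain_enlargement_never_demotes(toy_tx, toy_cds):
    """Monotonicity: growing a domain can only turn VUS into class 5."""
    for anchor in range(136, 300, 7):
        small = assign_class(
            _var(toy_tx, 181, "G", "A"), _nonsense_at(toy_tx, toy_cds, anchor), toy_tx
        )
        big_tx = toy_tx.with_domains([Domain("DOM1", 60, 90)])
        big = assign_class(
            _var(toy_tx, 181, "G", "A"), _nonsense_at(toy_tx, toy_cds, anchor), big_tx
        )
        assert not (small.iarc_class == 5 and big.iarc_class == 3)


def test_common_variant_is_benign_even_if_truncating(toy_tx, toy_cds):
    """MAF >= 1% in any reference population takes precedence over PTV rules."""
    var = _var(toy_tx, 181, "G", "A", mafs={"MAF_EXAC": 0.02})
    cv = assign_class(var, _nonsense_at(toy_tx, toy_cds, 49), toy_tx)
    assert (cv.iarc_class, cv.rationale) == (1, ("maf_benign",))
    # just below threshold in all populations -> rules proceed
    var2 = _var(toy_tx, 181, "G", "A", mafs={"MAF_EXAC": 0.009, "MAF_GMC": 0.002})
    assert assign_class(var2, _nonsense_at(toy_tx, toy_cds, 49), toy_tx).iarc_class == 5


def test_override_forces_class(toy_tx, toy_cds):
    ov = OverrideList()
    ov.add("GENE1", "c.470C>T", 2, "low-risk allele per meta-analysis")
    var = _var(toy_tx, 181, "G", "A", vid="c.470C>T")
    cv = assign_class(var, _nonsense_at(toy_tx, toy_cds, 49), toy_tx, overrides=ov)
    assert (cv.iarc_class, cv.rationale) == (2, ("override",))


def test_final_intron_splice_evaluated_via_last_exon(toy_tx, toy_cds):
    """A splice variant of the final intron truncates at the last exon's
    first coding base (inside the zone, rescued by an overlapping domain
    only when one is present downstream)."""
    from panelburden.classification import ConsequenceCall

    call = ConsequenceCall("essential_splice", splice_detail="donor_plus1", intron_index=2)
    cv = assign_class(_var(toy_tx, 421, "G", "T"), call, toy_tx)
    # last exon starts at cds 191; tail [191,300] intersects DOM1 (178-210)
    assert cv.iarc_class == 5
    assert "final_intron_zone_eval" in cv.notes
    bare_tx = toy_tx.with_domains([])
    cv2 = assign_class(_var(toy_tx, 421, "G", "T"), call, bare_tx)
    assert (cv2.iarc_class, cv2.rationale) == (3, ("nmd_escape_vus",))


def test_missense_default_vus_and_damaging_flag(toy_tx, toy_cds):
    from panelburden.classification import ConsequenceCall

    mis = ConsequenceCall("missense", cds_anchor=4)
    var = _var(
        toy_tx, 134, "C", "A", mafs={"MAF_EXAC": 0.0005},
        verdicts={"PRED1": "damaging", "PRED2": "damaging"},
    )
    cv = assign_class(var, mis, toy_tx)
    assert cv.iarc_class == 3
    assert cv.rationale == ("default_vus", "missense_vus", "damaging_missense_flag")
    assert cv.damaging_missense


@pytest.mark.parametrize(
    "mafs,verdicts,expected",
    [
        ({"MAF_EXAC": 0.0005}, {"P1": "damaging", "P2": "damaging"}, True),
        ({}, {"P1": "damaging", "P2": "tolerated"}, False),
        ({"MAF_EXAC": 0.002}, {"P1": "damaging", "P2": "damaging"}, False),
        ({}, {"P1": "damaging", "P2": "unknown"}, False),
        ({}, {"P1": "damaging", "P2": "damaging"}, True),  # absent MAF counts as rare
    ],
)
def test_flag_damaging_missense_rules(toy_tx, mafs, verdicts, expected):
    from panelburden.classification import ConsequenceCall

    var = _var(toy_tx, 134, "C", "A", mafs=mafs, verdicts=verdicts)
    assert flag_damaging_missense(var, ConsequenceCall("missense", cds_anchor=4)) is expected


def test_flag_requires_missense(toy_tx):
    from panelburden.classification import ConsequenceCall

    var = _var(toy_tx, 181, "G", "A", verdicts={"P1": "damaging", "P2": "damaging"})
    assert not flag_damaging_missense(var, ConsequenceCall("nonsense", cds_anchor=49))


# ---- VCF driver ------------------------------------------------------------


def test_classify_vcf_deterministic_and_skips_unknown_tx(tmp_path, sim_cohort):
    paths = sim_cohort.write(tmp_path / "sim")
    from panelburden.transcripts import load_transcripts
    from panelburden.cli import _read_cds_fasta

    txs = {
        t.transcript_id: t
        for t in load_transcripts(str(paths["gff3"]), domains=str(paths["domains"]))
    }
    cfg = ClassifyConfig(cds_sequences=_read_cds_fasta(str(paths["cds_fasta"])))
    ov = OverrideList.from_tsv(str(paths["overrides"]))
    classified, summary = classify_vcf(str(paths["vcf"]), txs, ov, cfg)
    assert summary["n_classified"] == len(sim_cohort.rows)
    assert summary["n_skipped_unknown_transcript"] == 0
    assert summary["class_counts"][5] > 0 and summary["class_counts"][1] > 0

    out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_classified_tsv(classified, str(out1))
    classified2, _ = classify_vcf(str(paths["vcf"]), txs, ov, cfg)
    write_classified_tsv(classified2, str(out2))
    assert out1.read_bytes() == out2.read_bytes()

    # drop one transcript -> its records are skipped and counted
    del txs["TX_TP53"]
    _, summary3 = classify_vcf(str(paths["vcf"]), txs, ov, cfg)
    assert summary3["n_skipped_unknown_transcript"] > 0
    assert (
        summary3["n_classified"] + summary3["n_skipped_unknown_transcript"]
        == summary["n_classified"]
    )
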