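"""Shared paths and lazy pipeline steps for the analysis scripts."""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM_DIR = RESULTS / "simulated_cohort"
SEED = 17  # single seed for the whole simulated analysis chain


def ensure_simulation() -> dict:
    """Run the cohort simulation if its bundle is not already on disk."""
    from panelburden.simulate import default_config, simulate_cohort

    manifest = SIM_DIR / "manifest.json"
    names = ["vcf", "gff3", "domains", "cds_fasta", "phenotypes",
             "controls", "dmis_controls", "overrides", "truth", "manifest"]
    files = {
        "vcf": "cases.vcf", "gff3": "transcripts.gff3", "domains": "domains.tsv",
        "cds_fasta": "cds.fasta", "phenotypes": "phenotypes.tsv",
        "controls": "controls.tsv", "dmis_controls": "controls_damaging_missense.tsv",
        "overrides": "overrides.tsv", "truth": "truth.tsv", "manifest": "manifest.json",
    }
    if manifest.exists():
        return {k: SIM_DIR / v for k, v in files.items()}
    cohort = simulate_cohort(default_config(SEED))
    return cohort.write(SIM_DIR)


def ensure_classified() -> Path:
    """Classify the simulated VCF if not already done."""
    out = RESULTS / "classified.tsv"
    if out.exists():
        return out
    import json

    from panelburden.classification import ClassifyConfig, OverrideList, classify_vcf, write_classified_tsv
    from panelburden.cli import _read_cds_fasta
    from panelburden.transcripts import load_transcripts

    paths = ensure_simulation()
    transcripts = {
        t.transcript_id: t
        for t in load_transcripts(str(paths["gff3"]), domains=str(paths["domains"]))
    }
    cfg = ClassifyConfig(cds_sequences=_read_cds_fasta(str(paths["cds_fasta"])))
    overrides = OverrideList.from_tsv(str(paths["overrides"]))
    classified, summary = classify_vcf(str(paths["vcf"]), transcripts, overrides, cfg)
    write_classified_tsv(classified, str(out))
    with open(RESULTS / "classified.summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return out
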