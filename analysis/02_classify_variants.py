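"""Classify every simulated variant with the five-tier rule engine.

Consumes the simulated VCF plus transcript models, CDS sequences and the
override list; writes results/classified.tsv and a JSON summary with
per-class and per-gene counts.
"""

import json

from _common import RESULTS, ensure_classified


def main() -> None:
    path = ensure_classified()
    summary = json.loads((RESULTS / "classified.summary.json").read_text())
    print(f"classified variants -> {path}")
    print(f"  alleles classified: {summary['n_classified']} "
          f"(skipped, unknown transcript: {summary['n_skipped_unknown_transcript']})")
    for cls in ("1", "2", "3", "4", "5"):
        print(f"  class {cls}: {summary['class_counts'][cls]}")
    print(f"  protein-truncating: {summary['n_ptv']}, "
          f"damaging-missense flagged: {summary['n_damaging_missense']}")


if __name__ == "__main__":
    main()
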