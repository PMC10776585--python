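#!/usr/bin/env python
"""Tally the annotation evidence over the 25 high-ratio candidate variants.

Applies the five counting rules to the packaged annotation tables: ClinVar
benign-or-likely-benign labels, QC failure in the independent genomes
dataset, specific OMIM gene-phenotype links, availability of an explicit
protein-structure prediction, and regulatory evidence (RegulomeDB rank
stratum < 3 or score > 0.5).

Writes results/findings.json and results/findings.txt.
"""

import json
from pathlib import Path

from fmratio import packaged_annotations, summarize_findings

OUT = Path("results")


def main() -> None:
    annotations = packaged_annotations()
    summary = summarize_findings(annotations)
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "findings.txt").write_text(summary.to_text() + "\n")
    with open(OUT / "findings.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
    print(summary.to_text())
    print(f"\noutputs in {OUT}/findings.json and {OUT}/findings.txt")


if __name__ == "__main__":
    main()
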