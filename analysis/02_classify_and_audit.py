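#!/usr/bin/env python
"""Classify the synthetic corpus and audit against ground truth.

Applies the hierarchical string-matching classifier plus the immunostain
and biomarker parsers to results/synthetic/corpus.tsv, writes the labels
TSV, and reports per-axis agreement with the generator's truth.
"""

from pathlib import Path

import pandas as pd

from lungbm.classifier import audit_agreement, classify_corpus
from lungbm.ihc import annotate_case
from lungbm.records import read_corpus, write_labels
from lungbm.records import TruthRecord, _site_set_from_str

OUT = Path("results/synthetic")


def load_truth(path: Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"case_id": str, "patient_id": str})
    return [
        TruthRecord(
            case_id=r["case_id"], patient_id=r["patient_id"],
            accession_year=int(r["accession_year"]),
            true_category=r["true_category"],
            true_primary_site=r["true_primary_site"],
            true_subtype_reported=r["true_subtype_reported"],
            true_subtype_refined=r["true_subtype_refined"],
            true_site_set=_site_set_from_str(r["true_site_set"]),
        )
        for r in df.to_dict("records")
    ]


def main() -> None:
    reports = read_corpus(OUT / "corpus.tsv")
    truths = load_truth(OUT / "truth.tsv")
    labels = classify_corpus(reports)
    text_of = {r.case_id: r.text for r in reports}
    for lab in labels:
        annotate_case(lab, text_of[lab.case_id])
    write_labels(labels, OUT / "labels.tsv")

    agreement = audit_agreement(labels, truths)
    pd.Series(agreement.accuracy, name="accuracy").to_csv(
        OUT / "audit_accuracy.csv"
    )
    agreement.mismatches.to_csv(OUT / "audit_mismatches.csv", index=False)
    print(f"classified {len(labels)} cases")
    for axis, acc in agreement.accuracy.items():
        print(f"  {axis:14s} accuracy {acc:.4f}")
    print(f"{len(agreement.mismatches)} mismatches "
          f"-> {OUT / 'audit_mismatches.csv'}")


if __name__ == "__main__":
    main()
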