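"""Record types flowing through the pipeline, with TSV round-trip I/O.

ReportRecord  -- one free-text report plus identifiers.
TruthRecord   -- generator-side ground truth paired with a synthetic report.
CaseLabel     -- the classification result for one case.
BiomarkerProfile -- per-marker molecular statuses incl. the PD-L1 TPS bin.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import vocab


class InputError(ValueError):
    """Raised when a pipeline operation receives malformed input."""


def bin_tps(tps: float) -> str:
    """Bin a PD-L1 tumour proportion score (percent of staining tumour cells).

    <1% -> negative; 1-49% -> low-positive; >=50% -> positive.
    """
    if tps < 0 or tps > 100:
        raise InputError(f"TPS must be in [0, 100], got {tps}")
    if tps < 1:
        return vocab.PDL1_NEGATIVE
    if tps < 50:
        return vocab.PDL1_LOW
    return vocab.PDL1_POSITIVE


@dataclass
class BiomarkerProfile:
    egfr: str = vocab.NOT_DONE
    alk_ihc: str = vocab.NOT_DONE
    alk_fish: str = vocab.NOT_DONE
    ras: str = vocab.NOT_DONE
    braf_v600: str = vocab.NOT_DONE
    ros1: str = vocab.NOT_DONE
    pdl1_tps: float | None = None

    @property
    def pdl1_bin(self) -> str:
        if self.pdl1_tps is None:
            return vocab.NOT_DONE
        return bin_tps(self.pdl1_tps)

    @property
    def alk(self) -> str:
        """Combined ALK status for tabulation: IHC takes precedence over FISH."""
        if self.alk_ihc != vocab.NOT_DONE:
            return self.alk_ihc
        return self.alk_fish


@dataclass
class ReportRecord:
    case_id: str
    patient_id: str
    accession_year: int
    text: str


@dataclass
class TruthRecord:
    case_id: str
    patient_id: str
    accession_year: int
    true_category: str
    true_primary_site: str = vocab.PRIMARY_NA
    true_subtype_reported: str = vocab.SUBTYPE_NA
    true_subtype_refined: str = vocab.SUBTYPE_NA
    true_site_set: frozenset[str] = frozenset({vocab.SITE_UNKNOWN})
    true_ihc: dict[str, str] = field(
        default_factory=lambda: {s: vocab.NOT_DONE for s in vocab.STAINS}
    )
    true_biomarkers: BiomarkerProfile = field(default_factory=BiomarkerProfile)
    confirmed: bool = True  # stands in for the pathologist report review

    def __post_init__(self) -> None:
        if not self.true_site_set:
            raise InputError("true_site_set must be non-empty")


@dataclass
class CaseLabel:
    case_id: str
    patient_id: str
    accession_year: int
    category: str
    primary_site: str = vocab.PRIMARY_NA
    subtype: str = vocab.SUBTYPE_NA
    refined_subtype: str = vocab.SUBTYPE_NA
    site_set: frozenset[str] = frozenset({vocab.SITE_UNKNOWN})
    ihc: dict[str, str] = field(
        default_factory=lambda: {s: vocab.NOT_DONE for s in vocab.STAINS}
    )
    biomarkers: BiomarkerProfile = field(default_factory=BiomarkerProfile)


_SET_SEP = ";"


def _site_set_to_str(sites: frozenset[str]) -> str:
    order = {s: i for i, s in enumerate(vocab.SITES)}
    return _SET_SEP.join(sorted(sites, key=lambda s: order.get(s, 99)))


def _site_set_from_str(s: str) -> frozenset[str]:
    return frozenset(x for x in str(s).split(_SET_SEP) if x)


def corpus_to_frame(reports: list[ReportRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in reports],
        columns=["case_id", "patient_id", "accession_year", "text"],
    )


def write_corpus(reports: list[ReportRecord], path: str | Path) -> None:
    corpus_to_frame(reports).to_csv(path, sep="\t", index=False)


def read_corpus(path: str | Path) -> list[ReportRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"case_id": str, "patient_id": str})
    return [
        ReportRecord(r.case_id, r.patient_id, int(r.accession_year), r.text)
        for r in df.itertuples()
    ]


def truth_to_frame(truths: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truths:
        row = {
            "case_id": t.case_id,
            "patient_id": t.patient_id,
            "accession_year": t.accession_year,
            "true_category": t.true_category,
            "true_primary_site": t.true_primary_site,
            "true_subtype_reported": t.true_subtype_reported,
            "true_subtype_refined": t.true_subtype_refined,
            "true_site_set": _site_set_to_str(t.true_site_set),
            "confirmed": t.confirmed,
        }
        for stain in vocab.STAINS:
            row[f"ihc_{stain}"] = t.true_ihc[stain]
        b = t.true_biomarkers
        row.update(
            egfr=b.egfr, alk_ihc=b.alk_ihc, alk_fish=b.alk_fish, ras=b.ras,
            braf_v600=b.braf_v600, ros1=b.ros1,
            pdl1_tps="" if b.pdl1_tps is None else b.pdl1_tps,
            pdl1_bin=b.pdl1_bin,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_truth(truths: list[TruthRecord], path: str | Path) -> None:
    truth_to_frame(truths).to_csv(path, sep="\t", index=False)


def labels_to_frame(labels: list[CaseLabel]) -> pd.DataFrame:
    rows = []
    for c in labels:
        row = {
            "case_id": c.case_id,
            "patient_id": c.patient_id,
            "accession_year": c.accession_year,
            "category": c.category,
            "primary_site": c.primary_site,
            "subtype": c.subtype,
            "refined_subtype": c.refined_subtype,
            "site_set": _site_set_to_str(c.site_set),
        }
        for stain in vocab.STAINS:
            row[f"ihc_{stain}"] = c.ihc[stain]
        b = c.biomarkers
        row.update(
            egfr=b.egfr, alk_ihc=b.alk_ihc, alk_fish=b.alk_fish, ras=b.ras,
            braf_v600=b.braf_v600, ros1=b.ros1,
            pdl1_tps="" if b.pdl1_tps is None else b.pdl1_tps,
            pdl1_bin=b.pdl1_bin,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_labels(labels: list[CaseLabel], path: str | Path) -> None:
    labels_to_frame(labels).to_csv(path, sep="\t", index=False)


def frame_to_labels(df: pd.DataFrame) -> list[CaseLabel]:
    out = []
    for row in df.to_dict("records"):
        tps = row.get("pdl1_tps")
        tps = None if tps in ("", None) or pd.isna(tps) else float(tps)
        out.append(
            CaseLabel(
                case_id=str(row["case_id"]),
                patient_id=str(row["patient_id"]),
                accession_year=int(row["accession_year"]),
                category=row["category"],
                primary_site=row["primary_site"],
                subtype=row["subtype"],
                refined_subtype=row["refined_subtype"],
                site_set=_site_set_from_str(row["site_set"]),
                ihc={s: row[f"ihc_{s}"] for s in vocab.STAINS},
                biomarkers=BiomarkerProfile(
                    egfr=row["egfr"], alk_ihc=row["alk_ihc"],
                    alk_fish=row["alk_fish"], ras=row["ras"],
                    braf_v600=row["braf_v600"], ros1=row["ros1"],
                    pdl1_tps=tps,
                ),
            )
        )
    return out
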