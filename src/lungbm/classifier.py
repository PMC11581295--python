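"""Hierarchical free-text string-matching classification of reports.

Each report receives exactly one diagnostic category (six mutually exclusive
groupings resolved by hierarchy), a primary site when categorized as a
probable metastasis, a lung-cancer subtype honouring the supersession rules
(adenocarcinoma, squamous cell carcinoma, and small cell carcinoma each
supersede the generic non-small cell pattern), and the set of all matched
neuroanatomical location codes.

Matching is case-insensitive substring/stem matching over normalized text;
sentences containing a negation cue ("no ...", "negative for ...") are
ignored, so distractors such as "Negative for small cell carcinoma." do not
fire.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from . import vocab
from .lexicon import MatchLexicon, default_lexicon
from .records import CaseLabel, InputError, ReportRecord, TruthRecord

_SENTENCE_SPLIT = re.compile(r"[.;\n]")
_NORMALIZE = re.compile(r"[^a-z0-9]+")
_NEGATION = re.compile(
    r"\bno\b|\bnot\b|negative for|without|free of|absence of|rule out"
)


def normalize(text: str) -> str:
    """Lowercase and collapse punctuation/whitespace to single spaces."""
    return _NORMALIZE.sub(" ", text.lower()).strip()


def sentences(text: str, *, drop_negated: bool = True) -> list[str]:
    """Normalized sentences, optionally dropping negated ones.

    "not otherwise specified" is canonicalized to "nos" first so the
    negation cue does not swallow generic non-small cell phrasing.
    """
    out = []
    for raw in _SENTENCE_SPLIT.split(text):
        s = normalize(raw)
        if not s:
            continue
        s = s.replace("not otherwise specified", "nos")
        if drop_negated and _NEGATION.search(s):
            continue
        out.append(s)
    return out


def _matches(sents: list[str], lexicon: MatchLexicon, axis: str) -> list:
    hits = []
    for rule, pat in lexicon.axis_rules(axis):
        if any(pat.search(s) for s in sents):
            hits.append(rule)
    return hits  # already in descending priority order


def classify_diagnosis(
    text: str, lexicon: MatchLexicon | None = None
) -> tuple[str, str, str]:
    """Assign (category, subtype, primary_site) to one report text.

    The subtype axis is populated only for probable metastases with a lung
    primary; a lung metastasis matching no subtype keyword is "other", all
    other cases are "not-applicable".  Reports matching two different organ
    keywords get primary_site "multiple/ambiguous".
    """
    if not text or not text.strip():
        raise InputError("report text must be non-empty")
    if lexicon is None:
        lexicon = default_lexicon()
    sents = sentences(text)

    cat_hits = _matches(sents, lexicon, "category")
    category = cat_hits[0].label if cat_hits else "unclassified"

    if category != "probable metastasis":
        return category, vocab.SUBTYPE_NA, vocab.PRIMARY_NA

    organ_labels = {r.label for r in _matches(sents, lexicon, "primary_site")}
    if len(organ_labels) == 0:
        primary = vocab.PRIMARY_UNKNOWN
    elif len(organ_labels) == 1:
        primary = next(iter(organ_labels))
    else:
        primary = vocab.PRIMARY_AMBIGUOUS

    if primary != "lung":
        return category, vocab.SUBTYPE_NA, primary

    sub_hits = _matches(sents, lexicon, "subtype")
    subtype = sub_hits[0].label if sub_hits else vocab.SUBTYPE_OTHER
    return category, subtype, primary


def code_locations(text: str, lexicon: MatchLexicon | None = None) -> frozenset[str]:
    """All matched neuroanatomical location codes; {unknown} when none match.

    Set semantics deduplicate repeated mentions, and hyphenated dual-site
    forms ("temporo-parietal") match both stems.
    """
    if not text or not text.strip():
        raise InputError("report text must be non-empty")
    if lexicon is None:
        lexicon = default_lexicon()
    sents = sentences(text)
    labels = {r.label for r in _matches(sents, lexicon, "location")}
    return frozenset(labels) if labels else frozenset({vocab.SITE_UNKNOWN})


def classify_report(
    report: ReportRecord, lexicon: MatchLexicon | None = None
) -> CaseLabel:
    """Full label for one report (diagnosis axes + location codes)."""
    if lexicon is None:
        lexicon = default_lexicon()
    category, subtype, primary = classify_diagnosis(report.text, lexicon)
    sites = code_locations(report.text, lexicon)
    return CaseLabel(
        case_id=report.case_id,
        patient_id=report.patient_id,
        accession_year=report.accession_year,
        category=category,
        primary_site=primary,
        subtype=subtype,
        refined_subtype=subtype,
        site_set=sites,
    )


def classify_corpus(
    reports: list[ReportRecord], lexicon: MatchLexicon | None = None
) -> list[CaseLabel]:
    if lexicon is None:
        lexicon = default_lexicon()
    return [classify_report(r, lexicon) for r in reports]


@dataclass
class AgreementReport:
    accuracy: dict[str, float]
    mismatches: pd.DataFrame

    def __getitem__(self, axis: str) -> float:
        return self.accuracy[axis]


_AXES = {
    "category": lambda p, t: p.category == t.true_category,
    "primary_site": lambda p, t: (
        t.true_category != "probable metastasis"
        or p.primary_site == t.true_primary_site
    ),
    "subtype": lambda p, t: (
        t.true_subtype_reported == vocab.SUBTYPE_NA
        or p.subtype == t.true_subtype_reported
    ),
    "location": lambda p, t: p.site_set == t.true_site_set,
}


def audit_agreement(
    predicted: list[CaseLabel], truth: list[TruthRecord]
) -> AgreementReport:
    """Per-axis exact-match accuracy of predictions against ground truth.

    Predictions and truth must align one-to-one by case id.  The subtype
    axis is audited against the reported (pre-refinement) subtype and only
    over cases where the truth defines one; primary site only over true
    metastases.
    """
    if len(predicted) != len(truth):
        raise InputError(
            f"length mismatch: {len(predicted)} predictions vs "
            f"{len(truth)} truth records"
        )
    tmap = {t.case_id: t for t in truth}
    rows = []
    correct = {axis: 0 for axis in _AXES}
    denom = {axis: 0 for axis in _AXES}
    for p in predicted:
        t = tmap.get(p.case_id)
        if t is None:
            raise InputError(f"no truth record for case {p.case_id}")
        for axis, check in _AXES.items():
            if axis == "subtype" and t.true_subtype_reported == vocab.SUBTYPE_NA:
                continue
            if axis == "primary_site" and t.true_category != "probable metastasis":
                continue
            denom[axis] += 1
            if check(p, t):
                correct[axis] += 1
            else:
                rows.append(
                    {
                        "case_id": p.case_id,
                        "axis": axis,
                        "predicted": _axis_value(p, axis),
                        "truth": _axis_truth(t, axis),
                    }
                )
    accuracy = {
        axis: (correct[axis] / denom[axis]) if denom[axis] else float("nan")
        for axis in _AXES
    }
    return AgreementReport(
        accuracy=accuracy,
        mismatches=pd.DataFrame(rows, columns=["case_id", "axis", "predicted",
                                               "truth"]),
    )


def _axis_value(p: CaseLabel, axis: str):
    return {
        "category": p.category,
        "primary_site": p.primary_site,
        "subtype": p.subtype,
        "location": ";".join(sorted(p.site_set)),
    }[axis]


def _axis_truth(t: TruthRecord, axis: str):
    return {
        "category": t.true_category,
        "primary_site": t.true_primary_site,
        "subtype": t.true_subtype_reported,
        "location": ";".join(sorted(t.true_site_set)),
    }[axis]
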