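"""Immunostain and lung-biomarker extraction, and subtype refinement.

parse_stain      -- tri-state (positive/negative/not-done) for TTF-1, p63,
                    p40 and neuroendocrine markers from report text.
refine_subtype   -- the immunostain re-classification of generic non-small
                    cell carcinoma: TTF-1 positive with p63 NOT positive
                    (negative or not performed) -> adenocarcinoma; TTF-1
                    negative with p63 positive -> squamous cell carcinoma.
parse_biomarkers -- EGFR / ALK (IHC and FISH) / RAS / BRAF V600 / ROS-1
                    statuses and the PD-L1 tumour proportion score with its
                    <1% / 1-49% / >=50% bin.

p40 is parsed but deliberately excluded from refinement (too rarely
performed in the emulated cohort to inform the rules).
"""

from __future__ import annotations

import re
import warnings

from . import vocab
from .records import BiomarkerProfile, CaseLabel, InputError, bin_tps

_STAIN_SYNONYMS: dict[str, list[str]] = {
    "TTF-1": [r"ttf\s?1\b", r"thyroid transcription factor\s?1"],
    "p63": [r"\bp63\b"],
    "p40": [r"\bp40\b"],
    "neuroendocrine markers": [
        r"synaptophysin", r"chromogranin", r"\bcd56\b", r"\binsm1\b",
        r"neuroendocrine markers?",
    ],
}

_ANY_STAIN = re.compile(
    "|".join(p for pats in _STAIN_SYNONYMS.values() for p in pats)
)
_NOT_DONE_CUES = re.compile(
    r"not (?:performed|done|available)|pending|quantity insufficient|"
    r"insufficient (?:tissue|material)"
)
_RESULT = re.compile(r"\b(positive|negative)\b")


def _normalize_sentences(text: str) -> list[str]:
    out = []
    for raw in re.split(r"[.;\n]", text):
        s = re.sub(r"[^a-z0-9]+", " ", raw.lower()).strip()
        if s:
            out.append(s)
    return out


def parse_stain(text: str, stain_name: str) -> str:
    """Extract a tri-state immunostain result from report text.

    A result is returned only when an unambiguous result statement for the
    stain exists; anything else (no mention, "not performed", conflicting
    statements) yields not-done.  When several stains share a sentence
    ("TTF-1 positive, p63 negative") the result token belonging to the
    queried stain is the first one after its mention and before the next
    stain mention.
    """
    if stain_name not in _STAIN_SYNONYMS:
        raise InputError(f"unknown stain {stain_name!r}")
    pats = [re.compile(p) for p in _STAIN_SYNONYMS[stain_name]]
    verdicts = []
    for s in _normalize_sentences(text):
        mentions = [m for p in pats for m in p.finditer(s)]
        if not mentions:
            continue
        if _NOT_DONE_CUES.search(s):
            continue  # counts as not performed
        for m in mentions:
            after = s[m.end():]
            nxt = _ANY_STAIN.search(after)
            window = after[: nxt.start()] if nxt else after
            res = _RESULT.search(window)
            if res is None:
                # "positive for TTF-1" phrasing: look immediately before
                before = s[: m.start()]
                prev = None
                for r in _RESULT.finditer(before):
                    prev = r
                if prev is not None and _ANY_STAIN.search(before[prev.end():]):
                    prev = None
                res = prev
            if res is not None:
                verdicts.append(res.group(1))
    if not verdicts or len(set(verdicts)) > 1:
        return vocab.NOT_DONE
    return verdicts[0]


def refine_subtype(reported_subtype: str, ttf1: str, p63: str) -> str:
    """Immunostain refinement of the reported lung-cancer subtype.

    Applies only to generic non-small cell carcinoma NOS; every other
    subtype passes through unchanged.  "p63 NOT positive" means negative
    or not performed, so the adenocarcinoma rule fires on TTF-1 positive
    cases without a p63 result.  Idempotent by construction.
    """
    if reported_subtype != vocab.SUBTYPE_NSCLC:
        return reported_subtype
    if ttf1 == vocab.POSITIVE and p63 in (vocab.NEGATIVE, vocab.NOT_DONE):
        return vocab.SUBTYPE_AC
    if ttf1 == vocab.NEGATIVE and p63 == vocab.POSITIVE:
        return vocab.SUBTYPE_SCC
    return vocab.SUBTYPE_NSCLC


_MARKER_PATTERNS: dict[str, str] = {
    "egfr": r"\begfr\b",
    "alk_fish": r"\balk\b[a-z0-9 ]*?\b(?:fish|fluorescence in situ)",
    "alk_ihc": r"\balk\b",
    "ras": r"\bk?ras\b",
    "braf_v600": r"\bbraf\b",
    "ros1": r"\bros\s?1\b",
}

_MARKER_RESULT = re.compile(
    r"\b(positive|negative|detected|not detected|identified|rearranged)\b"
)
_PDL1_TPS = re.compile(
    r"pd[\s-]?l[\s-]?1[^.;\n]*?(?:tps|tumou?r proportion score)\s*(?:of\s*)?"
    r"[:=]?\s*(<\s*1|\d+(?:\.\d+)?)\s*%",
    re.IGNORECASE,
)


def _marker_status(text_sentences: list[str], marker: str) -> str:
    pat = re.compile(_MARKER_PATTERNS[marker])
    verdicts = []
    for s in text_sentences:
        m = pat.search(s)
        if m is None:
            continue
        if marker == "alk_ihc" and re.search(_MARKER_PATTERNS["alk_fish"], s):
            continue  # FISH sentence, not IHC
        if _NOT_DONE_CUES.search(s):
            continue
        res = _MARKER_RESULT.search(s[m.end():]) or _MARKER_RESULT.search(s)
        if res is None:
            continue
        token = res.group(1)
        if token in ("positive", "detected", "identified", "rearranged"):
            # "not detected" keeps its "not" after normalization
            prefix = s[max(0, res.start() - 4): res.start()]
            if "not" in prefix:
                verdicts.append(vocab.NEGATIVE)
            else:
                verdicts.append(vocab.POSITIVE)
        else:
            verdicts.append(vocab.NEGATIVE)
    if not verdicts or len(set(verdicts)) > 1:
        return vocab.NOT_DONE
    return verdicts[0]


def parse_biomarkers(text: str) -> BiomarkerProfile:
    """Extract the lung biomarker profile from report text.

    A malformed PD-L1 TPS (non-numeric or above 100%) raises a parse
    warning and leaves the marker not-done.
    """
    if not text or not text.strip():
        raise InputError("report text must be non-empty")
    sents = _normalize_sentences(text)
    profile = BiomarkerProfile(
        egfr=_marker_status(sents, "egfr"),
        alk_ihc=_marker_status(sents, "alk_ihc"),
        alk_fish=_marker_status(sents, "alk_fish"),
        ras=_marker_status(sents, "ras"),
        braf_v600=_marker_status(sents, "braf_v600"),
        ros1=_marker_status(sents, "ros1"),
    )
    m = _PDL1_TPS.search(text)
    if m:
        raw = m.group(1).replace(" ", "")
        tps = 0.0 if raw.startswith("<") else float(raw)
        if tps > 100:
            warnings.warn(
                f"PD-L1 TPS {tps} outside [0, 100]; treating as not done",
                stacklevel=2,
            )
        else:
            profile.pdl1_tps = tps
    return profile


def annotate_case(label: CaseLabel, text: str) -> CaseLabel:
    """Fill the IHC tri-states and biomarker profile and refine the subtype."""
    label.ihc = {s: parse_stain(text, s) for s in vocab.STAINS}
    label.biomarkers = parse_biomarkers(text)
    label.refined_subtype = refine_subtype(
        label.subtype, label.ihc["TTF-1"], label.ihc["p63"]
    )
    return label


__all__ = [
    "parse_stain",
    "refine_subtype",
    "parse_biomarkers",
    "annotate_case",
    "bin_tps",
]
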