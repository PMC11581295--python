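"""Closed label vocabularies shared across the pipeline.

Every axis the report classifier emits draws from one of these lists; the
tabulation and statistics layers rely on the fixed orderings to produce
byte-reproducible output.
"""

from __future__ import annotations

# Diagnostic groupings, listed in ascending hierarchy order: when several
# category patterns fire on one report, the later (more specific) grouping
# wins.  "unclassified" is the no-match fallback.
CATEGORIES = [
    "unclassified",
    "brain cardiovascular disease",
    "miscellaneous lesions",
    "other brain lesions",
    "probable metastasis",
    "primary brain tumour",
]

# Lung-cancer subtypes used in the refined classification.
SUBTYPE_AC = "adenocarcinoma"
SUBTYPE_SCC = "squamous cell carcinoma"
SUBTYPE_SCLC = "small cell carcinoma"
SUBTYPE_NSCLC = "non-small cell carcinoma NOS"
SUBTYPES = [SUBTYPE_AC, SUBTYPE_SCC, SUBTYPE_SCLC, SUBTYPE_NSCLC]
SUBTYPE_OTHER = "other"
SUBTYPE_NA = "not-applicable"

# Neuroanatomical location codes.  The five named regions plus the two
# catch-all codes; "unknown" is the no-match fallback and never co-occurs
# with a named site.
NAMED_SITES = ["frontal", "parietal", "temporal", "occipital", "cerebellum"]
SITE_OTHER = "other"
SITE_UNKNOWN = "unknown"
SITES = NAMED_SITES + [SITE_OTHER, SITE_UNKNOWN]

# Primary sites for probable metastases.
PRIMARY_SITES = ["lung", "breast", "melanoma", "colorectal", "renal", "other"]
PRIMARY_UNKNOWN = "unknown"
PRIMARY_AMBIGUOUS = "multiple/ambiguous"
PRIMARY_NA = "not-applicable"

# Immunostain and biomarker tri-states.
POSITIVE = "positive"
NEGATIVE = "negative"
NOT_DONE = "not-done"
TRISTATES = [POSITIVE, NEGATIVE, NOT_DONE]

STAINS = ["TTF-1", "p63", "p40", "neuroendocrine markers"]

MARKERS = ["egfr", "alk_ihc", "alk_fish", "pdl1", "ras", "braf_v600", "ros1"]

# PD-L1 tumour proportion score bins.
PDL1_NEGATIVE = "negative"        # TPS < 1%
PDL1_LOW = "low-positive"         # 1% <= TPS < 50%
PDL1_POSITIVE = "positive"        # TPS >= 50%
PDL1_BINS = [PDL1_NEGATIVE, PDL1_LOW, PDL1_POSITIVE]

# Abbreviations used in figure/heatmap labels.
SITE_ABBREV = {
    "frontal": "FRO",
    "parietal": "PAR",
    "temporal": "TEM",
    "occipital": "OCC",
    "cerebellum": "CER",
}
SUBTYPE_ABBREV = {
    SUBTYPE_AC: "AC",
    SUBTYPE_SCC: "SCC",
    SUBTYPE_SCLC: "SCLC",
    SUBTYPE_NSCLC: "NSCLC",
}
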