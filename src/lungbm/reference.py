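"""Published summary tables from the 234-patient lung brain-metastasis cohort.

These are the printed patient/lesion tabulations of the source cohort the
synthetic generator emulates, bundled as in-memory fixtures so every derived
statistic (global subtype-by-site exact test, PD-L1 contrasts, pairwise
decomposition, overlap-matrix summaries) can be recomputed without any
patient-level data.
"""

from __future__ import annotations

import pandas as pd

from . import exact, vocab
from .tables import OverlapMatrix

SITES5 = vocab.NAMED_SITES
SUBTYPE_ORDER = [
    vocab.SUBTYPE_AC, vocab.SUBTYPE_SCC, vocab.SUBTYPE_SCLC, vocab.SUBTYPE_NSCLC
]


def overlap_matrix() -> pd.DataFrame:
    """The 7x7 neuroanatomical site co-occurrence matrix (patient counts)."""
    data = [
        [88, 4, 4, 0, 0, 1, 0],
        [4, 48, 2, 9, 0, 2, 0],
        [4, 2, 20, 0, 0, 0, 0],
        [0, 9, 0, 35, 2, 2, 0],
        [0, 0, 0, 2, 61, 10, 0],
        [1, 2, 0, 2, 10, 17, 0],
        [0, 0, 0, 0, 0, 0, 1],
    ]
    return pd.DataFrame(data, index=vocab.SITES, columns=vocab.SITES)


def lesion_table() -> pd.DataFrame:
    """Immunostain-refined subtype x site lesion counts (255 lesions)."""
    data = {
        "frontal": [59, 8, 6, 15],
        "parietal": [31, 5, 4, 8],
        "temporal": [14, 5, 0, 1],
        "occipital": [21, 8, 2, 4],
        "cerebellum": [37, 1, 17, 6],
        "unknown/other": [2, 0, 1, 0],
    }
    return pd.DataFrame(data, index=SUBTYPE_ORDER)


def patient_counts() -> pd.Series:
    """Patients per refined subtype (234 patients)."""
    return pd.Series(
        [152, 23, 28, 31], index=SUBTYPE_ORDER, name="patients"
    )


def simplified_lesion_table() -> pd.DataFrame:
    """The 4x5 lesion table after dropping the unknown/other column (n=252)."""
    return lesion_table().drop(columns=["unknown/other"])


def biomarker_subtype_tables() -> dict[str, pd.DataFrame]:
    """Biomarker status by reported-then-refined subtype (patient counts)."""
    cols = [vocab.SUBTYPE_AC, vocab.SUBTYPE_SCC, vocab.SUBTYPE_NSCLC,
            vocab.SUBTYPE_SCLC]
    egfr = pd.DataFrame(
        {"adequate": [48, 7, 9, 1], "negative": [43, 7, 6, 1],
         "positive": [5, 0, 3, 0]}, index=cols,
    ).T
    pdl1 = pd.DataFrame(
        {"adequate": [60, 7, 11, 1], "negative": [19, 3, 4, 1],
         "low-positive": [12, 1, 2, 0], "positive": [29, 3, 5, 0]},
        index=cols,
    ).T
    ras = pd.DataFrame(
        {"adequate": [36, 6, 8, 1], "negative": [16, 5, 6, 1],
         "positive": [20, 1, 2, 0]}, index=cols,
    ).T
    return {"egfr": egfr, "pdl1": pdl1, "ras": ras}


def biomarker_site_tables() -> dict[str, pd.DataFrame]:
    """Biomarker status by neuroanatomical site (lesion counts, named sites)."""
    egfr = pd.DataFrame(
        {"adequate": [27, 17, 4, 12, 11], "negative": [22, 16, 4, 12, 9],
         "positive": [5, 1, 0, 0, 2]}, index=SITES5,
    ).T
    pdl1 = pd.DataFrame(
        {"adequate": [27, 25, 5, 17, 13], "negative": [6, 9, 5, 5, 6],
         "low-positive": [4, 3, 0, 5, 4], "positive": [17, 13, 0, 7, 3]},
        index=SITES5,
    ).T
    ras = pd.DataFrame(
        {"adequate": [21, 12, 3, 12, 8], "negative": [12, 8, 2, 8, 3],
         "positive": [9, 4, 1, 4, 5]}, index=SITES5,
    ).T
    return {"egfr": egfr, "pdl1": pdl1, "ras": ras}


def biomarker_overview() -> pd.DataFrame:
    """Cohort-level biomarker availability and positivity counts."""
    return pd.DataFrame(
        {
            "adequate": [65, 78, 79, 51, 51],
            "negative": [57, 77, 27, 28, 50],
            "low-positive": [0, 0, 15, 0, 0],
            "positive": [8, 1, 37, 23, 1],
        },
        index=["egfr", "alk", "pdl1", "ras", "braf_v600"],
    )


# The four PD-L1 negative-vs-positive site contrasts flagged as significant.
PDL1_FLAGGED_CONTRASTS = [
    ("parietal", "temporal"),
    ("frontal", "temporal"),
    ("temporal", "occipital"),
    ("frontal", "cerebellum"),
]


def pdl1_negative_positive_contrast(site_a: str, site_b: str):
    """2x2 table of PD-L1 negative/positive lesion counts for two sites."""
    t = biomarker_site_tables()["pdl1"]
    return pd.DataFrame(
        {
            "negative": [t.loc["negative", site_a], t.loc["negative", site_b]],
            "positive": [t.loc["positive", site_a], t.loc["positive", site_b]],
        },
        index=[site_a, site_b],
    )


def reference_statistics(seed: int = 0, mc_reps: int = 1_000_000) -> dict:
    """Recompute every statistic derivable from the bundled cohort tables.

    Returns a flat dict of numbers: the global subtype-by-site Monte-Carlo
    Fisher p, the exact PD-L1-by-site p, the biomarker-by-subtype tests
    (small cell excluded), the ten PD-L1 negative/positive site contrasts,
    and the overlap-matrix summaries.
    """
    out: dict = {}

    om = OverlapMatrix.from_matrix(overlap_matrix())
    out["pure"] = {s: int(v) for s, v in om.pure.items()}
    out["mixed_patients"] = int(om.mixed)
    out["total_patients"] = int(om.pure.sum() + om.mixed)

    simp = simplified_lesion_table()
    out["simplified_lesion_total"] = int(simp.to_numpy().sum())
    out["simplified_cell_count"] = int(simp.size)
    res = exact.fisher_rxc_mc(simp.to_numpy(), reps=mc_reps, seed=seed)
    out["subtype_site_fisher_p"] = res.p
    out["subtype_site_fisher_se"] = res.mc_se
    out["subtype_site_fisher_reps"] = res.mc_reps

    pdl1_site = biomarker_site_tables()["pdl1"].drop(index=["adequate"])
    out["pdl1_site_fisher_p"] = exact.fisher_rxc_exact(pdl1_site.to_numpy()).p

    subtype_tabs = biomarker_subtype_tables()
    for marker in ("egfr", "pdl1", "ras"):
        t = subtype_tabs[marker].drop(index=["adequate"])
        t = t.drop(columns=[vocab.SUBTYPE_SCLC])
        out[f"{marker}_subtype_fisher_p"] = exact.fisher_rxc_exact(
            t.to_numpy()
        ).p

    site_tabs = biomarker_site_tables()
    for marker in ("egfr", "ras"):
        t = site_tabs[marker].drop(index=["adequate"])
        out[f"{marker}_site_fisher_p"] = exact.fisher_rxc_exact(t.to_numpy()).p

    contrasts = {}
    import itertools

    for a, b in itertools.combinations(SITES5, 2):
        contrasts[f"{a}-{b}"] = exact.fisher_2x2(
            pdl1_negative_positive_contrast(a, b).to_numpy()
        ).p
    out["pdl1_negative_positive_contrasts"] = contrasts
    out["pdl1_significant_site_contrasts"] = sum(
        1 for v in contrasts.values() if v < 0.05
    )

    pairs = exact.all_pairs_2x2(simp)
    out["pairwise_tables_count"] = int(pairs.size)
    return out
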