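"""Synthetic pathology-report corpus generator with paired ground truth.

Emulates a regional neuropathology archive: a mix of diagnostic categories
in which probable metastases carry a primary site, lung metastases carry a
subtype with a site distribution that depends on the subtype, a fraction of
patients carry two location codes, immunostain availability and results are
consistent with the subtype-refinement rules, and biomarker availability is
gated by accession-year bands.  Every report is paired with a TruthRecord so
the downstream classifier, refiner and tabulators can be audited without any
real data.

The default parameters are the emulated cohort's own frequencies: a 4,625 /
854 / 538 diagnostic funnel shape, 234/511 lung primaries, the subtype-site
joint distribution of the 255-lesion tabulation, a 36/234 two-site overlap
rate, TTF-1/p63/p40 availability of 206, 46 and 5 per 234, and year-banded
biomarker testing (none before 2014, 69.6% from 2016 on).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import vocab
from .records import BiomarkerProfile, ReportRecord, TruthRecord
from .ihc import refine_subtype


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


def _default_category_mix() -> dict[str, float]:
    # shares of a 4,625-case archive funnel
    counts = {
        "unclassified": 69,
        "brain cardiovascular disease": 550,
        "miscellaneous lesions": 460,
        "other brain lesions": 740,
        "probable metastasis": 854,
        "primary brain tumour": 1952,
    }
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def _default_primary_site_mix() -> dict[str, float]:
    # lung fixed at 234/511; the remainder split over common primaries
    lung = 234 / 511
    rest = 1 - lung
    shares = {"breast": 0.30, "melanoma": 0.22, "colorectal": 0.16,
              "renal": 0.10, "other": 0.22}
    out = {"lung": lung}
    out.update({k: rest * v for k, v in shares.items()})
    return out


def _default_subtype_site_joint() -> np.ndarray:
    # lesion-proportion joint over subtype x (5 named sites + unknown/other)
    counts = np.array(
        [
            [59, 31, 14, 21, 37, 2],
            [8, 5, 5, 8, 1, 0],
            [6, 4, 0, 2, 17, 1],
            [15, 8, 1, 4, 6, 0],
        ],
        dtype=float,
    )
    return counts / counts.sum()


@dataclass
class BiomarkerConfig:
    """Availability and positivity of lung biomarkers by accession-year band."""

    year_band_testing: dict[tuple[int, int], float] = field(
        default_factory=lambda: {
            (2011, 2013): 0.0,
            (2014, 2015): 0.064,
            (2016, 2020): 87 / 125,
        }
    )
    # per-marker availability conditional on any biomarker testing
    availability: dict[str, float] = field(
        default_factory=lambda: {
            "egfr": 65 / 90, "alk": 78 / 90, "pdl1": 79 / 90,
            "ras": 51 / 90, "braf_v600": 51 / 90, "ros1": 0.0,
        }
    )
    positivity: dict[str, float] = field(
        default_factory=lambda: {
            "egfr": 8 / 65, "alk": 1 / 78, "ras": 23 / 51,
            "braf_v600": 1 / 51, "ros1": 0.02,
        }
    )
    # PD-L1 TPS bin probabilities: <1%, 1-49%, >=50%
    pdl1_bins: tuple[float, float, float] = (27 / 79, 15 / 79, 37 / 79)
    alk_fish_fraction: float = 0.2  # ALK tested by FISH rather than IHC

    def testing_rate(self, year: int) -> float:
        for (lo, hi), rate in self.year_band_testing.items():
            if lo <= year <= hi:
                return rate
        return 0.0


@dataclass
class GeneratorConfig:
    n_cases: int = 2000
    seed: int = 0
    lexical_noise: float = 0.0
    year_range: tuple[int, int] = (2011, 2020)
    multi_case_rate: float = 0.05       # patients with a second specimen
    repeat_site_concordance: float = 6 / 8
    confirm_rate: float = 538 / 854     # review-confirmed metastases
    category_mix: dict[str, float] = field(default_factory=_default_category_mix)
    primary_site_mix: dict[str, float] = field(
        default_factory=_default_primary_site_mix
    )
    subtype_site_joint: np.ndarray = field(
        default_factory=_default_subtype_site_joint
    )
    overlap_rate: float = 36 / 234      # lung patients with two site codes
    max_overlap_sites: int = 2
    reclass_rate_ac: float = 37 / 152   # P(reported generic NSCLC | refined AC)
    reclass_rate_scc: float = 4 / 23
    ihc_availability: dict[str, float] = field(
        default_factory=lambda: {"TTF-1": 206 / 234, "p63": 46 / 234,
                                 "p40": 5 / 234}
    )
    biomarkers: BiomarkerConfig = field(default_factory=BiomarkerConfig)

    def validate(self) -> None:
        if not isinstance(self.n_cases, (int, np.integer)) or self.n_cases < 1:
            raise ConfigError(f"n_cases must be a positive integer, got "
                              f"{self.n_cases!r}")
        for name, vec, keys in [
            ("category_mix", self.category_mix, vocab.CATEGORIES),
            ("primary_site_mix", self.primary_site_mix, vocab.PRIMARY_SITES),
        ]:
            if set(vec) != set(keys):
                raise ConfigError(f"{name}: expected keys {sorted(keys)}")
            if any(v < 0 for v in vec.values()):
                raise ConfigError(f"{name}: negative probability")
            if abs(sum(vec.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name}: probabilities must sum to 1")
        joint = np.asarray(self.subtype_site_joint, dtype=float)
        if joint.shape != (4, 6):
            raise ConfigError("subtype_site_joint: expected a 4x6 matrix")
        if (joint < 0).any() or abs(joint.sum() - 1.0) > 1e-9:
            raise ConfigError("subtype_site_joint: entries must be a "
                              "probability distribution summing to 1")
        for name in ("lexical_noise", "multi_case_rate", "confirm_rate",
                     "overlap_rate", "repeat_site_concordance",
                     "reclass_rate_ac", "reclass_rate_scc"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for stain, v in self.ihc_availability.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"ihc_availability[{stain!r}] must be in "
                                  f"[0, 1], got {v}")
        if self.max_overlap_sites < 2:
            raise ConfigError("max_overlap_sites must be >= 2")
        if abs(sum(self.biomarkers.pdl1_bins) - 1.0) > 1e-9:
            raise ConfigError("biomarkers.pdl1_bins must sum to 1")


# rendering phrase tables ---------------------------------------------------

_SUBTYPE_PHRASE = {
    vocab.SUBTYPE_AC: "adenocarcinoma",
    vocab.SUBTYPE_SCC: "squamous cell carcinoma",
    vocab.SUBTYPE_SCLC: "small cell carcinoma",
    vocab.SUBTYPE_NSCLC: "non-small cell carcinoma",
}
_SUBTYPE_SYNONYM = {
    vocab.SUBTYPE_AC: "pulmonary adenocarcinoma",
    vocab.SUBTYPE_SCC: "squamous cell carcinoma, keratinizing",
    vocab.SUBTYPE_SCLC: "small cell neuroendocrine carcinoma",
    vocab.SUBTYPE_NSCLC: "non-small cell carcinoma, not otherwise specified",
}
_SITE_PHRASE = {
    "frontal": "left frontal lobe",
    "parietal": "left parietal lobe",
    "temporal": "left temporal lobe",
    "occipital": "left occipital lobe",
    "cerebellum": "cerebellum",
    vocab.SITE_OTHER: "brainstem",
    vocab.SITE_UNKNOWN: "brain, site not specified",
}
_COMBINING = {
    "frontal": "fronto", "parietal": "parieto", "temporal": "temporo",
    "occipital": "occipito", "cerebellum": "cerebello",
}
_ADJECTIVE = {
    "frontal": "frontal", "parietal": "parietal", "temporal": "temporal",
    "occipital": "occipital", "cerebellum": "cerebellar",
}
_CATEGORY_PHRASES = {
    "primary brain tumour": [
        "Glioblastoma, IDH-wildtype",
        "Meningioma, WHO grade 1",
        "Diffuse astrocytoma",
    ],
    "brain cardiovascular disease": [
        "Organizing hematoma",
        "Subacute infarct with macrophage reaction",
        "Arteriovenous malformation",
    ],
    "other brain lesions": [
        "Demyelinating lesion",
        "Brain abscess with acute inflammation",
    ],
    "miscellaneous lesions": [
        "Gliosis and reactive changes",
        "Unremarkable brain tissue",
    ],
    "unclassified": [
        "Specimen submitted for review, see comment",
        "Fragments of tissue, see addendum",
    ],
}
_PRIMARY_PHRASE = {
    "breast": "breast",
    "colorectal": "colorectal",
    "renal": "renal",
    "other": "prostate",
}
_DISTRACTORS = [
    "No evidence of meningioma.",
    "Negative for small cell carcinoma.",
    "No definite glioma is identified.",
    "Without evidence of lymphoma.",
]


def _diagnosis_sentence(t: TruthRecord, noise: float, rng) -> str:
    cat = t.true_category
    if cat != "probable metastasis":
        phrases = _CATEGORY_PHRASES[cat]
        idx = int(rng.integers(len(phrases))) if noise > 0 else 0
        return f"Final diagnosis: {phrases[idx]}."
    primary = t.true_primary_site
    if primary == "melanoma":
        return "Final diagnosis: Metastatic malignant melanoma."
    if primary == "lung":
        phrase = _SUBTYPE_PHRASE[t.true_subtype_reported]
        if noise > 0 and rng.random() < noise:
            if rng.random() < 0.15:
                phrase = "poorly differentiated carcinoma"  # unsubtypable
            else:
                phrase = _SUBTYPE_SYNONYM[t.true_subtype_reported]
        organ = "pulmonary" if (noise > 0 and rng.random() < noise * 0.5) \
            else "lung"
        return f"Final diagnosis: Metastatic {phrase} consistent with " \
               f"{organ} primary."
    organ = _PRIMARY_PHRASE[primary]
    return f"Final diagnosis: Metastatic carcinoma consistent with {organ} " \
           f"primary."


def _location_sentence(t: TruthRecord, noise: float, rng) -> str | None:
    sites = sorted(t.true_site_set, key=vocab.SITES.index)
    if noise > 0 and rng.random() < noise * 0.1:
        return None  # location omitted from the report
    named = [s for s in sites if s in vocab.NAMED_SITES]
    if (
        len(sites) == 2 and len(named) == 2
        and noise > 0 and rng.random() < noise
    ):
        comb = f"{_COMBINING[named[0]]}-{_ADJECTIVE[named[1]]}"
        return f"Location: {comb} region."
    phrases = [_SITE_PHRASE[s] for s in sites]
    return f"Location: {' and '.join(phrases)}."


def _ihc_sentences(t: TruthRecord, noise: float, rng) -> list[str]:
    out = []
    display = {"TTF-1": "TTF-1", "p63": "p63", "p40": "p40"}
    for stain in ("TTF-1", "p63", "p40"):
        res = t.true_ihc[stain]
        if res == vocab.NOT_DONE:
            continue
        if noise > 0 and rng.random() < noise:
            out.append(f"{display[stain]} is {res} in tumour cells.")
        else:
            out.append(f"{display[stain]}: {res}.")
    ne = t.true_ihc["neuroendocrine markers"]
    if ne != vocab.NOT_DONE:
        out.append(f"Synaptophysin: {ne}.")
    return out


def _biomarker_sentences(t: TruthRecord, noise: float, rng) -> list[str]:
    b = t.true_biomarkers
    out = []
    for name, status in [("EGFR", b.egfr), ("ALK IHC", b.alk_ihc),
                         ("ALK FISH", b.alk_fish), ("KRAS", b.ras),
                         ("BRAF V600", b.braf_v600), ("ROS1", b.ros1)]:
        if status != vocab.NOT_DONE:
            out.append(f"{name}: {status}.")
    if b.pdl1_tps is not None:
        tps = b.pdl1_tps
        tps_txt = str(int(tps)) if float(tps).is_integer() else str(tps)
        if noise > 0 and rng.random() < noise:
            out.append(f"PD-L1 tumour proportion score of {tps_txt}%.")
        else:
            out.append(f"PD-L1 TPS {tps_txt}%.")
    return out


def render_report(
    truth: TruthRecord, noise: float = 0.0, rng=None
) -> str:
    """Render one report text from its ground truth.

    At noise 0 the text contains exactly the canonical keyword for each true
    label; at noise > 0 synonyms, hyphenated dual-site phrasing and negated
    distractor sentences may appear, and the subtype or location sentence may
    degrade.  Same truth and same generator state give the same text.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    parts = [_diagnosis_sentence(truth, noise, rng)]
    loc = _location_sentence(truth, noise, rng)
    if loc:
        parts.append(loc)
    parts.extend(_ihc_sentences(truth, noise, rng))
    parts.extend(_biomarker_sentences(truth, noise, rng))
    if noise > 0:
        k = int(rng.random() < noise) + int(rng.random() < noise * 0.5)
        if k:
            picks = rng.choice(len(_DISTRACTORS), size=k, replace=False)
            parts.extend(_DISTRACTORS[i] for i in picks)
    return " ".join(parts)


# truth sampling ------------------------------------------------------------

def _split_unknown_other(p_uo: float) -> tuple[float, float]:
    # merged unknown/other column split 2:1 between "other" and "unknown"
    return (2 / 3) * p_uo, (1 / 3) * p_uo


def _site_distribution(joint_row: np.ndarray) -> np.ndarray:
    """Per-subtype conditional over the seven internal site codes."""
    p = joint_row / joint_row.sum()
    p_other, p_unknown = _split_unknown_other(p[5])
    return np.array([p[0], p[1], p[2], p[3], p[4], p_other, p_unknown])


def _draw_site_set(cond: np.ndarray, cfg: GeneratorConfig, rng) -> frozenset:
    if rng.random() < cfg.overlap_rate:
        # multi-site patients: distinct codes, never "unknown"
        weights = cond[:6].copy()
        if weights.sum() == 0:
            weights = np.ones(6)
        weights = weights / weights.sum()
        n_sites = 2 if cfg.max_overlap_sites == 2 else int(
            rng.integers(2, cfg.max_overlap_sites + 1)
        )
        n_sites = min(n_sites, int((weights > 0).sum()))
        idx = rng.choice(6, size=max(2, n_sites), replace=False, p=weights)
        return frozenset(vocab.SITES[i] for i in idx)
    i = int(rng.choice(7, p=cond / cond.sum()))
    return frozenset({vocab.SITES[i]})


def _tri(rng, p_done: float, p_pos: float) -> str:
    if rng.random() >= p_done:
        return vocab.NOT_DONE
    return vocab.POSITIVE if rng.random() < p_pos else vocab.NEGATIVE


def _draw_ihc(
    reported: str, refined: str, cfg: GeneratorConfig,
    ttf1_free: float, p63_free: float, rng,
) -> dict[str, str]:
    """Stain tri-states consistent with the refinement rules.

    Re-classified cases have forced stain patterns; the free-draw rates are
    pre-solved so the configured marginal availability holds in expectation.
    """
    ihc = {s: vocab.NOT_DONE for s in vocab.STAINS}
    if reported == vocab.SUBTYPE_NSCLC:
        if refined == vocab.SUBTYPE_AC:
            ihc["TTF-1"] = vocab.POSITIVE
            if rng.random() < p63_free:
                ihc["p63"] = vocab.NEGATIVE
        elif refined == vocab.SUBTYPE_SCC:
            ihc["TTF-1"] = vocab.NEGATIVE
            ihc["p63"] = vocab.POSITIVE
        else:  # stays generic NSCLC
            if rng.random() < ttf1_free:
                if rng.random() < 0.5:
                    ihc["TTF-1"] = vocab.POSITIVE
                    ihc["p63"] = vocab.POSITIVE  # blocks the AC rule
                else:
                    ihc["TTF-1"] = vocab.NEGATIVE
                    if rng.random() < p63_free:
                        ihc["p63"] = vocab.NEGATIVE
            else:
                if rng.random() < p63_free:
                    ihc["p63"] = vocab.NEGATIVE
    elif reported == vocab.SUBTYPE_AC:
        ihc["TTF-1"] = _tri(rng, ttf1_free, 0.92)
        ihc["p63"] = _tri(rng, p63_free, 0.05)
    elif reported == vocab.SUBTYPE_SCC:
        ihc["TTF-1"] = _tri(rng, ttf1_free, 0.10)
        ihc["p63"] = _tri(rng, p63_free, 0.90)
    elif reported == vocab.SUBTYPE_SCLC:
        ihc["TTF-1"] = _tri(rng, ttf1_free, 0.85)
        ihc["p63"] = _tri(rng, p63_free, 0.10)
        ihc["neuroendocrine markers"] = _tri(rng, 25 / 28, 1.0)
    ihc["p40"] = _tri(rng, cfg.ihc_availability["p40"],
                      0.9 if refined == vocab.SUBTYPE_SCC else 0.05)
    return ihc


def _free_stain_rates(cfg: GeneratorConfig) -> tuple[float, float]:
    """Solve the free TTF-1/p63 availability so marginals match the config."""
    joint = np.asarray(cfg.subtype_site_joint, dtype=float)
    p_ref = joint.sum(axis=1)  # refined-subtype marginal (AC, SCC, SCLC, NSCLC)
    p_forced_ttf1 = p_ref[0] * cfg.reclass_rate_ac + \
        p_ref[1] * cfg.reclass_rate_scc
    tt = cfg.ihc_availability["TTF-1"]
    ttf1_free = min(1.0, max(0.0, (tt - p_forced_ttf1) / (1 - p_forced_ttf1)))
    # p63 is forced positive for re-classified SCC and for generic-NSCLC
    # cases drawn TTF-1 positive
    p_forced_p63 = p_ref[1] * cfg.reclass_rate_scc + \
        p_ref[3] * ttf1_free * 0.5
    pp = cfg.ihc_availability["p63"]
    p63_free = min(1.0, max(0.0, (pp - p_forced_p63) / (1 - p_forced_p63)))
    return ttf1_free, p63_free


def _draw_biomarkers(cfg: GeneratorConfig, year: int, rng) -> BiomarkerProfile:
    bc = cfg.biomarkers
    profile = BiomarkerProfile()
    if rng.random() >= bc.testing_rate(year):
        return profile
    if rng.random() < bc.availability["egfr"]:
        profile.egfr = vocab.POSITIVE if rng.random() < bc.positivity["egfr"] \
            else vocab.NEGATIVE
    if rng.random() < bc.availability["alk"]:
        status = vocab.POSITIVE if rng.random() < bc.positivity["alk"] \
            else vocab.NEGATIVE
        if rng.random() < bc.alk_fish_fraction:
            profile.alk_fish = status
        else:
            profile.alk_ihc = status
    if rng.random() < bc.availability["pdl1"]:
        b = int(rng.choice(3, p=np.asarray(bc.pdl1_bins)))
        if b == 0:
            profile.pdl1_tps = 0.0
        elif b == 1:
            profile.pdl1_tps = float(rng.integers(1, 50))
        else:
            profile.pdl1_tps = float(rng.integers(50, 101))
    if rng.random() < bc.availability["ras"]:
        profile.ras = vocab.POSITIVE if rng.random() < bc.positivity["ras"] \
            else vocab.NEGATIVE
    if rng.random() < bc.availability["braf_v600"]:
        profile.braf_v600 = vocab.POSITIVE \
            if rng.random() < bc.positivity["braf_v600"] else vocab.NEGATIVE
    if rng.random() < bc.availability["ros1"]:
        profile.ros1 = vocab.POSITIVE if rng.random() < bc.positivity["ros1"] \
            else vocab.NEGATIVE
    return profile


_CATEGORY_ORDER = vocab.CATEGORIES


def _draw_truth(
    case_id: str, patient_id: str, year: int, cfg: GeneratorConfig,
    ttf1_free: float, p63_free: float, marginal_site: np.ndarray, rng,
) -> TruthRecord:
    cat_p = np.array([cfg.category_mix[c] for c in _CATEGORY_ORDER])
    category = _CATEGORY_ORDER[int(rng.choice(len(_CATEGORY_ORDER), p=cat_p))]
    t = TruthRecord(
        case_id=case_id, patient_id=patient_id, accession_year=year,
        true_category=category,
    )
    t.true_site_set = _draw_site_set(marginal_site, cfg, rng) \
        if category != "probable metastasis" else frozenset()

    if category != "probable metastasis":
        return t

    sites_p = np.array([cfg.primary_site_mix[s] for s in vocab.PRIMARY_SITES])
    primary = vocab.PRIMARY_SITES[int(rng.choice(len(sites_p), p=sites_p))]
    t.true_primary_site = primary
    t.confirmed = bool(rng.random() < cfg.confirm_rate)

    joint = np.asarray(cfg.subtype_site_joint, dtype=float)
    if primary == "lung":
        p_ref = joint.sum(axis=1)
        k = int(rng.choice(4, p=p_ref / p_ref.sum()))
        refined = vocab.SUBTYPES[k]
        if refined == vocab.SUBTYPE_AC and rng.random() < cfg.reclass_rate_ac:
            reported = vocab.SUBTYPE_NSCLC
        elif refined == vocab.SUBTYPE_SCC and \
                rng.random() < cfg.reclass_rate_scc:
            reported = vocab.SUBTYPE_NSCLC
        else:
            reported = refined
        t.true_subtype_reported = reported
        t.true_subtype_refined = refined
        t.true_site_set = _draw_site_set(_site_distribution(joint[k]), cfg, rng)
        t.true_ihc = _draw_ihc(reported, refined, cfg, ttf1_free, p63_free, rng)
        t.true_biomarkers = _draw_biomarkers(cfg, year, rng)
        check = refine_subtype(reported, t.true_ihc["TTF-1"], t.true_ihc["p63"])
        assert check == refined, "generated stains contradict refinement rules"
    else:
        t.true_site_set = _draw_site_set(marginal_site, cfg, rng)
    return t


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[ReportRecord], list[TruthRecord]]:
    """Generate a synthetic corpus with one TruthRecord per report.

    Deterministic given ``config.seed``; empirical frequencies converge to
    the configured mixes as n_cases grows.  A ``multi_case_rate`` fraction of
    patients receive a second, later specimen so first-case retention can be
    exercised; the second specimen samples the same site set with probability
    ``repeat_site_concordance``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ttf1_free, p63_free = _free_stain_rates(config)
    joint = np.asarray(config.subtype_site_joint, dtype=float)
    marginal_site = _site_distribution(joint.sum(axis=0))

    n_cases = int(config.n_cases)
    n_patients = max(1, round(n_cases / (1 + config.multi_case_rate)))
    n_second = n_cases - n_patients
    y0, y1 = config.year_range

    # patient-level first cases
    firsts = []
    for i in range(n_patients):
        pid = f"P{i + 1:06d}"
        year = int(rng.integers(y0, y1 + 1))
        firsts.append((pid, year))

    second_of = (
        rng.choice(n_patients, size=n_second, replace=False)
        if n_second else np.array([], dtype=int)
    )

    # draw truths for first cases (case ids assigned after ordering)
    truths: list[TruthRecord] = []
    for i, (pid, year) in enumerate(firsts):
        t = _draw_truth("", pid, year, config, ttf1_free, p63_free,
                        marginal_site, rng)
        truths.append(t)

    seconds: list[TruthRecord] = []
    for j in sorted(int(x) for x in second_of):
        base = truths[j]
        year2 = int(rng.integers(base.accession_year, y1 + 1))
        t2 = TruthRecord(
            case_id="", patient_id=base.patient_id, accession_year=year2,
            true_category=base.true_category,
            true_primary_site=base.true_primary_site,
            true_subtype_reported=base.true_subtype_reported,
            true_subtype_refined=base.true_subtype_refined,
            true_site_set=base.true_site_set,
            true_ihc=dict(base.true_ihc),
            true_biomarkers=replace(base.true_biomarkers),
            confirmed=base.confirmed,
        )
        if base.true_category == "probable metastasis" and \
                rng.random() >= config.repeat_site_concordance:
            if base.true_primary_site == "lung":
                k = vocab.SUBTYPES.index(base.true_subtype_refined)
                cond = _site_distribution(joint[k])
            else:
                cond = marginal_site
            t2.true_site_set = _draw_site_set(cond, config, rng)
        seconds.append(t2)

    # accession ordering: by year, first specimens before second ones
    ordered = sorted(
        [(t, 0) for t in truths] + [(t, 1) for t in seconds],
        key=lambda x: (x[0].accession_year, x[1], x[0].patient_id),
    )
    reports: list[ReportRecord] = []
    out_truths: list[TruthRecord] = []
    for n, (t, _) in enumerate(ordered, 1):
        t.case_id = f"C{n:07d}"
        text = render_report(t, noise=config.lexical_noise, rng=rng)
        reports.append(
            ReportRecord(t.case_id, t.patient_id, t.accession_year, text)
        )
        out_truths.append(t)
    return reports, out_truths
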