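"""Cohort construction and tabulation.

Builds the patient-level cohort (first case per patient), the site
co-occurrence overlap matrix with its Pure/Mixed summaries, lesion- and
patient-level subtype-by-site tables, conditional distributions, and the
biomarker-by-subtype / biomarker-by-site tables.

"Lesion" here means a (patient, distinct site code) pair: a patient whose
report carries two site codes contributes one lesion at each, so lesions
always number at least as many as patients.  A patient with no named
lobe/cerebellum code contributes a single lesion to the merged
"unknown/other" column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import vocab
from .records import CaseLabel, InputError


@dataclass
class ContingencyTable:
    """Labelled non-negative integer matrix with margins."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        arr = df.to_numpy()
        if (arr < 0).any():
            raise InputError("contingency table entries must be non-negative")
        self.data = df.astype(int)

    @property
    def row_margins(self) -> pd.Series:
        return self.data.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        return self.data.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.data.to_numpy().sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def drop_columns(self, labels: list[str]) -> "ContingencyTable":
        missing = [x for x in labels if x not in self.data.columns]
        if missing:
            raise InputError(f"unknown column label(s): {missing}")
        kept = self.data.drop(columns=list(labels))
        if kept.shape[1] == 0:
            raise InputError("cannot drop every column of a contingency table")
        return ContingencyTable(kept)

    def to_csv(self, path: str | Path, sidecar: dict | None = None) -> None:
        path = Path(path)
        self.data.to_csv(path)
        meta = {
            "row_margins": self.row_margins.to_dict(),
            "col_margins": self.col_margins.to_dict(),
            "total": self.total,
        }
        if sidecar:
            meta.update(sidecar)
        path.with_suffix(".json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )


def simplify_table(table: ContingencyTable, drop_columns: list[str]) -> ContingencyTable:
    """Drop named columns and recompute margins."""
    return table.drop_columns(drop_columns)


class OverlapMatrix:
    """Symmetric site x site patient-count matrix with derived summaries.

    Cell (i, i) counts patients whose site set contains i; cell (i, j)
    counts patients whose set contains both i and j.  Derived rows:
    ``sum`` (row totals), ``diagonal``, ``off_diagonal`` (sum - diagonal),
    ``pure`` (patients with exactly {i}), and the scalar ``mixed`` (patients
    with more than one site).  When no patient carries more than two sites,
    pure = diagonal - off_diagonal holds exactly.
    """

    def __init__(self, matrix: pd.DataFrame, pure: pd.Series, mixed: int):
        self.matrix = matrix
        self.pure = pure
        self.mixed = int(mixed)

    @classmethod
    def from_patients(cls, site_sets: list[frozenset[str]]) -> "OverlapMatrix":
        sites = vocab.SITES
        m = pd.DataFrame(0, index=sites, columns=sites)
        pure = pd.Series(0, index=sites)
        mixed = 0
        for ss in site_sets:
            if not ss:
                raise InputError("every patient must have a non-empty site set")
            bad = ss - set(sites)
            if bad:
                raise InputError(f"unknown site code(s): {sorted(bad)}")
            codes = sorted(ss, key=sites.index)
            for i, a in enumerate(codes):
                for b in codes[i:]:
                    m.loc[a, b] += 1
                    if a != b:
                        m.loc[b, a] += 1
            if len(codes) == 1:
                pure[codes[0]] += 1
            else:
                mixed += 1
        return cls(m, pure, mixed)

    @classmethod
    def from_matrix(cls, matrix: pd.DataFrame) -> "OverlapMatrix":
        """Recover the summaries from a bare co-occurrence matrix.

        Valid when no patient carries more than two site codes: then
        pure_i = diagonal_i - off_diagonal_i and each mixed patient is
        counted twice off the diagonal.
        """
        m = pd.DataFrame(matrix)
        if not m.index.equals(m.columns):
            raise InputError("overlap matrix must have matching row/col labels")
        if not np.array_equal(m.to_numpy(), m.to_numpy().T):
            raise InputError("overlap matrix must be symmetric")
        diag = pd.Series(np.diag(m.to_numpy()), index=m.index)
        off = m.sum(axis=1) - diag
        pure = diag - off
        if (pure < 0).any():
            raise InputError(
                "negative pure count: matrix is not consistent with "
                "at most two sites per patient"
            )
        mixed = int(off.sum()) // 2
        return cls(m, pure, mixed)

    @property
    def sum_row(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    @property
    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.matrix.to_numpy()), index=self.matrix.index)

    @property
    def off_diagonal(self) -> pd.Series:
        return self.sum_row - self.diagonal

    @property
    def n_patients(self) -> int:
        return int(self.pure.sum()) + self.mixed

    def summary_frame(self) -> pd.DataFrame:
        """The matrix with the Sum/Diagonal/Off-diagonal/Pure summary rows."""
        out = self.matrix.copy()
        out.loc["sum"] = self.sum_row
        out.loc["diagonal"] = self.diagonal
        out.loc["off-diagonal"] = self.off_diagonal
        out.loc["pure"] = self.pure
        return out


def first_case_per_patient(cases: list[CaseLabel]) -> list[CaseLabel]:
    """Keep each patient's earliest case (accession year, then case id)."""
    for c in cases:
        if c.accession_year is None:
            raise InputError(f"case {c.case_id} lacks an ordering key")
    best: dict[str, CaseLabel] = {}
    for c in sorted(cases, key=lambda c: (c.accession_year, c.case_id)):
        best.setdefault(c.patient_id, c)
    return [best[p] for p in sorted(best, key=lambda p: (best[p].accession_year,
                                                         best[p].case_id))]


def overlap_matrix(patients: list[CaseLabel]) -> OverlapMatrix:
    return OverlapMatrix.from_patients([p.site_set for p in patients])


_UO = "unknown/other"


def _lesion_sites(site_set: frozenset[str]) -> list[str]:
    """Sites a patient contributes lesions to, with the merged fallback.

    One lesion per named site in the set; a patient with no named site
    contributes exactly one lesion to the merged unknown/other column.
    """
    named = [s for s in vocab.NAMED_SITES if s in site_set]
    return named if named else [_UO]


def site_by_subtype(
    patients: list[CaseLabel], *, subtype_attr: str = "refined_subtype"
) -> tuple[ContingencyTable, pd.Series]:
    """Lesion counts by subtype and site, plus patients per subtype."""
    cols = vocab.NAMED_SITES + [_UO]
    counts = pd.DataFrame(0, index=vocab.SUBTYPES, columns=cols)
    npat = pd.Series(0, index=vocab.SUBTYPES, name="patients")
    for p in patients:
        subtype = getattr(p, subtype_attr)
        if subtype not in vocab.SUBTYPES:
            continue
        npat[subtype] += 1
        for s in _lesion_sites(p.site_set):
            counts.loc[subtype, s] += 1
    return ContingencyTable(counts), npat


def single_site_subset(patients: list[CaseLabel]) -> list[CaseLabel]:
    """Patients with exactly one site code, in a named lobe/cerebellum."""
    return [
        p for p in patients
        if len(p.site_set) == 1 and next(iter(p.site_set)) in vocab.NAMED_SITES
    ]


def conditional_distributions(table: ContingencyTable, axis: str) -> pd.DataFrame:
    """Proportions conditional on one axis.

    ``axis="columns"`` answers: given the site, how likely is each subtype
    (each column sums to 1).  ``axis="rows"``: given the subtype, how likely
    is each site (each row sums to 1).  Slices with a zero margin are
    returned as missing.
    """
    df = table.data.astype(float)
    if axis in ("columns", "site"):
        margins = df.sum(axis=0)
        out = df.div(margins.where(margins > 0), axis=1)
    elif axis in ("rows", "subtype"):
        margins = df.sum(axis=1)
        out = df.div(margins.where(margins > 0), axis=0)
    else:
        raise InputError(f"axis must be 'rows' or 'columns', got {axis!r}")
    return out


_MARKER_STATUS_ROWS = {
    "egfr": ["negative", "positive"],
    "alk": ["negative", "positive"],
    "ras": ["negative", "positive"],
    "braf_v600": ["negative", "positive"],
    "pdl1": ["negative", "low-positive", "positive"],
}


def _marker_status(p: CaseLabel, marker: str) -> str:
    if marker == "pdl1":
        return p.biomarkers.pdl1_bin
    if marker == "alk":
        return p.biomarkers.alk
    return getattr(p.biomarkers, marker)


def biomarker_tables(
    patients: list[CaseLabel],
    markers: tuple[str, ...] = ("egfr", "alk", "pdl1", "ras", "braf_v600"),
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Biomarker status by subtype (patients) and by site (lesions).

    Site attribution follows lesion semantics (one count per named site in
    the patient's site set); unknown/other sites are excluded from the site
    tables.  Markers with no tested patient yield empty tables.
    """
    by_subtype: dict[str, pd.DataFrame] = {}
    by_site: dict[str, pd.DataFrame] = {}
    for marker in markers:
        statuses = _MARKER_STATUS_ROWS[marker]
        rows = ["adequate"] + statuses
        t_sub = pd.DataFrame(0, index=rows, columns=vocab.SUBTYPES)
        t_site = pd.DataFrame(0, index=rows, columns=vocab.NAMED_SITES)
        for p in patients:
            status = _marker_status(p, marker)
            if status == vocab.NOT_DONE or p.refined_subtype not in vocab.SUBTYPES:
                continue
            t_sub.loc["adequate", p.refined_subtype] += 1
            t_sub.loc[status, p.refined_subtype] += 1
            for s in p.site_set & set(vocab.NAMED_SITES):
                t_site.loc["adequate", s] += 1
                t_site.loc[status, s] += 1
        if int(t_sub.loc["adequate"].sum()) == 0:
            t_sub = t_sub.iloc[0:0]
            t_site = t_site.iloc[0:0]
        by_subtype[marker] = t_sub
        by_site[marker] = t_site
    return by_subtype, by_site
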