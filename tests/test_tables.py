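"""Cohort tabulation: overlap matrix, lesion/patient tables, biomarkers."""

import numpy as np
import pandas as pd
import pytest

from lungbm import reference, vocab
from lungbm.records import BiomarkerProfile, CaseLabel, InputError
from lungbm.tables import (
    ContingencyTable, OverlapMatrix, biomarker_tables,
    conditional_distributions, first_case_per_patient, overlap_matrix,
    simplify_table, single_site_subset, site_by_subtype,
)


def _case(cid, pid, year=2015, sites=("frontal",), subtype=vocab.SUBTYPE_AC,
          **bio):
    return CaseLabel(
        case_id=cid, patient_id=pid, accession_year=year,
        category="probable metastasis", primary_site="lung",
        subtype=subtype, refined_subtype=subtype,
        site_set=frozenset(sites),
        biomarkers=BiomarkerProfile(**bio),
    )


# --- first case per patient -----------------------------------------------

def test_first_case_retained():
    cases = [_case("c2", "p1", year=2016), _case("c1", "p1", year=2014),
             _case("c3", "p2", year=2015)]
    kept = first_case_per_patient(cases)
    assert {c.case_id for c in kept} == {"c1", "c3"}


def test_first_case_identity_when_single():
    cases = [_case(f"c{i}", f"p{i}") for i in range(5)]
    assert len(first_case_per_patient(cases)) == 5


def test_first_case_counts():
    cases = [_case(f"c{i}", f"p{i}") for i in range(10)]
    cases += [_case(f"d{i}", f"p{i}", year=2019) for i in range(3)]
    assert len(first_case_per_patient(cases)) == 10


# --- overlap matrix -------------------------------------------------------

def test_overlap_matrix_hand_count():
    om = OverlapMatrix.from_patients(
        [frozenset({"frontal"}), frozenset({"frontal"}),
         frozenset({"frontal", "parietal"})]
    )
    assert om.diagonal["frontal"] == 3
    assert om.diagonal["parietal"] == 1
    assert om.matrix.loc["frontal", "parietal"] == 1
    assert om.pure["frontal"] == 2
    assert om.pure["parietal"] == 0
    assert om.mixed == 1
    assert om.n_patients == 3


def test_overlap_matrix_symmetry():
    rng = np.random.default_rng(0)
    sets = []
    for _ in range(50):
        k = rng.integers(1, 3)
        sets.append(frozenset(
            rng.choice(vocab.SITES[:6], size=k, replace=False)
        ))
    om = OverlapMatrix.from_patients(sets)
    assert np.array_equal(om.matrix.to_numpy(), om.matrix.to_numpy().T)


def test_pure_and_mixed_recovered_from_reference_matrix():
    """From the bare 7x7 co-occurrence matrix alone, the two-site identity
    recovers pure = (79, 31, 14, 22, 49, 2, 1) and 36 mixed patients."""
    om = OverlapMatrix.from_matrix(reference.overlap_matrix())
    assert list(om.pure) == [79, 31, 14, 22, 49, 2, 1]
    assert om.mixed == 36
    assert om.n_patients == 234
    assert list(om.diagonal) == [88, 48, 20, 35, 61, 17, 1]
    assert list(om.off_diagonal) == [9, 17, 6, 13, 12, 15, 0]


def test_pure_identity_holds_for_two_site_cohorts():
    rng = np.random.default_rng(1)
    sets = []
    for _ in range(200):
        if rng.random() < 0.2:
            sets.append(frozenset(
                rng.choice(vocab.SITES[:6], size=2, replace=False)
            ))
        else:
            sets.append(frozenset({str(rng.choice(vocab.SITES[:6]))}))
    om = OverlapMatrix.from_patients(sets)
    rebuilt = OverlapMatrix.from_matrix(om.matrix)
    assert (om.pure == rebuilt.pure).all()
    assert om.mixed == rebuilt.mixed


def test_overlap_matrix_rejects_empty_site_set():
    with pytest.raises(InputError):
        OverlapMatrix.from_patients([frozenset()])


# --- subtype x site tables ------------------------------------------------

def test_site_by_subtype_lesion_semantics():
    patients = [_case("c1", "p1", sites=("frontal", "parietal"))]
    table, npat = site_by_subtype(patients)
    row = table.data.loc[vocab.SUBTYPE_AC]
    assert list(row) == [1, 1, 0, 0, 0, 0]
    assert table.row_margins[vocab.SUBTYPE_AC] == 2  # two lesions
    assert npat[vocab.SUBTYPE_AC] == 1               # one patient


def test_site_by_subtype_unknown_other_counts_once():
    patients = [
        _case("c1", "p1", sites=("unknown",)),
        _case("c2", "p2", sites=("other",)),
        _case("c3", "p3", sites=("frontal", "other")),
    ]
    table, _ = site_by_subtype(patients)
    # named site suppresses the merged column; pure other/unknown count once
    assert table.data.loc[vocab.SUBTYPE_AC, "unknown/other"] == 2
    assert table.data.loc[vocab.SUBTYPE_AC, "frontal"] == 1
    assert table.total == 3


def test_site_by_subtype_empty_cohort():
    table, npat = site_by_subtype([])
    assert table.total == 0
    assert npat.sum() == 0


def test_lesion_conservation(zero_noise_corpus):
    """Total lesions equal the summed named-site counts plus fallbacks."""
    from lungbm.classifier import classify_corpus

    _, reports, _ = zero_noise_corpus
    labels = [c for c in classify_corpus(reports)
              if c.primary_site == "lung"]
    table, npat = site_by_subtype(labels, subtype_attr="subtype")
    named = set(vocab.NAMED_SITES)
    expected = sum(
        max(1, len(c.site_set & named)) for c in labels
        if c.subtype in vocab.SUBTYPES
    )
    assert table.total == expected
    assert npat.sum() <= table.total  # patients never exceed lesions


# --- simplification -------------------------------------------------------

def test_simplify_reference_table_totals_252():
    lesions = ContingencyTable(reference.lesion_table())
    assert lesions.total == 255
    simplified = simplify_table(lesions, ["unknown/other"])
    assert simplified.total == 252
    assert simplified.shape == (4, 5)
    assert int(simplified.data.size) == 20


def test_simplify_nothing_is_identity():
    t = ContingencyTable(reference.lesion_table())
    assert simplify_table(t, []).data.equals(t.data)


def test_simplify_rejects_unknown_and_total_drop():
    t = ContingencyTable(reference.lesion_table())
    with pytest.raises(InputError):
        simplify_table(t, ["nonexistent"])
    with pytest.raises(InputError):
        simplify_table(t, list(t.data.columns))


def test_margin_commutativity():
    t = ContingencyTable(reference.lesion_table())
    s = simplify_table(t, ["unknown/other"])
    assert (s.row_margins == s.data.sum(axis=1)).all()
    assert (s.col_margins == t.col_margins.drop("unknown/other")).all()


# --- single-site subset ---------------------------------------------------

def test_single_site_subset_rules():
    patients = [
        _case("c1", "p1", sites=("frontal", "parietal")),  # excluded: two
        _case("c2", "p2", sites=("frontal",)),             # included
        _case("c3", "p3", sites=("other",)),               # excluded: other
        _case("c4", "p4", sites=("unknown",)),             # excluded
    ]
    kept = single_site_subset(patients)
    assert [c.case_id for c in kept] == ["c2"]


def test_single_site_subset_reference_count():
    """The reference overlap matrix implies 195 single-lesion patients in
    named sites (198 pure minus pure-other and pure-unknown)."""
    om = OverlapMatrix.from_matrix(reference.overlap_matrix())
    named_pure = int(om.pure[vocab.NAMED_SITES].sum())
    assert named_pure == 195


# --- conditional distributions --------------------------------------------

def test_conditional_on_site_cerebellum_share():
    t = ContingencyTable(reference.simplified_lesion_table())
    cond = conditional_distributions(t, "columns")
    assert cond.loc[vocab.SUBTYPE_AC, "cerebellum"] == pytest.approx(37 / 61)
    assert np.allclose(cond.sum(axis=0), 1.0)


def test_conditional_slices_sum_to_one():
    t = ContingencyTable(pd.DataFrame([[5, 5], [5, 5]]))
    cond = conditional_distributions(t, "rows")
    assert (cond.to_numpy() == 0.5).all()


def test_conditional_zero_margin_missing():
    t = ContingencyTable(pd.DataFrame([[2, 0], [3, 0]]))
    cond = conditional_distributions(t, "columns")
    assert cond.iloc[:, 1].isna().all()


# --- biomarker tables -----------------------------------------------------

def test_biomarker_table_single_patient():
    patients = [_case("c1", "p1", sites=("frontal",), egfr=vocab.POSITIVE)]
    by_subtype, by_site = biomarker_tables(patients)
    assert by_subtype["egfr"].loc["positive", vocab.SUBTYPE_AC] == 1
    assert by_subtype["egfr"].loc["adequate", vocab.SUBTYPE_AC] == 1
    assert by_site["egfr"].loc["positive", "frontal"] == 1


def test_biomarker_site_excludes_unknown_other():
    patients = [_case("c1", "p1", sites=("other",), egfr=vocab.NEGATIVE)]
    by_subtype, by_site = biomarker_tables(patients)
    assert by_subtype["egfr"].loc["adequate"].sum() == 1
    assert by_site["egfr"].to_numpy().sum() == 0


def test_biomarker_all_not_done_gives_empty_tables():
    patients = [_case("c1", "p1")]
    by_subtype, by_site = biomarker_tables(patients, markers=("egfr",))
    assert by_subtype["egfr"].empty
    assert by_site["egfr"].empty


def test_reference_biomarker_fixture_margins():
    """The bundled biomarker tables reproduce their own printed margins."""
    sub = reference.biomarker_subtype_tables()
    assert list(sub["egfr"].loc["adequate"]) == [48, 7, 9, 1]
    assert int(sub["egfr"].loc["adequate"].sum()) == 65
    site = reference.biomarker_site_tables()
    assert int(site["pdl1"].loc["adequate"].sum()) == 87
    assert list(site["pdl1"].loc["negative"]) == [6, 9, 5, 5, 6]
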