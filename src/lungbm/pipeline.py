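"""End-to-end orchestration: generate -> classify -> refine -> tabulate ->
test -> visualize, with a reproducible manifest.

Every stage logs its record count so the cohort funnel (all cases ->
probable metastases -> review-confirmed -> first case per patient -> lung
cohort) is inspectable, mirroring the flow of the emulated study.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, exact, vocab
from .classifier import audit_agreement, classify_corpus
from .ihc import annotate_case
from .lexicon import MatchLexicon, default_lexicon
from .records import (
    CaseLabel, ReportRecord, TruthRecord,
    read_corpus, write_corpus, write_labels, write_truth,
)
from .synthetic import GeneratorConfig, generate_corpus
from .tables import (
    OverlapMatrix, biomarker_tables, conditional_distributions,
    first_case_per_patient, overlap_matrix, simplify_table, single_site_subset,
    site_by_subtype,
)

log = logging.getLogger("lungbm")


@dataclass
class StatsOptions:
    method: str = "auto"        # auto | exact | mc
    reps: int = 200_000
    seed: int = 0
    alpha: float = 0.05


@dataclass
class RunConfig:
    output_dir: str | Path = "lungbm_run"
    corpus_path: str | Path | None = None   # None -> generate synthetically
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    lexicon_path: str | Path | None = None
    stats: StatsOptions = field(default_factory=StatsOptions)
    make_heatmap_image: bool = True

    def config_hash(self) -> str:
        payload = {
            "generator": _jsonable(self.generator),
            "stats": _jsonable(self.stats),
            "corpus_path": str(self.corpus_path) if self.corpus_path else None,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k))
                for k in obj.__dataclass_fields__}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run the full report-to-statistics pipeline; returns the manifest.

    Re-running with the same configuration reproduces every text output
    byte-identically (the rendered heatmap image is excluded from that
    guarantee).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.generator.seed,
        "stats_seed": config.stats.seed,
        "counts": {},
        "stages": [],
        "notes": [],
    }

    def stage(name: str, count: int) -> None:
        manifest["counts"][name] = count
        manifest["stages"].append(name)
        log.info("stage %-22s n=%d", name, count)

    lexicon = (
        MatchLexicon.from_file(config.lexicon_path)
        if config.lexicon_path else default_lexicon()
    )

    # --- corpus -----------------------------------------------------------
    truths: list[TruthRecord] | None = None
    if config.corpus_path is not None:
        reports = read_corpus(config.corpus_path)
    else:
        reports, truths = generate_corpus(config.generator)
        write_corpus(reports, out / "corpus.tsv")
        write_truth(truths, out / "truth.tsv")
    stage("corpus", len(reports))

    # --- classification ---------------------------------------------------
    text_of = {r.case_id: r.text for r in reports}
    labels = []
    for rep in reports:
        try:
            labels.extend(classify_corpus([rep], lexicon))
            annotate_case(labels[-1], text_of[rep.case_id])
        except Exception as e:  # abort with the stage and record id
            raise StageError("classify", f"case {rep.case_id}: {e}") from e
    write_labels(labels, out / "labels.tsv")
    stage("classified", len(labels))

    if truths is not None:
        agreement = audit_agreement(labels, truths)
        pd.Series(agreement.accuracy).to_csv(out / "audit_accuracy.csv",
                                             header=["accuracy"])
        agreement.mismatches.to_csv(out / "audit_mismatches.csv", index=False)

    # --- cohort funnel ----------------------------------------------------
    mets = [l for l in labels if l.category == "probable metastasis"
            and l.primary_site not in (vocab.PRIMARY_AMBIGUOUS,)]
    stage("probable_metastasis", len(mets))

    if truths is not None:
        confirmed_ids = {t.case_id for t in truths if t.confirmed}
        mets = [l for l in mets if l.case_id in confirmed_ids]
    stage("review_confirmed", len(mets))

    patients = first_case_per_patient(mets)
    stage("first_case_per_patient", len(patients))

    lung = [p for p in patients if p.primary_site == "lung"]
    stage("lung_cohort", len(lung))

    # --- tabulation -------------------------------------------------------
    if not lung:
        manifest["notes"].append(
            "no lung metastases in cohort: tables empty, statistics skipped"
        )
        _write_manifest(manifest, out)
        return manifest

    om = overlap_matrix(lung)
    om.summary_frame().to_csv(out / "table_overlap.csv")
    manifest["counts"]["mixed_patients"] = om.mixed

    lesions, npat = site_by_subtype(lung)
    t2 = lesions.data.copy()
    t2["lesions"] = lesions.row_margins
    t2["patients"] = npat
    t2.to_csv(out / "table_subtype_site.csv")

    simplified = simplify_table(lesions, ["unknown/other"])
    simplified.data.to_csv(out / "table_subtype_site_simplified.csv")

    conditional_distributions(simplified, "columns").to_csv(
        out / "dist_subtype_given_site.csv"
    )
    conditional_distributions(simplified, "rows").to_csv(
        out / "dist_site_given_subtype.csv"
    )

    single = single_site_subset(lung)
    stage("single_lesion_subset", len(single))
    single_tab, _ = site_by_subtype(single)
    single_tab.data.to_csv(out / "table_single_lesion.csv")

    by_subtype, by_site = biomarker_tables(lung)
    for marker, tab in by_subtype.items():
        tab.to_csv(out / f"table_biomarker_{marker}_subtype.csv")
    for marker, tab in by_site.items():
        tab.to_csv(out / f"table_biomarker_{marker}_site.csv")

    # --- statistics -------------------------------------------------------
    stats: dict = {}
    simp = simplified.data.to_numpy()
    if simp.sum() > 0 and min(simplified.shape) >= 2:
        res = _run_test(simp, config.stats)
        stats["subtype_site"] = _stats_entry(res)
        pairs = exact.all_pairs_2x2(simplified.data)
        pairs.to_csv(out / "pairwise_pvalues.csv")
        binned = pairs.map(exact.bin_pvalue)
        binned.to_csv(out / "pairwise_pvalue_bins.csv")
        row_order, col_order = exact.heatmap_order(pairs)
        ordered = pairs.loc[row_order, col_order]
        ordered.to_csv(out / "heatmap_matrix.csv")
        if config.make_heatmap_image:
            _render_heatmap(ordered, out / "heatmap.png")
    else:
        manifest["notes"].append("subtype-site table degenerate; test skipped")

    for marker, tab in by_subtype.items():
        body = tab.drop(index=["adequate"], errors="ignore")
        body = body.drop(columns=[vocab.SUBTYPE_SCLC], errors="ignore")
        body = body.loc[body.sum(axis=1) > 0, body.sum(axis=0) > 0]
        if body.shape[0] >= 2 and body.shape[1] >= 2:
            res = _run_test(body.to_numpy(), config.stats)
            stats[f"{marker}_subtype"] = _stats_entry(res)
    for marker, tab in by_site.items():
        body = tab.drop(index=["adequate"], errors="ignore")
        body = body.loc[body.sum(axis=1) > 0, body.sum(axis=0) > 0]
        if body.shape[0] >= 2 and body.shape[1] >= 2:
            res = _run_test(body.to_numpy(), config.stats)
            stats[f"{marker}_site"] = _stats_entry(res)

    (out / "stats.json").write_text(
        json.dumps(stats, indent=2, sort_keys=True) + "\n"
    )
    manifest["stats"] = stats
    _write_manifest(manifest, out)
    return manifest


def _run_test(table: np.ndarray, opts: StatsOptions) -> exact.ExactTestResult:
    if opts.method == "exact":
        return exact.fisher_rxc_exact(table)
    if opts.method == "mc":
        return exact.fisher_rxc_mc(table, reps=opts.reps, seed=opts.seed)
    return exact.fisher_rxc_auto(table, reps=opts.reps, seed=opts.seed)


def _stats_entry(res: exact.ExactTestResult) -> dict:
    entry = {"p": res.p, "method": res.method}
    if res.mc_reps is not None:
        entry["mc_reps"] = res.mc_reps
        entry["mc_se"] = res.mc_se
    return entry


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def _render_heatmap(pmat: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    cmap = ListedColormap(
        [exact.BIN_COLOURS[c] for _, _, c in exact.PVALUE_BINS]
    )
    norm = BoundaryNorm([0, 0.05, 0.1, 0.2, 0.4, 1.0], cmap.N)
    fig, ax = plt.subplots(
        figsize=(1.2 + 0.6 * pmat.shape[1], 1.2 + 0.5 * pmat.shape[0])
    )
    im = ax.imshow(pmat.to_numpy(), cmap=cmap, norm=norm, aspect="auto")
    ax.set_xticks(range(pmat.shape[1]), pmat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(pmat.shape[0]), pmat.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Fisher exact p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
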