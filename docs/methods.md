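# Methods

This note documents the models and procedures `lungbm` implements, the
choices made where the design was genuinely open, and what the synthetic
tests do and do not establish.

## Cohort design being emulated

The pipeline targets a retrospective neuropathology-archive design: all
brain surgical specimens over a ten-year window are coded by a hierarchical
free-text string-matching algorithm; algorithm-flagged probable metastases
are review-confirmed; one case per patient is retained (the earliest); the
lung-primary cohort is subtyped, refined with immunostains, and tabulated by
neuroanatomical site; sparse tables are tested with Fisher's exact test.
The emulated cohort has 234 lung-metastasis patients, 36 of whom carry two
location codes, yielding 255 lesions (252 after dropping the three patients
whose only code is unknown/other).

"Lesion" is operationalized as a patient × distinct-site-code pair.
Repeated sampling of the same site collapses to one lesion; a patient with
no named lobe/cerebellum code contributes exactly one lesion to the merged
unknown/other column. That rule is forced by the reference tabulation's own
arithmetic: its unknown/other column totals 3 — precisely the patients with
*only* unknown/other codes — while "other" codes co-occurring with named
sites are dropped, giving 255 = Σ|site set ∩ named sites| + 3.

## Classification

Matching is case-insensitive regex/stem matching over normalized text
(lowercased, punctuation collapsed); no statistical NLP. Rules live in a
plain-text lexicon (`src/lungbm/data/lexicon.tsv`): axis, priority, pattern,
label. Within an axis the highest-priority matching rule wins, which
implements both the category hierarchy (the six groupings are listed in
ascending order, so a report matching "metastatic … melanoma" and
"hematoma" codes as probable metastasis) and subtype supersession
(adenocarcinoma, squamous and small cell each outrank the generic non-small
cell pattern). The small cell pattern uses a negative lookbehind so
"non-small cell" never fires it.

Open choices made here:

- **Negation scope.** A sentence containing a negation cue ("no", "not",
  "negative for", "without"…) is ignored entirely for
  category/subtype/site/primary matching. This is the minimal rule that
  makes negated distractors ("Negative for small cell carcinoma.")
  harmless; "not otherwise specified" is canonicalized to "NOS" first so
  generic NSCLC phrasing survives.
- **Conflicting organ keywords** (two distinct primary-site labels) yield
  "multiple/ambiguous" and exclusion from the lung cohort, mirroring the
  restriction to metastases with one primary site.
- **Location vocabulary** is closed at seven codes: the five named regions,
  "other" (brainstem, thalamus, dura, …) and the no-match fallback
  "unknown", which never co-occurs with a named site.

## Immunostain refinement

Only reported generic NSCLC is eligible: TTF-1 positive with p63 **not**
positive → adenocarcinoma; TTF-1 negative with p63 positive → squamous cell
carcinoma; anything else stays NSCLC-NOS. "Not positive" is interpreted as
*negative or not performed*: with p63 done in only 46 of 234 patients, 37 of
72 generic-NSCLC cases could only have been re-classified as adenocarcinoma
if an absent p63 counts against squamous differentiation. The rule is
idempotent and never fires on a missing TTF-1. p40 is parsed but excluded
from refinement (performed in ~5 of 234). For tabulation, ALK status is the
union of IHC and FISH with IHC taking precedence when both are present (the
reference tabulation prints a single ALK row).

PD-L1 tumour proportion scores bin as <1 % negative, 1–49 % low-positive,
≥50 % positive; the bin is a pure function of the parsed TPS, boundary-tested
at 0.9/1.0/49.9/50.0.

## Exact inference

All tests use probability ordering ("as or more extreme" by table
probability) with a relative tie tolerance of 1e-7, matching the standard R
implementation's two-sided convention — the convention under which the
reference p-values were produced.

- **2×2**: direct scan of the hypergeometric support.
- **r×c (Freeman–Halton)**: enumeration of all margin-compatible tables,
  organized as a network over states (column index, remaining row margins).
  A first pass memoizes, per state, the total null probability of its
  completions and the extreme attainable log-probabilities; a second
  depth-first pass then adds whole subtrees that are uniformly at or beyond
  the observed probability and prunes subtrees that cannot reach it. The
  3×5 PD-L1 table resolves in ~1,000 states. A node budget (default 5×10⁶
  allocation edges) guards infeasible inputs with an explicit refusal
  directing callers to the Monte-Carlo estimator.
- **Fixed-margin Monte Carlo**: tables sampled from the null multivariate
  hypergeometric distribution by sequential conditional (cell-by-cell
  hypergeometric) sampling, vectorized across replicates; the estimate uses
  the add-one correction p̂ = (1 + #extreme)/(reps + 1), so p̂ > 0 always,
  with binomial standard error reported. The 4×5 subtype-by-site table
  (n = 252) overflows practical enumeration — including the R reference
  implementation's workspace — so its p-value is quoted as a Monte-Carlo
  estimate with its SE.
- **Post-hoc decomposition**: every row-pair × column-pair 2×2 sub-table
  (60 for a 4×5 input), binned for display as
  [0, 0.05) red, [0.05, 0.1) pink, [0.1, 0.2) white, [0.2, 0.4) light blue,
  [0.4, 1] dark blue, and ordered by complete-linkage hierarchical
  clustering on Euclidean distances with label-sorted input for
  deterministic tie-breaking. An all-zero 2×2 sub-table (possible in small
  synthetic cohorts) is reported as p = 1. No multiple-testing correction
  is applied anywhere, by design of the emulated analysis; the 60 pairwise
  p-values are descriptive.

## Synthetic-data generator

The generator's defaults are the emulated cohort's own frequencies; they
are study conditions, not tuning knobs:

| parameter | default | source/rationale |
|---|---|---|
| category mix | metastasis 854/4625, unclassified 69/4625, rest split over tumour/vascular/misc groupings | archive funnel shape; non-metastasis shares are plausible fillers |
| review-confirmation rate | 538/854 | emulates the pathologist report review |
| lung fraction of metastases | 234/511 | cohort value |
| non-lung primary mix | breast 30 %, melanoma 22 %, colorectal 16 %, renal 10 %, other 22 % of the remainder | not stated for the cohort; typical metastasis epidemiology |
| subtype × site joint | 255-lesion tabulation proportions | cohort value |
| two-site overlap rate | 36/234 | cohort value; overlaps have exactly 2 sites by default (the Pure = Diagonal − Off-diagonal identity holds only then; ≥3 sites available for stress tests) |
| repeat-specimen rate / site concordance | 5 % of patients, 6/8 | cohort had 8/234 two-specimen patients, 6 concordant |
| TTF-1 / p63 / p40 availability | 206, 46, 5 per 234 | cohort values |
| re-classification rates | 37/152 of refined AC and 4/23 of refined SCC were reported as generic NSCLC | cohort values |
| biomarker testing by year band | 0 in 2011–13, 6.4 % in 2014–15, 87/125 in 2016–20 | cohort values; the 2014–15 rate is interpolated from the ~3 remaining tested cases |
| per-marker availability / positivity | EGFR 65/90, ALK 78/90, PD-L1 79/90 (bins 27/15/37), RAS 51/90, BRAF 51/90 | cohort biomarker overview; ROS-1 is parsed but defaults to 0 availability (no printed row) |

Accession years are uniform on 2011–2020. Stain results are drawn
*consistently with the refinement rules* (re-classified cases have forced
stain patterns), and the free availability rates are solved analytically
from the configured marginals, so TTF-1/p63 availability matches its target
in expectation despite the consistency constraints; the generator asserts
rule-consistency for every record.

Lexical noise is a single level in [0, 1] scaling three independent
channels — synonym substitution, negated distractor sentences, and
hyphenated dual-site phrasing — plus two genuine degradations (an
unsubtypable "poorly differentiated carcinoma" phrasing and an omitted
location sentence), so accuracy decreases monotonically in expectation.

**What passing synthetic tests shows — and does not.** Perfect zero-noise
round-trips establish that the classifier inverts the generator's canonical
rendering, i.e. internal consistency of lexicon, renderer and parser; they
say nothing about recall on real reports, whose phrasing diversity (typos,
institution-specific templates, OCR artifacts, free-prose microscopic
descriptions) the generator does not attempt to model. Corpus-dependent
quantities of the original archive (the 4,625→854→538→234 funnel counts,
the 94 % location-audit accuracy, the single-lesion-subset p = 0.00453) are
therefore *procedures* here, exercised on synthetic data, not numeric
targets.

## Numerical and reproducibility choices

- All randomness flows from one integer seed through
  `numpy.random.default_rng`; identical configurations give byte-identical
  corpora, tables and manifests (rendered images excluded).
- Tables are emitted with fixed label order (frontal, parietal, temporal,
  occipital, cerebellum); "other" and "unknown" stay separate internally
  and merge only at presentation.
- Probability vectors must sum to 1 within 1e-9; configuration errors name
  the offending field.
- Degenerate inputs: empty margins are dropped before testing (a table
  reduced below 2×2 has p = 1); zero conditioning margins yield missing
  proportions rather than NaN propagation; an empty lung cohort short-
  circuits the statistics with a logged reason.
- Analysis drivers use 3,000-case corpora and the acceptance script a
  2,000-case corpus with 10⁶ Monte-Carlo replicates — sizes at which every
  checked marginal sits within three binomial standard errors and the
  Monte-Carlo SE on the global test is ~2.6×10⁻⁵.

## Known limitations and flagged inconsistencies

- The reference biomarker overview lists EGFR adequacy n = 65 while the
  site-stratified EGFR row sums to 71. The two tabulations count different
  things (patients vs per-site lesions), but they cannot both be projected
  from one patient-level table with the printed margins; each bundled table
  therefore reproduces its own printed counts, and no attempt is made to
  reconcile them.
- Whether a patient with two lesions in the *same* lobe counted once or
  twice in the reference tabulation is not stated; distinct-site collapsing
  is assumed (it reproduces the overlap matrix's Sum row exactly).
- The generator's biomarker draws are independent across markers given
  testing; real panels are correlated (reflex testing), which only matters
  for joint-biomarker analyses the package does not perform.
- Negation handling is sentence-scoped; clause-level negation ("positive
  for TTF-1 but not p63") is resolved by stain-to-token proximity in the
  stain parser, not by the classifier's negation rule.
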