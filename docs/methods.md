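# Methods

## Model and assumptions

`mirlink` treats a differentiation culture as a short positive-valued
time series per transcript: one uncultured-control condition and an
ordered set of culture timepoints (default d4, d6, d8, d10, d12, d14)
with replicate cultures (default 3). The analysis assumes (i) each
miRNA's control signal is a valid per-entity baseline, so fold changes
FC_t = mean_t / mean_control are comparable across miRNAs regardless of
absolute probe intensity; (ii) canonical seed complementarity
(miRNA positions 2–8 against the 3′UTR) is the primary determinant of
targeting; and (iii) a genuinely repressive miRNA→target relationship
shows up as negative Pearson correlation between the two log2
trajectories over the culture window. All three are standard working
assumptions for this class of array time-course analysis, not tested
hypotheses; the package's statistics quantify evidence under them.

## Stage-by-stage procedure and parameters

**Normalization** (`expression.normalize_to_control`). Replicates are
combined by arithmetic mean of the fluorescence index before the ratio
(geometric-mean mode available); both numerator and denominator are
floored at 1.0 fluorescence unit (configurable) so that zero or
near-zero signal yields large-but-finite fold changes rather than
infinities. The control timepoint itself always normalizes to exactly 1.

**Selection** (`select_differential`). The 5-fold criterion (default
`fold_threshold=5`, must exceed 1) is applied to the whole trajectory —
an entity qualifies if any non-control timepoint reaches the threshold —
because a differentiation course can peak mid-way; an endpoint-only flag
restricts to the final timepoint. Comparisons are inclusive (exactly
5-fold counts). If an entity crosses in both directions, the direction
with the larger |log2 FC| wins; an exact tie is classified up and
flagged ambiguous.

**Site scanning** (`target_prediction.scan_sites`). Patterns are derived
from the seed by reverse complementation; the terminal A of 8mer and
7mer-A1 is an adenosine required in the UTR irrespective of the miRNA's
position-1 base. Overlapping windows are resolved greedily by
specificity precedence 8mer > 7mer-m8 > 7mer-A1 > 6mer, so the 7mer
embedded in every 8mer occurrence is not double-reported. Coordinates
are 0-based half-open on the UTR sense strand everywhere, including all
TSV outputs. DNA-alphabet input is mapped T→U first; N never matches.

**Context-style scoring** (`context_score`). score = base(type) +
w_AU·(0.5 − AU fraction of ≤30-nt flanks) + w_pos·min(d_end, 1500)/1500,
with base(8mer) = −0.31, base(7mer-m8) = −0.16, base(7mer-A1) = −0.10,
base(6mer) = −0.02, w_AU = 0.20, w_pos = 0.10. These coefficients are
this package's own surrogate — chosen to preserve the canonical
site-type strength ordering and the qualitative AU-context and
end-proximity effects — not fitted values from any published model;
published context scoring additionally requires cross-species
conservation data that an offline desk tool cannot assume. All
coefficients are configurable.

**Duplex refinement** (`duplex_align`). A Gotoh local alignment of the
reversed miRNA against the site window extended 25 nt each side
(clipped at UTR bounds): Watson-Crick pair +5, G:U wobble +2, mismatch
−3, gap open −8 (first gap column), gap extend −2 (each further
column); columns pairing seed positions 2–8 are doubled, gap columns
never are. The empty alignment floors the score at 0. A pair is
"refined" when its best site's duplex score ≥ 80 (configurable); with
refinement enabled the percentile and duplex filters apply
conjunctively.

**Ranking** (`aggregate_and_rank`). aggregate_score per (miRNA, gene) is
the sum of its site context scores; 6mer sites are detected and
reported but excluded from the aggregate by default (include flag
provided) since they are marginal in isolation. Targeting strength is
the negated aggregate; pairs at or beyond the 95th percentile of the
strength distribution are retained, ties at the cut included. The cut
is global across all pairs by default; a per-miRNA mode is available.

**Annotation filter** (`annotation_filter`). Exact full-term equality
after case folding, never substring matching, with evidence_count ≥ 1
by default. The annotation map is a local (gene, term, evidence_count)
TSV so runs are reproducible offline; no ontology-tree expansion or
synonym resolution is attempted.

**Enrichment** (`enrichment`). Right-tail hypergeometric probability
via `scipy.stats.hypergeom.sf` (log-space-stable); the universe
defaults to the union of all pathway genes since a knowledge base's
internal background is generally unknowable, with an override. Ranking
is ascending p, ties by descending ratio k/K then lexical pathway id —
a deterministic rule the underlying test does not itself provide.
Raw p-values are reported by default; Benjamini–Hochberg q-values can
be attached without changing the order. The summary reports the covered
fraction |query ∩ ∪top-K| / n as a percentage at one decimal.

**Linkage** (`linkage`). Trajectories are timepoint means (n = number
of shared timepoints, ≥3), log2-transformed by default because
normalized expression is ratio-scaled (raw-scale flag provided). p is
two-sided from t = r√((n−2)/(1−r²)) on n−2 df; |r| = 1 is reported with
p = 0 by convention. Constant series make r undefined and are skipped
(with a logged count) during edge assembly, or raise when tested
directly. In the default `negative` mode an edge needs r < 0 and
p < 0.05.

## What the synthetic generator emulates — and what it does not

`synthetic_data` reproduces the statistical structure the pipeline
assumes: a control plus six every-second-day timepoints, three
replicate cultures, planted ≥5-fold monotone up/down miRNA
trajectories, planted canonical seed sites at recorded coordinates,
target trajectories anti-correlated with their regulator, and one
pathway with a planted query overlap. Defaults chosen where no external
value exists: multiplicative log-normal noise with σ = 0.2 on replicate
values (≈20 % CV, typical of fluorescence arrays; intensities are
positive and right-skewed, hence log-normal), trajectory noise
σ = 0.1, baselines log-uniform in [50, 5000] units, 22-nt miRNAs,
1-kb UTRs. Planted expression ramps log-linearly from baseline to
baseline × fold at the final timepoint — the simplest monotone shape
satisfying the endpoint fold contract; real trajectories peak and
plateau in varied ways.

Two deliberate guards keep planted truth exactly recoverable:
the bases flanking a planted site are pinned so a chance neighbouring
A (or position-8 complement) cannot upgrade the planted type, and the
UTRs of planted target genes are scrubbed of chance sites of *other*
planted miRNAs — otherwise, in low-noise settings where all planted
trajectories are nearly collinear, a chance cross-site would create a
statistically genuine but unplanted edge. An optional clean-background
mode scrubs all 7/8-mer sites of every simulated miRNA from all UTRs
(6mers optionally; guaranteeing 6mer-free long UTRs may not converge,
so it is off by default).

What passing tests on these data do **not** show: robustness to probe
saturation, dye bias or background subtraction (not simulated),
correlated noise across timepoints, non-monotone regulation, targeting
via non-canonical or 3′-supplementary sites, or conservation-informed
ranking. Results on real array data depend on upstream preprocessing
that is outside this package.

## Numerical choices and degenerate inputs

- Percentile cut uses linear-interpolated percentiles with an inclusive
  ≥ comparison: 100 distinct strengths at the 95th percentile retain
  exactly the 5 strongest; an all-tied distribution is fully retained.
- The duplex DP and the scanner are exactly reproducible (pure integer
  scores, no floating accumulation hazards at these sizes).
- Empty UTRs, empty edge lists and header-only expression tables are
  valid degenerate inputs producing empty outputs, not errors;
  duplicate ids, negative values, inconsistent contingency counts and
  out-of-range thresholds fail fast with typed exceptions mapped to
  distinct CLI exit codes.
- Fixture and test sizes (20–300 miRNAs, 56–150 genes, 1-kb UTRs,
  100-seed Monte-Carlo loops) are chosen so the whole suite and the
  acceptance script each run in well under a minute on one core while
  leaving the planted effects at realistic magnitudes.

## Known limitations

- The context-style score is ordinal, not calibrated repression; its
  percentile cut is a ranking device, and absolute scores should not be
  compared across runs with different coefficient settings.
- The duplex aligner scores base pairing only; no thermodynamic folding
  energy, no target-site accessibility.
- Pearson gating on 6 timepoint means has limited power (|r| ≳ 0.81
  needed at α = 0.05, two-sided); true weak links will be missed, and
  the direction-consistency flag is descriptive, not a test.
- Fisher enrichment treats genes as exchangeable; no gene-length or
  expression-level bias correction.
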