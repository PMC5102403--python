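# Methods

## Study design emulated by the generator

`pulldown.synth` simulates a replicated tagged-bait purification study:
five organs by default, each with 6–10 knock-in (KI) purification/MS
runs and 6–11 mock (WT) runs (drawn per organ unless fixed in the
config), the bait present in every KI run with count ≥ 1 and in no mock
run. Each organ carries `planted_per_organ` true interactors (default
30, matching per-organ interactome sizes of a few dozen); a shared pool
of `round(shared_fraction × planted_per_organ)` proteins (default 30%)
is planted in every organ, so the pairwise shared fraction is realized
exactly, and the remaining interactors are organ-unique.

Counts and backgrounds:

* **Spectral counts** for planted interactors are negative-binomial with
  mean 10 and dispersion 0.3 (variance = μ + 0.3 μ²), because spectral
  counts are over-dispersed relative to Poisson; a `count_model="poisson"`
  switch is provided. A planted interactor drops out of a single KI run
  with probability `detection_floor` (default 0.05).
* **Contaminants** are a fixed "sticky protein" ranking drawn once per
  universe (default 300 proteins), detected in *both* genotypes with
  probability 0.9 · rank^(−1) (a power law capped at 0.9), so the same
  background recurs across runs and genotypes the way mock-purification
  backgrounds do. Because contamination is genotype-symmetric, these
  proteins are removed by background subtraction, not by fiat.
* **Database edges** combine per-organ "core wiring" (each planted
  interactor linked to another same-organ planted interactor with
  probability 0.9, and to the bait itself with probability 0.1) with a
  sparse Erdős–Rényi background (p = 5 × 10⁻⁴ over the catalog).
* **Substrate labels** are Bernoulli with base rate 1.95% and relative
  risk 6.6 among planted interactors, reproducing the contrast the
  overlay test is designed to detect (≈12.9% vs 1.95%).
* **Sequences** are i.i.d. uniform over the 20 amino acids
  (length 100–1000) except labeled substrates, which receive one
  embedded S-P-x-K consensus site whose four context positions are
  favourable with probability 0.6 each — this spreads substrate scores
  over several discrete values instead of piling them at 0, which keeps
  the percentile calibration non-degenerate.
* **Reporter intensities** are lognormal per peptide; the KO channel is
  the KI channel times the protein's true fold change times
  2^N(0, 0.15) noise (log2 sd configurable). By default three planted
  partners of the iTRAQ organ get fold 4 and one gets fold 0.1.

All randomness flows from one seed through named substreams (universe /
runs / iTRAQ), so a stage can be regenerated independently and equal
configs produce byte-identical files.

What the generator does **not** model: peptide-to-protein inference,
shared peptides, tag-position effects on capture (the real protocol
pooled amino- and carboxy-tagged material ~1:1), organ biology beyond
set overlap, isotope-impurity cross-talk in reporter channels, and any
correlation between a protein's abundance and its detectability. Passing
the recovery tests therefore shows the scoring rules are correct and
well-calibrated under the stated noise model, not that they are robust
to protein-inference artifacts in real data.

## Interactor scoring

The detection-table one-tailed Fisher test plus the pseudocounted
peptide-rate ratio is this package's concrete instantiation of the
per-protein evidence statistics (p/ratio × tissue/all); every threshold
is config-exposed (`ScoringThresholds`: α_core = α_pooled = 0.05,
min ratio 3, min KI detections 2, pseudocount 0.5). The 0.5 pseudocount
on per-run peptide rates is a standard continuity correction making
ratios finite and comparable. Ties at exactly α are included (≤/≥ as
written). No multiple-testing correction is applied by default — the
evidence tables report raw per-protein statistics — but
`ScoringThresholds(fdr=True)` switches the core call to
Benjamini–Hochberg-adjusted per-tissue p-values.

Category semantics: core calls are purely statistical; promotion makes a
protein core in any tissue where it was detected with a KI-biased ratio
once it is core-by-statistics elsewhere. The Category 2 / Category 3
distinction is this package's design: Category 2 rescues sub-threshold
proteins whose *pooled* evidence is significant, Category 3 rescues on
repeated detection alone; both require a database edge to a same-tissue
core interactor, and background-subtracted proteins are never rescued.
Removing the edge list demotes every Category 2/3 call to rejected and
changes no core call.

## Graph and overlap conventions

Database edges between called interactors are "solid" (same-organ or
cross-organ in the combined view); every interactor with no
database-edge *path* to the bait gets a direct dashed (`ms_only`) edge
to it, so the bait reaches every node and dashed edges mark interactions
supported only by the pulldown. Pairwise shared fractions are
deliberately directional — shared(A, B) = |A∩B|/|A| — because no single
symmetric convention reproduces both margins; both directions are
reported and any heatmap should use the row organ's denominator.
Unique/shared statistics are computed over all called interactors by
default (`core_only` switches to Category 1 only). The conservation
identity Σ organ-unique + multi-organ = combined size is exact by
construction and asserted in tests.

## Enrichment background convention

The background term/substrate counts (K of N) describe the whole
annotation universe *including* the gene list; the list is subtracted
from the background row before the exact test, giving the table
[[k, n−k], [K−k, (N−n)−(K−k)]]. This disjoint-rows convention is what
reproduces the published overlay statistics (15/117 vs 390/19,999 →
p = 8.9 × 10⁻⁹; 39/117 vs 1,296/16,408 → p = 2.4 × 10⁻¹⁵); testing the
printed rows unsubtracted gives 1.4 × 10⁻⁸ and 5.0 × 10⁻¹⁵ instead.
Reported folds use the printed rates (k/n)/(K/N). The EASE score is the
canonical jackknife variant — one supporting gene removed from the
list∩term overlap, other cells unchanged — hence EASE ≥ Fisher always
and EASE = 1 for k ≤ 1. Background sizes (19,999 for the known-substrate
proteome, 16,408 for the sequence-scored proteome) are configuration
values used as given per analysis.

## Motif model and stringency calibration

The motif scanner is an explicit functional stand-in for proprietary
position-specific scoring services: same interface (per-site best score
in [0, 1] with 0 = perfect, percentile stringency classes over a
background proteome, class medians) with a transparent, configurable
model. The default model gates on the mandatory +1 proline and penalizes
mismatches at +3 (K/R, weight 2 of 6) and at context offsets −2, +2, +4
(S/P/A) and +5 (K/R/A), weight 0.5 each; offsets falling outside the
sequence count as mismatches; positions are 1-based. Including alanine
in the context preference sets makes the bare consensus S-P-A-K score
exactly 0 while keeping chance full matches rare in uniform background
sequence. Stringency cutoffs are empirical quantiles of the background
protein-score distribution (defaults 0.2% and 1.0%), membership is
score ≤ threshold, and the high class is nested in medium by
construction. Calibration refuses backgrounds under 1000 proteins or
with all-equal scores. Because motif carriers enter the synthetic
interactome only through the substrate label, per-study interactome
motif enrichment is directionally positive but modest; the dose–response
of the enrichment p-value in the substrate relative risk is the sharp
check.

## iTRAQ quantitation

Peptide ratios use the median per protein (mean behind a flag) for
robustness to single-peptide outliers; peptides with a missing or
non-positive intensity in either channel are dropped, and a protein with
no usable peptide is reported `not_quantified`. Mock channels are used
only for optional intensity background subtraction (off by default).
Bait normalization divides each prey's KO:KI ratio by the bait's and is
idempotent and invariant to rescaling a whole channel; an unquantified
bait is a fatal error. Default call thresholds are 2.0 (gained) and 0.5
(lost).

## Numerical and I/O choices

Fisher tails are computed as hypergeometric survival functions
(scipy); an exhaustive test checks agreement with independent tail
enumeration to 10⁻¹² over every 2×2 table with total ≤ 40. Tables use a
UTF-8 tab-separated dialect with one `#`-prefixed header line and no
quoting; gene sets are GMT; sequences FASTA; graphs GraphML/SIF. One
canonical protein-id space is used as keys throughout. Duplicate protein
rows within a run are summed with a warning; edge-list endpoints absent
from the scored set are warned about and ignored for rescue. Logging is
timestamped and stage-scoped to stderr, so output files contain no
timestamps and full runs are byte-reproducible.

## Problem sizes

Default generator: 2000 proteins, 5 organs, ~80 runs, ~300 contaminants;
a full pipeline run takes a few seconds on one CPU. Tests use 300–2000
protein catalogs; the Monte-Carlo calibration checks use 100–120
independent universes at reduced sequence length.

## Known limitations

* The per-protein statistical test is an explicit, swappable
  instantiation chosen to match the published evidence columns, not a
  reconstruction of the original supplementary procedure.
* Whether a "detection" counts runs or purifications is not
  distinguishable here (one purification = one run).
* The motif model's scores are not comparable to any external scanner's
  absolute medians; only its contingency counts feed the enrichment
  stage.
* Printed overlap percentages from heterogeneous denominators cannot be
  regenerated from organ totals alone; the package reports both
  directional conventions instead of guessing.
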