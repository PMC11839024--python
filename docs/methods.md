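# Methods

## Scope and model

The package treats an organelle interactome as the product of three
evidence layers — a meta-analysis over published organelle proteomes, a
co-fractionation screen, and cross-linking mass spectrometry — integrated
into a graph and triaged against structural models. Upstream components
that produce the raw evidence are consumed, never re-implemented: search
engines and FDR control for cross-link identification, co-fractionation
classifiers (their [0,1] scores are opaque inputs), structure-prediction
inference, and the SPOC interaction classifier. The package's own
contributions are the filtering, integration, evaluation, and scanning
logic downstream of those inputs.

## Meta-analysis

Each protein carries three metrics: the count of independent datasets
identifying it, log-scale abundance in the organelle IP, and the count of
reported interactions with reference organelle proteins. Because a
monotone (e.g. logistic) transform leaves an ROC unchanged, ROC curves are
computed on the raw metrics. Partial AUC integrates the ROC over
false-positive rates in [0, 0.10] by trapezoid; the normalized form
divides by 0.10, so a perfect separator scores 1.0 and chance 0.05.

The combined score is the sum of the three metrics. By default each
metric is rank-normalized to [0,1] before summation: raw summation lets
whichever metric has the largest numeric range dominate, while rank
normalization preserves summation semantics with commensurable units. Raw
summation is available via `standardize=False`. Missing IP abundance is
imputed as the observed minimum (absence in an IP is evidence of
non-detection, not missingness at random); imputation is logged.

The calling threshold is the smallest score at which the fraction of
reference-negative proteins at or above it is ≤ the 10% target. Negatives
are defined operationally as proteins not on the curated reference list —
an approximation, since no curated negative set exists; the realized
false-positive rate it bounds is reported alongside every call table.
Ties at the threshold are included (≥) and the bound re-verified.
Exclusion-listed proteins (e.g. mitochondrially annotated) are vetoed
after thresholding and can never be called.

## Co-fractionation

Profiles are 48 non-negative intensities, fraction 1 being the highest
apparent mass. Normalization is row-wise (sum-to-1 by default, max-to-1
optionally); all-zero profiles are flagged and excluded from correlation.
The consensus across replicates drops the replicate most dissimilar
(lowest Pearson r) to the per-fraction median when its r falls below a
configurable floor (default 0.5), then averages the rest. The outlier
wording is ambiguous between replicate-level and fraction-level exclusion;
replicate-level is the default and a fraction-level variant
(`consensus_profile_fractionwise`) is provided.

When no external classifier score is supplied, the per-replicate
co-elution score is max(0, Pearson r) of replicate profiles — a documented
stand-in with the right monotonicity, not a classifier clone. The filter
itself is: score ≥ 0.7 in ≥ 2 replicates, complex size ≤ 25, complex peak
apparent mass ≥ 67 kDa. The mass cut is implemented through a marker
calibration table (fraction → kDa, log-interpolated); without calibration
the mass filter is skipped with a warning rather than silently passing or
failing pairs. All three thresholds are inclusive (≥) and configurable;
the filter is monotone in every replicate score.

## Cross-link tables

Links are canonicalized (accession_a ≤ accession_b; positions ordered for
intra-links) so duplicates collapse deterministically and output is
invariant to row order. The search-score filter is strict (> 40): a score
exactly at the threshold is removed. Deduplication keeps the best score
and the distinct-replicate count per canonical residue pair.

Topology consistency groups lumenal with extracellular ("non-cytosolic")
and requires both residues of a link on the same side. Residues inside a
transmembrane segment are classed by their nearest flanking compartment —
cross-linkable side chains at TM borders are accessible from the flanking
region. Residues in no segment are unannotated and excluded from the
consistency percentage.

Secondary-chemistry links (DHSO, DMTMM) map onto the DSSO-defined
interaction set through peptide ambiguity groups: a link whose peptide is
shared by paralogs annotates every primary interaction its expansion can
form, and unmatched links are reported separately.

## Network

XL and BN edges merge into an undirected simple graph; parallel evidence
lands on one edge carrying both `xl_count` and `bn_replicates_passing`.
Blocklisted nodes default to the purification handle (EEA1), ubiquitin
(UBC, usually a modification rather than a complex member), keratins
(`KRT*`), and any supplied marker proteins.

Endosome centering keeps the reference endosomal proteins and their direct
interactors; a second-order interactor is kept when connected to ≥ 1
direct interactor by a cross-link-supported edge and/or ≥ 2 direct
interactors by BN-only edges. The two-distinct-BN-edges reading follows
the rule's sentence structure; the one-edge-two-replicates alternative is
available via `bn_rule="two-replicates"`. Exclusively nuclear nodes are
removed as dubious connectivity before edges are induced. Blocklist and
centering commute (covered by a test).

Statistics: mean shortest path is the BFS average over connected pairs
only; the power-law statistic is the R² of a least-squares line on log
degree vs log frequency (degrees ≥ 1, zero-frequency bins dropped), with
a continuous-MLE exponent mode behind a flag. Note that on
preferential-attachment graphs of ~2000 nodes this per-degree R² sits
around 0.8–0.9 because singleton tail degrees scatter; the statistic still
separates scale-free from Erdős–Rényi graphs cleanly, which is what the
property test asserts.

Communities come from the Girvan–Newman edge-betweenness hierarchy cut at
maximum modularity, run per connected component, with betweenness ties
broken by the lexicographically smallest edge; the single-community
partition is a candidate, so cliques are not split. Community counts are
algorithm- and tie-break-sensitive, so no exact community count is treated
as a correctness target.

The rewiring null applies double edge swaps (10 per edge by default),
which conserve the degree sequence exactly and never create self-loops or
multi-edges; saturated graphs (stars, cliques) return with a warning.
Complex coherence reports within- vs between-complex shortest-path
distributions and the mean per-protein fraction of direct neighbors
sharing a complex, with an empirical enrichment p-value
p = (1 + #{nulls ≥ observed}) / (n_nulls + 1), bounded below by 1/101 at
100 permutations.

Triangles (3-cliques) are enumerated over sorted adjacency with the
constraint that at least one of the three edges is cross-link-supported;
the enumeration equals an O(n³) brute force on every tested graph.

## Structure checks

Models are Cα-level: per-chain coordinates plus per-residue confidence
(pLDDT 0–100; absent for experimental structures). All public residue
numbering is 1-based full-length positions; chain-internal numbering is
reconciled at load time via per-chain offsets. mmCIF/PDB I/O goes through
gemmi, reading B-factors as pLDDT for predicted models; synthetic
coordinates are quantized to 0.001 Å so file round-trips are bit-exact.

Distance evaluation statuses are exhaustive and mutually exclusive:
`unmapped` (outside the modeled range or missing Cα), `unstructured`
(either residue pLDDT ≤ 70; experimental structures skip the gate since no
pLDDT exists), `within` (distance ≤ threshold, inclusive), `exceeded`.
Thresholds form a (chemistry × model-source) matrix: 35 Å for DSSO/DMTMM
(and DHSO, for which no separate value is established) on standard
predictions and experimental structures; 30 Å for every chemistry on
link-assisted predictions, whose inference already consumed the links.
Summary fractions count within among {within ∪ exceeded}, reported
separately for intra- and inter-protein links, with zero denominators
reported absent rather than as 0.

Prediction triage: SPOC ≤ 0.33 is low-confidence (strictly greater
required); records without SPOC fall back to ipTM at the same threshold
and are `unscored` with neither. Scored records are `supported` when more
than 50% of measured interprotein links are within constraint,
`unstructured-only` when every link is unstructured/unmapped, `violated`
otherwise. Trimer acceptance needs ≥ 2 of 3 interface averages strictly
> 0.5, with missing interfaces counting as 0; the interface-average
statistic itself is consumed as an input column.

Interface contacts default to Cα–Cα ≤ 8 Å (Cα-only models must be
supported; an all-atom ≤ 5 Å mode would need full coordinates). The
variant scan is sequence-distance only: a variant hits when its protein
has a contact position within 2 residues. Pseudobond exports write one
deterministic sorted line per mapped link, colored by status, and
round-trip through a bundled parser.

## Synthetic data

The generators emulate the study conditions at their defaults and are the
fixture source for every test: 1000 proteins over 16 datasets (mirroring a
16-study presence/absence matrix), per-dataset detection sensitivity 0.5
for endosomal proteins against 0.08–0.25 for other compartments, IP
abundance shifted +1.5 log units for endosomal proteins with 10% missing,
and reference interaction counts Poisson(3.0) vs Poisson(0.3). BN profiles
are Gaussian peaks (sd 1.5 fractions) over 48 fractions, 3 replicates,
multiplicative noise CV 0.1. Structures are ideal α-helices (rise 1.5 Å,
100°/residue, radius 2.3 Å — consecutive Cα ≈ 3.83 Å) laid side by side
8 Å apart, optionally z-shifted so chains share only a local interface;
cross-links are sampled without replacement from residue pairs ≤ 35 Å
(true) and > 35 Å (decoys, 20/8 per model at defaults), with shortfalls
warned rather than raised. Variants are placed within / strictly outside
the 2-residue interface window.

A single integer seed feeds a named substream per generator
(CRC32-derived), so outputs are bit-identical under the same seed and
adding a generator never perturbs the others.

What the generators do **not** emulate: peptide-level identification and
FDR, protein inference, abundance-dependent detection bias, correlated
noise across fractions, disordered regions and conformational
heterogeneity in structures, or paralog sequence sharing (ambiguity groups
are supplied explicitly). Passing tests therefore demonstrate the
correctness of the filtering/integration/evaluation logic under planted
truth, not the end-to-end recovery performance on real organelle data.

## Problem sizes and determinism

Default test and driver sizes (synthetic world of 1000 proteins, models of
2 × 40 residues, networks of a few hundred nodes, 100 rewiring
permutations at 2 swaps per edge in the larger checks) were chosen so each
stage's behavior is fully exercised while the whole suite runs in well
under a minute; the statistics of interest (fractions, oracle agreement,
FP control) are size-independent by construction. All randomness flows
from explicit seeds; reruns with the same config produce byte-identical
reports.

## Known limitations

- The co-elution stand-in score (max(0, r)) is monotone in profile
  similarity but not calibrated to any classifier's score distribution;
  external score tables should be preferred when available.
- Girvan–Newman is O(m²·n)-ish and intended for core components of a few
  hundred nodes, matching the analysis scale here.
- The endosome-centering rule treats multi-compartment annotations by
  fixed precedence (endosome > lysosome > golgi > mito > nucleus), which
  undercounts genuinely dual-localized proteins.
- File-based (non-synthetic) orchestration is exposed per stage through
  the CLI subcommands; the single-config `all` runner currently drives
  the synthetic chain only.
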