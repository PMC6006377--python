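# Methods

srmkit implements the analysis path from discovery (DDA) proteomics of a
two-species mixture to a validated targeted (SRM) assay, together with a
synthetic dilution-series generator that makes every stage testable without
raw mass-spectrometry data. This note records the models, the defaults and
why they were chosen, and what the synthetic test bed does and does not
establish.

## In-silico digestion (`srmkit.proteolysis`)

Trypsin cleaves C-terminal to K or R; cleavage is suppressed when the next
residue is proline. Both rules are configurable through
`DigestParams.cleave_residues` / `no_cleave_before`; the proline rule is on
by default because the common digestion simulators apply it. Only fully
tryptic peptides are generated — peptides with a non-tryptic terminus arise
from in-source fragmentation or database-search settings, not from the
enzyme model — but `PeptideRecord` keeps per-terminus flags so downstream
protein-inference filters can express "at least one terminus tryptic".

Default filters: monoisotopic mass in [400, 6000] Da, length ≥ 5, up to 3
missed cleavages. Masses are monoisotopic throughout (residue masses from
pyteomics; water 18.010565 Da); average-mass mode is out of scope.
Hydrophilicity is the arithmetic mean of Hopp–Woods residue values.

Records containing nonstandard letters (B, J, O, U, X, Z) are excluded from
digestion and logged: their mass is undefined and downstream fragment m/z
would be meaningless. Empty or sub-minimal sequences raise rather than
returning sentinels, to fail fast inside pipelines.

Correctness is established against a brute-force oracle that enumerates
every substring bounded by cleavage sites and applies the filters
independently; the digest must match it exactly on random sequences
(including a hypothesis property test) and on 100 random 300-residue
proteins.

## Taxonomic specificity (`srmkit.taxonomy`)

A peptide observed in several organisms is assigned the deepest taxonomic
rank at which all of their lineages agree (lowest common ancestor). The
implementation is fully offline: the caller supplies a lineage table
(taxon_id, rank, name; shallow→deep) and a peptide→taxon occurrence map as
TSVs. A peptide is *discriminatory* for a target clade when the agreed
lineage prefix contains that clade, i.e. every organism carrying the
sequence lies inside it. Reporting uses the seven classical ranks; extra
intermediate ranks in the input participate in the LCA depth comparison.

Peptide identity is exact sequence match by default. Because isoleucine and
leucine are isobaric and indistinguishable by fragment mass, an
`equate_il=True` mode maps L→I before comparison; both modes are tested.

## Discovery statistics (`srmkit.discovery`)

Protein inferences are accepted when a protein has ≥ 2 distinct peptides of
which at least one has a tryptic terminus; upstream search-engine
probability filtering is represented by an optional boolean `prob_pass`
column (those mixture models are treated as a black box). Abundance is the
normalized spectral abundance factor, NSAF_i = (S_i/L_i) / Σ_j (S_j/L_j),
so each sample column sums to one and uniform count scaling cancels.

Ordination: Bray–Curtis dissimilarities (scipy) on NSAF with technical
replicates averaged first, embedded by non-metric MDS (scikit-learn SMACOF,
seeded). The dissimilarity choice is a configurable convention, not a
claim. Per-protein axis loadings are Pearson correlations between protein
abundance and axis coordinate, with a two-sided permutation p-value
p = (1 + #{|r_perm| ≥ |r_obs|}) / (1 + n_perm); the default n_perm = 1000
makes the attainable floor 1/1001 ≈ 0.000999. ANOSIM uses midranks,
R = (mean between-group rank − mean within-group rank)/(M/2), M = n(n−1)/2,
with label-permutation p; it is implemented in-package so the permutation
stream is seedable, and cross-checked against scikit-bio's implementation
in the test suite.

Candidates for targeted assays are the union of three criteria — detected
in every (dilution, replicate) pair; detected only in user-named
low-dilution samples; peptides of proteins with loading > 0.99 at the
permutation-floor p — minus any peptide in the cross-proteome shared set,
which is excluded unconditionally.

## Assay construction (`srmkit.assay`)

Theoretical b/y fragment m/z come from cumulative residue-mass sums
(proton 1.007276 Da); b_k and y_(n−k) neutral masses must sum to the
peptide neutral mass, asserted to 1e-4 Da. Library fragments detected in
fewer than `min_replicates` (default 2) technical replicates score zero;
the rest are rank-scored by relative intensity with a deterministic
tie-break (higher m/z, then y before b, then lower ordinal — higher-m/z
fragments are generally less interference-prone).

Caps follow the published convention: a peptide needs ≥ 3 quality
fragments to be schedulable, at most 4 transitions are kept per peptide
and at most 3 peptides per protein (by summed transition quality). The
stated ">3 peptides per protein" requirement in the source workflow
contradicts its own "no more than 3" cap and is resolved as: no minimum
per protein, maximum 3. Candidates without a usable library entry are
listed in `not_schedulable`, never dropped silently.

The transition list is split across method files (default 2) by greedy
longest-processing-time assignment of whole peptides. A peptide's
transitions are never divided between files — they must be co-acquired to
quantify the peptide — so balance is guaranteed only to within one
peptide's transition count (≤ 4 at the default cap), and is exact when all
peptides carry equal counts.

## SRM evaluation (`srmkit.srm`)

Inter-run normalization: QC-standard transitions are ranked by across-run
CV% (sample sd over mean, in percent); the 8 lowest with CV < 40% are
selected, and every area in a run is divided by that run's mean selected-QC
area. Fewer than 8 qualifying QC transitions is a warning (all qualifying
are used); none is an error. Noise-free multiplicative run effects cancel
exactly under this scheme, asserted to 1e-9.

Screening: only mixture samples (finite bacteria:phyto ratio) enter the
correlation — pure endpoints have no finite dilution factor, which with the
seven default mixtures gives n = 7. Per transition, Pearson r between
per-dilution mean normalized area and dilution factor is compared with the
analytic two-tailed critical value r_crit = t/√(n−2+t²),
t = t_{1−α/2, n−2}; at n = 7, α = 0.05 this is 0.754492…, printed as 0.755
under the half-up reporting convention (`round_half_up`). Correlation is on
raw scale by default with a log–log option; per-dilution mean over
biological replicates feeds it (replicate-level correlation is an option).
Missing areas are absent, not zero; a transition counts as detected in a
dilution when at least one replicate has area > 0. Transitions with fewer
than 3 usable levels are reported unevaluable, not failed.

## Synthetic dilution series (`srmkit.simulate`)

The default design reproduces the bench mixture table: constant 2.08×10⁹
bacterial cells against serially diluted phytoplankton (3.33×10⁷ down to
2.08×10⁵ cells; seven mixtures 62:1…10000:1 plus two pure endpoints).
Protein-mass ratio = cell ratio × per-cell protein-mass ratio; the per-cell
ratio defaults to 0.0788, back-calculated from the 10000:1 column
(788.0/10000), and then reproduces the remaining printed column values at
one decimal. Absolute per-cell protein masses are not modeled — only the
ratio is recoverable from the design table.

Toy proteomes are concatenations of unique random tryptic blocks (first
residue never proline, so block boundaries are exactly the digestion
boundaries) with a configurable number of planted peptides shared verbatim
between the two species; the planted list is the emitted ground truth for
the shared-peptide stage.

DDA is emulated as C cycles (default 200) of top-N (default 20) selection
by weighted sampling without replacement (Gumbel top-k), with peptide
weight = parent-protein lognormal abundance × the species' protein-mass
share in the mixture. This reproduces the essential censoring: the rare
species' peptides are outcompeted for MS2 slots at low protein share.
Dynamic-exclusion clocks, retention time and charge-state effects are not
modeled, so the simulator supports rank/limit properties, not absolute PSM
counts.

SRM quantification: area = response × protein_ratio × run_effect ×
exp(ε), ε ~ N(0, σ²) with σ = 0.05 (multiplicative error is standard for
LC-MS peak areas); flat negative-control transitions and QC transitions
omit the ratio term. Run effects are uniform on (0.7, 1.4) — ≈19%
across-run CV, so spiked QC standards remain selectable under the 40%
screen, as they are on a stable instrument. Peaks near the detection limit
drop out: with probability exp(−signal/detection_scale) only
chromatographic background (small lognormal area) is integrated.
detection_scale = 2.5×10⁵ (relative to the median responsive transition
level of 10⁵ × 4.9 at the lowest mixture) puts the expected fraction of
transitions with replicate CV > 100% at ≈19% in the lowest mixture,
falling to well under 1% at ratios ≥ 250:1 — the qualitative reliability
profile targeted quantification shows at low target abundance. Flat
controls emulate abundant constitutive peptides (500× level) and are
never censored. Default 250 responsive + 250 flat transitions, 10 QC,
biological triplicates.

Everything is deterministic under a fixed seed (byte-identical FASTA,
frame-identical tables).

### What the synthetic bed shows — and does not

End-to-end, the screen recovers planted responsive transitions with
pooled sensitivity ≈100% and specificity ≈97% (null false-pass rate
α/2 = 2.5%). Because the QC-mean normalization error is shared by every
transition within a run, false passes on a single simulated series are
clustered: one unlucky shared noise draw can push specificity on a single
series several points down. Performance figures are therefore pooled over
10–20 independently seeded series, which measures the operating
characteristics rather than one shared draw. Passing these checks shows
the pipeline's logic and statistics are correct at the stated noise level;
it says nothing about chromatographic interference, retention-time drift,
or matrix effects in real samples, which the generator does not model.

## Numerical conventions

- Reported r values and thresholds use decimal half-up rounding to 3
  decimals (the printed threshold 0.755 corresponds to the computed
  0.7545 at 4 decimals).
- CV requires ≥ 2 non-missing values and positive mean; otherwise NaN,
  flagged rather than silently zero.
- Quality ties, LCA rank order, and method-file assignment are all
  deterministic (explicit tie-break keys, stable sorts).
- Permutation tests use `numpy.random.default_rng(seed)`; p-values are
  (1 + exceedances)/(1 + n_perm) and can never be 0.

## Problem sizes

Test and acceptance runs use desk-scale inputs chosen to exercise every
code path: toy proteomes of ~30 proteins per species (digest oracles run
on 100 random 300-residue proteins), 500-transition quantification
matrices over 21 runs, and 10–20 pooled simulation replicates for the
end-to-end screen.
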