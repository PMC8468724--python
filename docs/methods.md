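# Methods

This note documents the models, conventions, and numerical choices behind
each pipeline stage, what the synthetic generators do and do not emulate,
and the known limitations.

## Curation

Records are excluded, in a fixed rule order (missing value, unparseable
value, censored relation, FC/Ratio readout, missing units, non-convertible
units, low confidence), and each rejected record is counted once under the
first rule it violates; with one planted violation per record the counts are
order-independent. Unit conversion accepts M/mM/µM/nM/pM with the `u`/`µ`/`μ`
dialects normalised case-insensitively before lookup. Left-censored
relations (`<`, `≤`) are retained and treated as exact values: only
right-censored measurements are uninformative for a "most potent value"
reduction. The deduplication key is the canonical SMILES after salt
stripping (largest organic fragment) and charge neutralisation, so salt
forms collapse deterministically without any third-party dedup tool; when
IC50 and Ki measurements coexist for one structure the minimum is taken
across readouts and the kept readout is recorded. Class binning uses strict
inequalities (< 1000 nM active, > 10 000 nM inactive), putting both
boundary values in the moderate class. Tautomer/ionisation-state enumeration
is deliberately not reproduced; curated output is one record per compound.

## Chemical space

Fingerprints are Morgan, radius 2, 1024 bits, held as a dense uint8 matrix
so cross-set similarity reduces to one matrix product. Tanimoto of two
all-zero fingerprints is defined as 0 (the 0/0 case). Scaffold content uses
Bemis–Murcko pruning; acyclic molecules yield an empty scaffold that is
reported but never counted as shared content. The scaffold diversity ratio
is |unique scaffolds| / |compounds|.

MCS search distinguishes two mapping modes: `strict_aromatic` uses exact
bond-order comparison, which prevents aromatic bonds from matching single
or double bonds and hence maps aromatic atoms only onto aromatic atoms;
`relaxed` ignores bond order entirely (benzene then matches cyclohexane
over all six atoms). Because MCS is NP-hard, each pair receives a
configurable time budget (default 5 s) and timed-out pairs are skipped with
a logged warning rather than stalling the run. A pair is reported when the
MCS has strictly more than `min_atoms` atoms (default 15).

The 2-D embedding is t-SNE over the raw fingerprint bits with a fixed
`random_state`, PCA initialisation, and perplexity capped at (n−1)/3 so
small sets remain embeddable; coordinates are deterministic per seed on a
given platform, but t-SNE distances are only locally meaningful.

## PLIF screening

A PLIF is collapsed to one bit per residue (any interaction type counts as
a contact); the per-interaction-type layout of commercial fingerprints is
tool-specific and the similarity is defined over residue contacts. The
screening function is the Tanimoto similarity between a compound's contact
profile and the X-ray reference ligand's profile restricted to the N most
frequently contacted residues across all docked ligands; frequency ties are
broken by ascending residue sequence number so the subset is deterministic.
N is swept over {5, 10, 15, 20, 25} and the choice among curves is left to
the analyst: `curve_diagnostics` reports the maximum enrichment (first
occurrence on ties), its threshold and coverage, and the number and depth
of non-monotone drops, which is the information that selection reasoning
needs.

Enrichment at threshold t is 100 × (actives among selected) / (selected),
with selection `value ≥ t` for similarities and `value ≤ t` for docking
scores; only the strict active class counts as active, so moderates depress
enrichment. Coverage is the number selected; zero-coverage points are
reported as undefined (NaN), never as 0%. At the loosest threshold
enrichment equals the dataset's base active rate exactly. The default
threshold grid is 0.0–1.0 in steps of 0.1.

The dual-hit criterion is an interval condition with explicit inclusivity
flags, defaulting to `0.8 < sim_A ≤ 0.9` and `sim_B ≥ 0.9`; the strict
lower bound and inclusive upper bound are honoured exactly, and the hit
table echoes both similarities per compound. The upper bound on target A
reflects the empirical observation that perfect PLIF similarity can select
sparsely covered, occasionally inactive poses.

## QSAR

Features are ~200 interpretable 2-D RDKit descriptors (an open descriptor
set of scope comparable to commercial interpretable sets), with inf/NaN
values imputed by column medians. The split is 80:20, stratified by class
(configurable), deterministic per seed. Hyperparameters (max depth, min
leaf size) are tuned by stratified k-fold CV (k = 10, reduced with a
warning when a class is smaller than k) maximising mean macro-F1 — the CV
objective is a package choice exposed as configuration — with ties broken
toward the simpler model (smaller depth, then larger leaf). Weight schemes
map their tuples onto (inactive, moderate, active), placing the heaviest
misprediction penalty on actives, consistent with screening use where
active-class precision matters most; `balanced` is inverse class frequency,
n / (k·count). All metrics are recomputed from the confusion matrix with
the one-vs-rest formulas (precision = TP/(TP+FP), recall = TP/(TP+FN), F1
harmonic mean, accuracy = trace/total); the precision of a class never
predicted is reported as undefined (NaN) and flagged, not silently zeroed.
Cross-application between datasets attaches an applicability-domain flag:
out-of-domain iff the compound's maximum Tanimoto to the training set is
below 0.3, roughly the background similarity between unrelated inhibitor
chemotypes. Seeds are mandatory arguments throughout; there is no hidden
global random state.

## MD statistics

Energy drift is the least-squares slope of total energy against time;
the verdict compares |slope × duration / mean| with a configurable relative
tolerance (default 1%). RMSF is per residue,
sqrt(mean over frames of squared displacement from the time-mean position),
averaged over the residue's atoms; frames are optionally (default on)
least-squares superposed onto the first frame using the non-ligand atoms,
which removes rigid-body drift for real trajectories. For small all-noise
systems the 6 fitted rigid-body degrees of freedom absorb part of the
fluctuation, so recovery tests on jitter-only synthetic trajectories (which
have no rigid-body motion by construction) disable superposition. For
isotropic per-axis jitter σ the expected RMSF is σ·√3.

Minimum distances are exact all-pairs Euclidean minima per frame; the
within-cutoff fraction uses a strict `<` (boundary frames are a
measure-zero concern; the choice is documented here). Distance
distributions use a Gaussian KDE with automatic bandwidth by default; a
zero-variance series falls back to a narrow Gaussian at the repeated value.

Hydrogen bonds use the geometric criterion d(D–A) ≤ 3.5 Å and
∠(H–D–A) ≤ 30°, the defaults of the standard GROMACS detector; both cutoffs
are configurable. Donor atoms must carry at least one hydrogen (via the
atom table's `parent_donor` column) or detection raises, naming the atom.
Occupancy of a residue is the fraction of frames with any bond whose
non-ligand partner is that residue; simultaneity counts distinct partner
residues per frame, so two bonds to one residue do not count as
simultaneous. Heatmap binning requires the bin width to be a multiple of
the frame spacing and to divide the run length within one frame; category
boundaries place counts of exactly 10 and 20 in the middle (`10-20`) class.

## Synthetic data

Generators are pure functions of a `SyntheticSpec` (bit-identical per
seed) and each returns a ground-truth ledger computed from the construction
arithmetic, independent of the modules under test. Default class counts are
170/160/170 (active/moderate/inactive, 500 compounds) — a near-balanced
split at the dataset size the QSAR recovery property uses; contact
matrices default to 200 residues with a 10-residue reference,
p_active = 0.9, p_inactive = 0.3 (moderates at the midpoint 0.6), and
background rate q = 0.05. Activities are log-uniform over [1, 10⁶] nM,
expressed in randomly chosen convertible units. H-bond streams offer an
exact-planting mode (deterministic prefix placement, so occupancies and the
≥1/≥2 simultaneity fractions are the sorted planted counts) alongside
Bernoulli and 2-state Markov modes; exact modes exist so recovery tests can
assert equality rather than statistical closeness. Trajectories are Cα-only
with isotropic Gaussian jitter about fixed, well-separated means, plus a
single-atom ligand placed at an exact per-frame distance from the reference
residue's instantaneous position, so the within-5 Å fraction is planted
exactly. Chemspace fixtures are curated homologous series on aromatic
cores, valid by construction, rather than random molecular graphs.

What the generators do *not* emulate — real ChEMBL value distributions and
assay heterogeneity, correlated descriptor blocks, pose-dependent contact
correlations, anisotropic and correlated residue motion, solvent — bounds
what passing tests show: they demonstrate that each statistic recovers the
structure it claims to measure, not that the pipeline's scientific
conclusions transfer to any particular real dataset.

## Problem sizes

Recovery tests and the acceptance script use 500-compound × 200-residue
contact matrices (100 replicates for enrichment behaviour), 500-compound
descriptor tables, 10 000-frame jitter trajectories, and 1000-frame H-bond
streams — sizes at which every statistical property being asserted is
well-resolved while the full suite stays fast.

## Known limitations

Docking itself, pose generation, commercial descriptor sets, pocket-surface
analysis, and trajectory generation are out of scope; the package consumes
their text outputs. Binary trajectory formats are not read. The MCS pair
count for two real datasets depends on the (unstated) search algorithm and
parameters and is therefore not treated as a reproducible quantity.
t-SNE coordinates are deterministic per seed but not comparable across
library versions.
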