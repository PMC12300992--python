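# Methods

This note records the scientific and numerical choices behind the package,
in the order the pipeline runs them.

## Curation model

The curation module assumes an input of per-assay inhibition constants
(Ki, nM) with a relation symbol: `=` for point measurements, `>` for
censored lower bounds. The structural admission rules — molecular weight
≤ 800 Da, ≥ 15 heavy atoms, elements restricted to
[H, B, C, N, O, F, P, S, Cl, Br, I] — encode what a drug-like
enzyme-inhibitor series looks like and exclude fragments, polymers, and
organometallics. Salt stripping keeps the fragment with the most heavy
atoms (ties broken by molecular weight); mixtures without a
carbon-containing fragment are rejected.

**Replicate consistency.** Deviation is |x − mean| / mean computed on Ki in
nM (not on pKi). For two replicates the mean is kept only when both values
deviate from it by at most 25%; otherwise both are discarded. For three or
more, one pass removes values deviating by more than 25% from the initial
mean, and survivors are re-averaged. Two deliberate conventions: the pass
is *single* (not iterated to a fixed point — iteration can oscillate and
rarely changes the outcome on real replicate noise), and the 25% boundary
counts as "keep" in both branches. A cluster with no survivors is
discarded outright, paralleling the two-value discard branch.

**Representation identity.** Duplicate detection operates at the level the
models see: two structures are one compound iff all three bit fingerprints
are identical and the unscaled descriptor vectors coincide (Euclidean
distance ≤ 1e−9). This is deliberately blind to stereochemistry — an
enantiomer pair collides in every representation, so keeping both would
hand the model one feature vector with two labels. Grouping buckets by
canonical SMILES first and then merges buckets by the concatenated
fingerprint byte-strings, which keeps the comparison near-linear; exact
pairwise verification runs only inside hash buckets.

**Labeling.** pKi = 9 − log₁₀(Ki/nM). Defaults for the four isoform
thresholds are 6.30 / 7.30 / 7.30 / 7.45 (hCA I / II / IX / XII) with a
±0.25 exclusion band; for new targets the median of the merged pKi
distribution is offered instead. Censored `>` records are integrated after
thresholding: a bound Ki > X gives pKi < pKi(X), and the record becomes a
confident inactive only when that bound lies *strictly below* threshold −
band — comparing against the threshold alone would let band-zone compounds
re-enter through the back door. Censored inactives carry their bound, not
a point potency (`is_bound=True`).

**Split.** Per-class random 80/20, floor on the training side, seeded.
This preserves the active/inactive ratio between train and test within
one compound per class.

## Representations and scaling

Circular (Morgan, radius 2 ≙ four-bond diameter) and path fingerprints are
hashed to 2048 binary bits; counts are not used. The 881-bit substructure
keys are a fixed dictionary generated deterministically at import:
element-count thresholds, ring-size/aromaticity/heteroatom features,
bonded element pairs, linear element triples and quadruples, and a block
of named functional groups. The layout follows the CACTVS/PubChem key
philosophy (one predefined motif per bit) but is not bit-compatible with
the PubChem service; the dictionary is versioned
(`isoprofiler-keys-1`) and model bundles refuse to load across versions.

The descriptor representation is the full RDKit 2D descriptor list (210
names on the pinned toolkit; the contract is the recorded name list, not
the count — bundles store it and refuse mismatches). Min–max scaling is
fitted on the **training set only** and applied unclipped to test and
screening data; fitting on all data would leak test-set ranges into
training. Constant features map to 0.

Tanimoto similarity of two all-empty fingerprints is 0/0; the package
defines it as 0 with a warning, and the kernel assigns empty rows zero
similarity everywhere, including the diagonal.

## Models

The grids name standard ranges: SVM C ∈ {0.1, 1, 10, 100} × kernel ∈
{linear, poly(2,3), RBF, sigmoid, Tanimoto}; RF trees ∈ {100, 300, 500} ×
max-features ∈ {sqrt, log2, 0.3}; KNN k ∈ {1, 3, 5, 7, 9} × weights ∈
{uniform, distance}; GP kernels {DotProduct, RBF, Matérn(1.5, 2.5),
RationalQuadratic} + WhiteKernel, plus the Tanimoto kernel on bits. Grids
are fully overridable from the YAML config. Ties in grid search break
toward the earlier grid entry; grids list simpler settings first, so the
tie-break prefers the simpler model deterministically.

KNN uses Jaccard distance (1 − Tanimoto) on bits and Euclidean distance on
scaled descriptors, keeping the distance notion aligned with the kernel
used elsewhere. SVM probabilities come from the built-in Platt calibration
(internal CV, seeded); the decision-function alternative was rejected
because downstream screening consumes calibrated probabilities at a 0.5
cutoff. "10-fold CV" is implemented as ten repeated stratified 80/20
random splits (Monte-Carlo CV); a classic disjoint k-fold mode sits behind
a flag.

Training rows are sorted by canonical SMILES before any fit. This makes
fitted models — including RF bootstraps and SVM probability calibration,
which are otherwise row-order sensitive — exactly invariant to the order
in which compounds are supplied, and is what makes two seeded pipeline
runs byte-identical.

Fold scores with undefined MCC (a zero factor under the root) are NaN,
excluded from CV means with a warning — never silently zero, which would
bias model selection toward degenerate folds.

## Screening cascade

Stages are predicates applied in order; output is always a subset of
input, and every hit carries a replayable (stage, pass/fail) trace.
Lipinski is applied strictly (zero violations) because the cascade's
purpose is prioritization, not admissibility; the common ≤ 1-violation
variant is a constructor argument. PAINS, Brenk, BMS, and Inpharmatica
alerts come from RDKit's filter catalogs; the NIBR-style stage loads a
small synthetic stand-in SMARTS subset shipped with the package (the
published NIBR rules are not redistributable from any installed toolkit).
Toxicity endpoints and commercial availability are pluggable predicates
and allow-lists — external services are out of scope. The novelty filter
removes a hit iff its maximum Tanimoto similarity (881-bit keys) to the
*isoform-specific* training set exceeds 0.80 strictly; a hit at exactly
0.80 survives.

Experimental comparison labels a (compound, isoform) pair active iff
Ki < 1000 nM. Censored values `>X` with X ≥ 1000 are confident inactives;
`>X` with X < 1000 is uninformative and excluded with a log entry.
Fold-selectivity for a reference isoform is Ki(other)/Ki(reference);
censored off-isoform values propagate as lower bounds on the ratio, and
compounds with a censored reference Ki are skipped.

## Attribution

Per-bit Shapley values are estimated by exact telescoping along random
feature permutations against a background set (default: a seeded sample of
up to 100 training fingerprints). For each permutation and background row,
only features where the molecule and that row differ are walked, and the
model-output change at each switch is credited to the switched feature;
averaging over walks gives the values. Because each walk telescopes from
the background prediction to the molecule's prediction, additivity
(Σφ + base = prediction) is exact by construction, not approximate. Two
permutations with a modest background are sufficient for stable atom maps
on 2048-bit fingerprints because per-molecule Hamming distances to the
background are small (tens of bits).

Atom mapping is defined for circular fingerprints: each on-bit's footprint
is the union of the atom environments (center + radius ≤ 2) that hash to
it — collisions merge, since a bit's evidence is its full structural
footprint. The weight of atom *a* is
[Σ over on-bits f ∋ a of φ_f / |atoms(f)|] / r(a), where r(a) counts the
distinct on-bits covering *a*. The normalization order (per-bit footprint
division first, then per-atom occurrence division) is fixed; an
`occurrence_only` alternative is exposed for sensitivity analysis, because
the double normalization admits more than one reading. Atoms covered by no
on-bit have weight exactly 0. Off-bit values are computed (the explainer
sees the full vector) but only on-bits are mapped to atoms.

## Synthetic data: what it emulates and what it does not

The generator emulates the *shape* of a curated Ki extract for a
sulfonamide-dominated inhibitor series: combinatorially decorated
drug-like scaffolds (primary-sulfonamide actives, carbonyl/ether/nitrile
inactives, 15–35 heavy atoms), log-normal potency around class centers
±1.3 pKi from the threshold, replicate noise with a 10% coefficient of
variation, duplicate clusters of sizes 2 and 3 (including salt forms and
engineered discordant and outlier clusters whose merge outcome is known in
closed form), 8% band-zone compounds, 10% censored records (70%
informative), and a handful of structurally out-of-range molecules. Every
record's intended fate is written to a manifest that downstream tests use
as an oracle.

Defaults (n = 500 records for the curation study, n = 400 balanced for the
separable library) were chosen as the smallest sizes at which every
curation branch is exercised with double-digit counts and the 4 × 4 model
matrix trains in seconds.

What it does **not** emulate: real medicinal-chemistry diversity (one
scaffold family per class), assay heterogeneity across laboratories,
activity cliffs, or class overlap — the separable library is noiseless by
design, since its purpose is *recovery* testing (a correct implementation
must find the planted rule; near-perfect test MCC is expected, and says
nothing about performance on real extracts). Published benchmarks on real
ChEMBL extracts report held-out MCC around 0.7–0.8 for this problem;
reproducing those requires the original database snapshot and is out of
scope here.

## Determinism and provenance

One master seed per run fans out to per-stage seeds by fixed offsets
(fixtures +0, curate +1, train +2, …), all recorded in a `run_manifest.json`
alongside a config hash, input digests, and toolkit versions. The manifest
is the only output containing wall-clock time; every computational
artifact of a seeded rerun is byte-identical, and the acceptance suite
asserts this end-to-end.

## Known limitations

- The 881-bit key dictionary is internally consistent but not
  PubChem-bit-compatible; novelty thresholds calibrated on true PubChem
  keys may transfer imperfectly.
- The NIBR alert stage is a reduced synthetic subset, not the published
  rule set; its survivor counts will differ from tools shipping the full
  rules.
- Gaussian-process training is O(n³) in training-set size and is practical
  here only because datasets are small; on realistically sized extracts
  the SVM/RF arms are the usable ones.
- Attribution is defined for circular fingerprints only; path and key bits
  have ambiguous or trivially global footprints and are deliberately not
  mapped.
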