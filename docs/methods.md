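# Methods

`varmech` implements a structure-aware triage of protein missense variants
and a statistical screen for interaction-mediated control of protein
abundance. This note describes the models, the synthetic data that
exercises them, the numerical choices, and the limits of what the tests
demonstrate.

## Variant discretisation and mechanism triage

Each missense variant carries two scores: a sequence-based pathogenicity
score in [0, 1] (AlphaMissense-like) and a predicted folding free-energy
change ΔΔG in kcal/mol (FoldX-like, positive = destabilising). Scores are
discretised with fixed thresholds:

* pathogenicity: `< 0.34` benign, `> 0.564` pathogenic, otherwise ambiguous;
* stability: `< −2` stabilising, `> 2` destabilising, otherwise neutral.

Boundary values fall in the middle class: the thresholds are defined with
strict inequalities on both sides, so 0.34 and ±2 are ambiguous/neutral.
When a gene carries several somatic mutations in one sample, only the
variant with the highest pathogenicity score is retained (ties broken by
position, then alternate residue, for determinism).

A pathogenic variant receives exactly one primary mechanism in the
precedence order **stability → pocket → interface**: a destabilising ΔΔG
wins outright; otherwise membership of the variant position in any
high-confidence pocket residue set, then in any confident interface set;
otherwise `unclassified`. The precedence order is a genuine design choice
— overlaps between categories are possible and no canonical tie-break
exists — so it is configurable (`mechanism_precedence`), with the default
reflecting the fact that loss of stability is the most common
loss-of-function mode and the most reliably predicted. Two ΔΔG thresholds
coexist on purpose: 2 kcal/mol for triage and class labels, 1.5 kcal/mol
for the cis-pQTL destabilisation enrichment; both are config keys.

Structures arrive as PDB/mmCIF with per-residue confidence (pLDDT, 0–100)
in the B-factor field. Before stability-related analyses, low-confidence
regions are removed: a residue is dropped iff it lies in at least one
contiguous 10-residue window with mean pLDDT < 50; chains shorter than
the window are judged by their whole-chain mean. Trimmed residues are by
default also excluded from pocket/interface membership at triage time,
and from the pocket pLDDT average (`annotate_pockets(keep_masks=...)`).

## Pocket scoring

Pocket predictions arrive as cavity fill-point clouds with a raw composite
score (AutoSite-like, dimensionless, typically 0–1000). Pocket-associated
residues are those with any atom strictly within 4.5 Å of any fill point.
The confidence-weighted composite score is

    combined = raw × mean_pLDDT / 100

over the pocket-associated residues. The multiplicative form preserves
the raw score's scale, annihilates zero-confidence pockets, and is
strictly monotone in both inputs; it is isolated in one function
(`score_pocket`) so an additive alternative can be swapped in. The
high-confidence filter (`combined > 800` by default) lives in config; the
threshold is meaningful only relative to the raw-score scale of the
upstream pocket detector. Variant enrichment in pockets uses Fisher's
exact test on (variant vs not) × (pocket-associated vs not), either
pooled over the proteome or per structure, with Benjamini–Hochberg
correction across tests; score-binned enrichment uses quantile bins.

## Interfaces and pDockQ

Two interface definitions coexist deliberately:

* **annotation rule** (enrichment, clustering, triage): a residue is at
  the interface iff any of its atoms lies strictly within 5 Å of any atom
  of the partner chain;
* **pDockQ rule**: contacts are representative-atom pairs (Cβ, Cα for
  glycine, the single pseudo-atom in synthetic chains) within 8 Å.

pDockQ is the sigmoid

    pDockQ = L / (1 + exp(−k·(x − x0))) + b,   x = ⟨pLDDT⟩_interface × ln(contacts)

with L = 0.724, x0 = 152.611, k = 0.052, b = 0.018 (the published
constants of the score; kept in config). Zero contacts return the floor
b = 0.018; x = x0 gives L/2 + b = 0.380. Scores are binned poor
(< 0.23) / weak ([0.23, 0.5]) / confident (> 0.5), and when several
models exist for a pair the highest-pDockQ model is analysed.

Hub proteins (≥ 5 partners with confident models) are examined for
mutually exclusive binding: partner footprints on the receptor become a
binary partner × residue matrix, clustered with Jaccard distance and
average linkage, cut at distance 0.7. Metric, linkage and cut are not
canonical — they are config keys — but the combination has a convenient
property: identical footprints merge at distance 0, disjoint ones at 1,
so planted disjoint modes are recovered exactly. Distance comparisons
throughout are strict (`<`) in double precision; no rounding is applied.

## Abundance control screen

Per gene Y, protein level P_Y is modelled from transcript T_Y with
experimental batch C as indicator covariates:

    M0: P_Y = β0 + β1·T_Y + C·βC + ε
    MA: P_Y = β0 + β1·T_Y + β2·CNV_X + C·βC + ε

where CNV_X ∈ {−2…2} is the GISTIC-discretised copy number of a candidate
controlling partner X, entered as a single numeric covariate (matching
the single β2). Both models are ordinary least squares with Gaussian
maximum-likelihood variance (ML, not REML, so the χ² reference of the LRT
holds as written); LRT = 2(logL_A − logL_0) is referred to χ²(1), and
the identity LRT = n·log(RSS0/RSS_A) is computed alongside as a
cross-check. Only the X→Y direction with CNV of X is fitted — copy number
cannot be influenced by a partner's protein level, which is what makes
the test directional. BH-FDR < 0.01 flags significant control; positive
β2 is the attenuation signature.

Preprocessing mirrors standard proteogenomic practice: samples with more
than 500 mutations are dropped; genes need ≥ 25 % non-missing coverage in
all three modalities; mRNA and protein are batch-normalised and genes
with batch-corrected mRNA–protein Pearson r < 0.3 are removed (the
concordance filter runs on corrected values — a deliberate choice, since
batch structure otherwise dominates the correlation). Batch
normalisation is the map x ↦ (x − batch mean) − batch median of the
centred values, i.e. regression on batch indicators followed by
conversion to log fold changes against the batch median; the composite
map is exactly idempotent, so re-running `preprocess` is a no-op. Model
fits use complete-case (pairwise) deletion. Residual comparisons across
variant classes (pathogenicity × stability × copy-number stratum, with
GISTIC −1 = loss, ≥ 0 = compensated, −2 excluded because the protein is
absent) use two-sided Mann–Whitney tests against the benign/neutral
reference of the same stratum; the reference is per-stratum so that
copy-number effects cannot masquerade as variant effects.

## Synthetic data

The generators produce every input with planted truth, emitted separately
from the data; no analysis stage reads the truth.

* **Proteomes** — pLDDT profiles are smoothed Gaussian noise clipped to
  [60, 98]; with probability `low_conf_rate` a protein receives one
  contiguous stretch (12–30 residues) drawn from [22, 45], which a
  10-residue mean < 50 always detects. Pocket and interface truth sets
  are planted on confident residues.
* **Chains** — one pseudo-atom (CB) per residue at 9 Å spacing along a
  line. The spacing is unphysical on purpose: it guarantees that a
  planted contact at 4 Å is the *only* inter-chain pair below 5 Å while
  all others exceed 8 Å, making interface recovery exactly checkable. All
  distance code operates on atoms, so these chains exercise the same
  paths as full-atom input.
* **Variants** — pathogenicity scores are a two-component mixture with
  each component strictly inside its class (benign < 0.34, pathogenic
  > 0.564); a stated fraction of pathogenic variants draws
  ΔΔG = 2 + Exp(1.5) (destabilising), the rest stay in (−2, 2);
  pathogenic variants land on planted functional residues with
  configurable odds.
* **Hubs** — 14 partners by default, footprints partitioned into disjoint
  mode regions; each partner keeps a random (1 − overlap/2) fraction of
  its mode footprint, so same-mode footprints share ≥ (1 − overlap) while
  cross-mode footprints stay disjoint.
* **Multi-omics** — CNV is i.i.d. GISTIC with frequencies
  (0.02, 0.18, 0.60, 0.18, 0.02) for (−2, −1, 0, 1, 2) — the discretised
  scale has defined semantics but no canonical frequencies, so these are
  config values chosen to keep ±2 rare; T = 0.5·CNV + batch + N(0, 0.5);
  P = 0.8·T + β2·CNV_X + batch + N(0, 0.5); batch offsets are N(0, 0.3)
  per gene and batch; missingness is injected completely at random at
  5 %. Noise is Gaussian throughout, matching the Gaussian OLS/χ²
  assumptions of the screen. Optional mutation planting shifts the
  protein value of pathogenic + destabilising events by a stated amount.

What the generators do **not** emulate: realistic protein geometry,
AlphaFold failure modes other than low-pLDDT stretches (spurious pockets,
paralog-confused interfaces), correlated CNV segments, non-Gaussian
proteomics noise, or informative missingness. Passing tests therefore
demonstrate correctness of the statistical and geometric machinery under
its stated assumptions, not performance on real cohorts.

## Numerical choices and calibration

* The LRT is computed twice per fit (log-likelihood difference via normal
  log-densities at σ̂²_ML, and n·log(RSS0/RSS_A)); the evaluation battery
  verifies agreement to 1e-8 over 1,000 random instances.
* A numerically perfect null fit (RSS0 ≤ 1e-12·n) short-circuits to
  LRT = 0, p = 1; a perfect alternative fit with imperfect null returns
  LRT = ∞, p = 0. Constant CNV on complete cases is flagged degenerate
  (LRT 0, p 1).
* The χ²(1)-referenced LRT is mildly anticonservative in finite samples:
  at n = 200 the null fraction of p < 0.05 is ≈ 0.053–0.055 rather than
  0.050 (the classical O(1/n) inflation; an F-test would remove it but
  the χ² reference is the model's definition). BH-FDR at 0.01 absorbs
  this comfortably — measured mean false-discovery proportion is ≈ 0.01.
* Fisher's exact test reports the sample odds ratio ad/bc (∞ when bc = 0
  and ad > 0) with the minimum-likelihood two-sided p by default;
  directional enrichments (cis-pQTL) use the one-sided test.
* Tie-breaks everywhere are deterministic and documented: worst-variant
  selection by (score, position, alternate residue); pocket ranking by
  (score, protein, pocket id); best-model selection by input order.

## Problem sizes of the evaluation battery

The reproduction script (`scripts/acceptance.py`) and the end-to-end test
module run: 1,000 random LRT instances; 2,000 null pairs at n = 200 for
calibration; 200 replicates of 900 null + 100 alternative pairs at
n = 300 for FDR/sensitivity; 500 replicates for β2 recovery; 100 random
models for the distance oracles; 100 hubs for mode recovery; 100
simulations for the residual-shift detection. These sizes put Monte Carlo
error well below the asserted margins while keeping the full battery in
the minutes range on one core.

## Known limitations

* The screen tests one partner at a time; co-amplified partners or shared
  complexes induce correlated tests that BH handles only approximately.
* The composite pocket score's functional form is a package choice; only
  its monotonicity and limiting behaviour are guaranteed, not equivalence
  to any external tool's internal benchmark.
* Interface-mode clustering depends on the flat-cut threshold for
  footprints with intermediate overlap; recovery guarantees hold for
  overlap ≤ 0.2.
* The CLI handles single-model, two-chain PDB input; assemblies beyond
  two chains and mmCIF writing of multi-assembly files are out of scope.
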