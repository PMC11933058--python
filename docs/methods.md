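# Methods

This note documents the models and procedures behind each triage dimension,
the defaults and why they were chosen, what the synthetic fixtures do and do
not emulate, and the numerical conventions.

## Sequence identity

All sequence comparisons use one global aligner: match 1, mismatch 0, linear
gap penalty −1 (Needleman–Wunsch via Biopython's `PairwiseAligner`). The
reported quantity is *identity*, not similarity: matches divided by alignment
length, so gaps count against the denominator. On equal-length pairs whose
optimal alignment is gap-free this reduces to (L − mismatches)/L, which makes
the uniqueness thresholds exact arithmetic: 80% identity on a 250-residue
VH+VL concatenation is 50 differences, and on a 50-residue six-CDR
concatenation 10 differences. At high divergence (roughly > 15%
substitutions) the aligner may prefer a gapped alignment with more matches,
so the closed form is a lower bound there; the identity itself remains
well-defined.

The `full` mode compares VH+VL concatenations (the wording "differences
between two full-length VH-VL pairs" reads as one concatenated comparison,
which is what is implemented); `cdr6` compares the H1..L3 concatenation.
Sequences containing X are rejected by default (`allow_x` admits them; X
never matches anything).

## CDR delimitation

Kabat spans are located through framework anchors rather than a full
numbering: the first intra-domain cysteine (Kabat H22/L23), the tryptophan
closing CDR-H1/L1 (H36/L35), the second cysteine (H92/L88) and the J-segment
WGxG / FGxG motifs. CDR-H2 is taken as the 16 positions Kabat 50–65 starting
14 residues after W36; CDR-L2 as the 7 positions starting 15 after W35.
Kabat insertion bookkeeping (35A/B, 52A–C, 82A–C, 100A–K) is not modelled:
the anchor rules reproduce the textbook Kabat spans on the bundled
IGHV3-23-like / IGKV1-39-like scaffolds and on any chain whose framework
lengths match them, which covers every sequence the synthetic generator can
emit. Chains whose anchors cannot be found raise an annotation error naming
the chain. Kabat was chosen because CDR-based identity claims in the patent
literature are historically Kabat-based.

## PTM liability model

Motif classes and patterns: N-glycosylation N-X-S/T and N-X-C (the classical
X ≠ P exception is off by default for fidelity to the plain sequon table and
available as an option), K-D/E glycation, N-G/S/D/T/H deamidation,
D-G/S/N/T/H isomerization, D-P cleavage, and the context-free single residues
M, W (oxidation) and C (hydrolysis). The liable residue is the first of the
match; overlapping motifs are all reported, once per class per position. A
motif is *not* a prediction of modification — risk is modulated by two
layers:

- **Exposure.** Relative side-chain accessibility is binned low (rsa ≤
  0.30), medium (0.30 < rsa ≤ 0.60), high (rsa > 0.60); half-open bins make
  the three tiers a partition of [0, 1]. The headline "exposed motif count"
  counts sites with rsa > 0.30 and excludes lysine glycation sites, which are
  too numerous to be informative (they stay in the full site list).
- **Germline conservation.** A site is lower-risk when the same motif class
  matches at the aligned position of the assigned germline; positions falling
  in insertions are conservatively treated as not conserved (with a logged
  warning).

## Coarse surface model

A structure is reduced to one bead per residue: the side-chain heavy-atom
centroid, or Cα for glycine and side-chain-less residues (alternate locations
take conformer A). Bead radii derive from standard side-chain volumes,
r = (3V/4π)^⅓.

**RSA.** Shrake–Rupley-style sphere sampling (512 Fibonacci points, probe
1.4 Å) on the bead spheres. In a one-bead representation nothing but
neighbouring residues occludes a side chain, so the per-residue-type maximum
of the usual Gly-X-Gly convention is the isolated bead's full accessible
sphere, and the accessible-point fraction *is* the relative accessibility (an
isolated residue scores exactly 1). The implementation agrees with an
independent Shrake–Rupley code (Bio.PDB) to < 5% mean absolute deviation on
fixture panels (measured ≈ 0.4%).

**Centroids.** Surface residues (rsa > 0.05; the low cut keeps loop residues)
are partitioned into N centroids by seeded k-means on the bead coordinates;
N defaults to 150 for a full Fv and is configurable within the 50–250 band
(smaller toys use proportionally smaller N). Centroid positions are member
means; the partition property (every surface residue in exactly one centroid)
is exact by construction and asserted in tests.

**Properties.** Per centroid: hydrophobicity = RSA-weighted mean
Kyte–Doolittle value of members (exposure weighting reflects that only the
displayed surface matters); charge = Σ member formal charges (D/E −1, K/R +1,
His 0 at the implied neutral pH); potential = Σ over non-member charged
residues of q·332/(ε(r)·r) with the fast screening dielectric ε(r) = 4r
(kcal·mol⁻¹·e⁻¹; distances clamped at 1 Å); curvature = signed inverse radius
of the algebraic least-squares sphere fitted to the surface neighbourhood
within 10 Å, positive when the sphere centre lies on the protein-interior
side (convex). Neighbourhoods with < 4 points, or coplanar to within 0.15 Å
(where the algebraic fit is ill-posed), report curvature 0. Analytic limits
— +1/R on a sphere, 0 on a plane, Coulomb superposition linearity — are
asserted in tests.

**Patches.** For thresholding, hydrophobicity and curvature are compared as
signed values (hydrophobic and convex ends are the risky ones) and charge and
potential as magnitudes (either sign of a strong patch matters). Thresholds
are quantiles of the pooled reference-panel centroid values — moderate = 93rd
percentile, intense = 99th — and a patch must span at least 3 mutually
adjacent (≤ 10 Å) extreme centroids. The original two-tier intent was a 90th
/ 98th split, but with ~10% of centroids hot by construction, chance
adjacency produces spurious "patches" on most structures; the calibrated
defaults leave unplanted fixture shells patch-free on 97/100 seeds while
recovering ≥ 80% of the membership of planted 15-residue caps.

## Aggregation (anomaly) model

Each structure maps to a fixed 20-vector: for each of the four properties,
the mean, sd and max of the centroid values on their thresholding scale plus
the largest-patch residue count and the patch count. An isolation forest
(100 trees, subsample min(256, n), mandatory seed) is trained on a reference
panel; the exposed score is the standard anomaly scale 2^(−E[h(x)]/c(ψ)) ∈
(0, 1], higher = more anomalous, ≈ 0.5 for unremarkable points. A candidate
is flagged when its score exceeds the reference-panel mean by more than 2
standard deviations (strict inequality). The reference distribution defaults
to the training panel's own scores; a separate panel can be supplied.
Scoring always runs through the package's own tree traversal (verified to
reproduce scikit-learn's `score_samples` to machine precision), so the JSON
persistence (serialised tree arrays + schema version) round-trips to
identical scores. Scores are comparable only within a feature-schema version
and a training panel; the absolute scale is not comparable across tools.

## Humanness

Score = fraction of a chain's overlapping 9-mers present in the 9-mer set of
a human reference panel. The model is deterministic, trainable from any
sequence collection, monotone in reference coverage (duplicating reference
sequences changes nothing), exactly 1 on reference members and near 0 on
random sequences. k = 9 balances specificity (chance 9-mer collisions are
negligible) against tolerance of isolated substitutions. The warning floor
in the triage pipeline is the midpoint of the human and non-human fixture
score means, computed at configuration time.

## Off-target search

Similarity of two antibodies = 100 × Σ(wᵢ·idᵢ)/Σwᵢ over the six CDR pairs,
where idᵢ is the per-CDR global-alignment identity and the weight wᵢ is that
alignment's length — so H3 dominates naturally and the weighting scheme
matches the identity denominator. Hits are grouped per distinct target
(best-scoring record kept, supporting ties recorded), the query's intended
target is excluded by exact name, results are filtered at a minimum score
(default 40) and tiered high (≥ 70, configurable policy) or medium, and the
2×2 tier × human/non-human profile is reported.

## Interface scoring

No docking: a candidate is rigidly superposed (Kabsch, proper rotation
enforced) onto the reference antibody's bound orientation, using
correspondences from per-chain sequence alignment (≥ 20 alignable positions
required). Facing pairs are centroid pairs within 8 Å (configurable; the
scale of one coarse region). PCC is the mean per-pair complementarity: +1
when both centroids are hydrophobic (above the moderate hydrophobicity
threshold), +1 for opposite-sign net charges, −1 for same-sign charges, terms
summed per pair — salt bridges and hydrophobic packing score favourably,
charge clashes unfavourably; the form is symmetric under swapping the two
sides. IR counts facing pairs (a documented alternative merges adjacent
pairs into contiguous regions). The C-score is panel-relative: the mean of
min-max-normalised PCC and IR within the candidate panel (degenerate spreads
map to 0.5; a candidate with no contacts has undefined PCC and receives the
panel-worst normalised value 0). Epitope/paratope maps list residues of
facing centroids within the cutoff of the other side; competition between two
antibodies is predicted when the Jaccard overlap of their epitopes reaches
0.25 (reported alongside the raw overlap).

## Synthetic fixtures — what they emulate, and what passing tests show

The generator module defines the study conditions for every test:

- **Germlines**: 12 heavy + 12 light synthetic human-plausible V-domains
  derived from IGHV3-23-like / IGKV1-39-like templates with diversified CDRs,
  pairwise ≥ 21 substitutions apart so that a query with ≤ 10 somatic
  mutations is always nearest its true germline. Bundling synthetic scaffolds
  avoids redistributing curated germline databases.
- **Fv panels**: germline pairs + uniform substitutions at non-anchor
  positions (default 0–10 per chain, the observed somatic-drift magnitude)
  + planted PTM motifs at recorded positions.
- **Toy structures**: 230-residue perturbed ellipsoidal bead shells
  (surface-dominated geometry, ~4 Å bead spacing) with planted hydrophobic /
  charged surface caps. They exercise operator correctness — partitioning,
  patch recovery, pose recovery — not folding physics; a pass says nothing
  about modelling accuracy on real Ig domains.
- **Binding scenario**: an antigen with a charged/hydrophobic epitope cap, a
  complementary reference antibody in contact, one jittered true binder and
  three decoys whose defects survive framework superposition (a rigid
  rotation would be undone by alignment, so decoys instead flip paratope
  charges, retract the paratope, or relocate the paratope chemistry to the
  opposite pole).
- **Reference sets**: a 200-record target-annotated antibody database and
  735-value benchmark distributions (exposed-motif counts ~ N(8, 3) clipped
  at 0, CDR total length ~ N(58, 5), CDR total charge ~ N(0, 3) — plausible
  clinical-stage magnitudes).

Every generator is a pure function of spec + seed (byte-identical reruns),
and ground truth is emitted alongside.

- **Checkpoint domains**: the IgV ectodomains of human TIM3 (UniProt Q8TDQ0,
  residues 22–131) and TIGIT (Q495A1, 22–141) are bundled as a small FASTA
  for the cross-checkpoint identity check; under the package's gap-penalised
  identity they align at ~16%, consistent with the very low sequence identity
  of the two V-set folds.

## Numerical conventions and degenerate inputs

Ties in nearest-neighbour searches resolve to the first database record;
k-means and the forest take mandatory seeds; patch output order is
deterministic (size, then smallest centroid id); report JSON is written with
sorted keys so full pipeline reruns are byte-identical. Degenerate cases are
explicit: empty databases, unannotated queries, zero-spread reference
distributions, zero facing pairs and oversized patch plants all raise typed
errors rather than guessing.

## Problem sizes

Defaults used by the test suite and the acceptance script: 25–30 reference
structures for thresholds and the forest, 60 centroids on 230-residue toys,
50 anomaly-recovery trials, 100 ranking trials, 1,000 scanner-oracle
sequences — sizes at which every stochastic check is stable across seeds
while the whole suite runs in about a minute.

## Known limitations

- The anchor-based Kabat rules assume standard framework lengths; heavily
  engineered scaffolds or unusual J segments may fail annotation (by design,
  loudly).
- The one-bead surface model cannot resolve sub-residue chemistry; RSA,
  patches and the anomaly score are screening-level quantities.
- The electrostatic model is a screened Coulomb sum, not Poisson–Boltzmann.
- Humanness is a containment score against whatever reference it is given;
  it is not a T-cell epitope (immunogenicity) predictor.
- PCC/IR/C scores rank poses within a panel; they are not binding free
  energies and have no physical units.
- Off-target tiers (high ≥ 70) are explicit, configurable policy — the score
  is a similarity, not a calibrated binding probability.
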