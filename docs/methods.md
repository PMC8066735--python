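# Methods

## Problem and model

`plantloc` predicts the subcellular localization of plant proteins over 11
compartments (plastid, cytoplasm, extracellular, nucleus, mitochondrion,
cell membrane, Golgi, ER, vacuole, peroxisome, cell wall). The problem is
multiclass *and* multilabel: a minority of plant proteins reside in two
compartments, and the observed dual classes are pairs
(mitochondrion+plastid, cytoplasm+nucleus, cytoplasm+Golgi).

Each protein is encoded as a fixed, ordered vector of 479 features:

| block | size | content |
|---|---|---|
| AAC | 20 | amino-acid composition |
| APAAC | 30 | amphiphilic pseudo composition, λ=5, w=0.1 |
| Blosum | 8 | mean projection on BLOSUM62 components |
| CTDC/CTDT/CTDD | 21/21/105 | grouped composition, transition, distribution |
| Geary | 40 | autocorrelation, 4 properties × lags 1..10 |
| PAAC | 30 | type-I pseudo composition, λ=10, w=0.1 |
| PsePC | 22 | type-I pseudo composition, λ=2, w=0.05 |
| PseSC | 26 | type-II pseudo composition, λ=2 × 3 properties, w=0.05 |
| scalar/scale | 57 | charge, Boman-type, aliphatic, covariance indices, hydrophobic moments, instability, pI, and 8 multi-dim scale projections |
| QSO/SOCN | 60/20 | quasi-sequence-order under two distance matrices, nlag=10 |
| external | 18 | sorting-signal/tool scores (cTP, mTP, SP, TM, other, NLS, ER score, 5 sub-mitochondrial SVM scores, 6 conformation propensities) |
| Homology | 1 | GO-homology compartment code (0 = no hit) |

Three base classifiers are fitted on identical rows and features:
inverse-distance-weighted KNN with k = 12 on features standardized by
training-fold mean/sd, a 100-tree random forest, and gradient boosting with
50 rounds, maximum depth 5, learning rate 0.1 and multiclass log-loss. The
consensus is the unweighted mean of the three class-probability vectors
(average voting). The top-consensus compartment is always called; the
runner-up is added when its consensus probability reaches the threshold
θ (default 0.30), so a near-tie (≈0.45/0.40) yields two labels while a
dominant winner yields one. At most two labels are ever emitted, matching
the observed dual classes.

Dual-location training proteins are duplicated, once per constituent
compartment, before base-model fitting (`duplicate` policy); a `pair-class`
policy (pairs as temporary extra classes whose probability is split back
onto the constituents at prediction) is available for comparison. The
duplicate default reflects that the base learners are configured with 11
target classes.

## Pseudo-composition parameter pinning

The four pseudo-composition blocks share one λ/weight convention but the
printed block sizes force the λ per block: PsePC (22 = 20+λ) → λ=2,
PseSC (26 = 20+λ·Λ, Λ=3 properties) → λ=2, PAAC (30 = 20+λ) → λ=10,
APAAC (30 = 20+2λ) → λ=5. Weights follow the 0.05 (λ=2 blocks) / 0.1
(PAAC/APAAC) convention of the pseudo-composition literature. The
correlation properties are the canonical triplet — Kyte–Doolittle
hydrophobicity, Hopp–Woods hydrophilicity, side-chain mass — standardized
over the 20 residues (population SD).

## Property data: genuine tables and synthetic surrogates

Scalar per-residue tables (Kyte–Doolittle, Hopp–Woods, Vihinen flexibility,
Emini accessibility, Janin and Guy transfer energies, Eisenberg consensus
hydrophobicity, the instability dipeptide weights) come from Biopython;
side-chain masses, heavy-atom counts and pH-dependent charges are computed
from standard residue chemistry. The CTD groupings are the standard
7-property, 3-group partition of the grouped-descriptor literature, shipped
as data.

The nine multi-dimensional scale families (Cruciani, FASGAI, MS-WHIM,
protFP, stScales, tScales, VHSE, zScales; 3/6/3/8/8/5/8/5 components) are
**synthetic surrogates**: fixed orthogonal rotations of the principal
components of an 11-property matrix of the genuine per-residue values
above. They reproduce each family's dimensionality and overall
hydrophobic/steric/electronic character without transcribing the published
numeric tables, which are not redistributable here; the `Blosum` block is a
principal-component decomposition of the real BLOSUM62 rows. The two
residue distance matrices behind QSO/SOCN are likewise computed: Euclidean
distance in the standardized hydrophobicity/hydrophilicity/mass space, and
in the BLOSUM62 component space, each normalized to max 1. Downstream code
treats all of these as opaque `PropertyScale` data, so substituting
published tables only means editing `plantloc/scales.py`.

Consequences: block sizes, orderings and all algorithmic behaviour match
the schema exactly, but individual scale-projection *values* are not
comparable to outputs of the R packages that popularized these families.

## Numerical conventions

- **CTDD percentile rule**: position of the ceil(q·count)-th occurrence of
  a group, as 100·pos/length; an absent group contributes five zeros.
- **CTDT normalization**: transition counts are divided by the number of
  group-changing adjacent pairs, so the three pair rates per property sum
  to 1 whenever any transition exists (all-zero otherwise). The common
  alternative divides by L−1; the sum-to-1 contract was chosen and is
  pinned by tests.
- **Geary degenerate case**: zero-variance (e.g. homopolymer) input yields
  c(k)=1, the no-autocorrelation fixpoint; the variance test uses a
  rounding-safe threshold (sum of squares < 1e-12·L).
- **Instability index**: the published dipeptide-weight formula,
  10/L · Σ DIWV, via Biopython.
- **pI**: bisection of the net-charge curve on [0, 14] to 1e-4 pH, with an
  EMBOSS-style pKa set (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1,
  H 6.5, K 10.8, R 12.5, Y 10.1). Determinism and testability (an
  independent grid-scan oracle) motivated fixing one pKa table.
- **Hydrophobic moments**: Eisenberg scale, maximum over an 11-residue
  sliding window (full sequence when shorter), angles 100° (helix) and
  160° (sheet).
- **Auto/cross-covariance**: lagged mean products of standardized
  hydrophobicity/hydrophilicity values, averaged over lags 1..10; the two
  cross terms use the two lag directions.
- **Minimum length**: sequences shorter than 11 residues are rejected for
  extraction (sequence-order descriptors with nlag=10 are undefined below
  nlag+1).
- **Ambiguous residues**: default policy maps U→C, O→K, B→N, Z→Q, J→L and
  drops X; `drop-residue` and `reject` policies are available.
- **Serialization**: feature tables round-trip as TSV at 12 significant
  digits.

## Feature selection

- **ReliefF**: all instances sampled by default, k=10 neighbors,
  min-max-scaled diffs, misses weighted by class prior over the complement;
  a class with fewer members than k reduces k with a warning. Weights lie
  in [−1, 1]; constant features score exactly 0.
- **OneR**: equal-frequency discretization (10 bins, distinct-value bins
  for low-cardinality features); score = training accuracy of the
  majority-class-per-bin rule.
- **CFS + genetic search**: merit k·r̄_cf / √(k + k(k−1)·r̄_ff) with
  symmetric-uncertainty correlations on discretized variables, maximized by
  a bitmask GA (population 50, 100 generations, uniform crossover 0.6,
  bit-flip mutation 0.02, tournament size 3, elitism 1, seed required).
  With elitism the best merit is non-decreasing over generations.

  Note an algebraic identity: for a subset of m exact copies of one
  feature, r̄_ff = 1 and the merit collapses to m·r̄_cf/√(m²) = r̄_cf — a
  perfectly redundant copy never *raises* merit but does not strictly
  lower it either; the strict penalty appears for irrelevant additions
  (lower r̄_cf) and the reward for complementary ones (low r̄_ff). Tests
  pin both directions.

- Subset sizes for the ranking methods are user-chosen (`--top-n`,
  default 95); published subset sizes from comparable studies are
  empirical outcomes of their data, not a rule.

## Evaluation

A record is correct iff the predicted label set equals the true set — a
dual-location protein must have both compartments called; subtotals are
reported for single-label, dual-label and pooled records. One-vs-rest
tallies count a dual record as a positive of each true compartment.
ACC/Sn/Sp/MCC follow the standard confusion-matrix formulas with MCC = 0 on
a vanishing denominator factor. AUC is the midrank Mann–Whitney statistic
per class, macro-averaged across classes that occur. Report rows carry a
record-level MCC of the exact-set indicator.

Cross-validation stratifies by exact label set, shuffled with the run seed;
selection (when requested) is re-fitted inside each training fold. When
every stratum is smaller than the fold count (e.g. leave-one-out), the
split degrades to unstratified folds with a warning.

## Synthetic data: what it does and does not emulate

The generator plants, per compartment, (a) a composition signature — three
residues boosted by +0.06·s each over a UniProt-like background, s =
`signal_strength` ∈ [0,1]; (b) for plastid, mitochondrion, nucleus and cell
membrane, sorting-signal-like motif blocks (N-terminal R/S- or R/L-rich
stretches, an internal K/R block, a 19-residue hydrophobic block) inserted
with probability s; and (c) mock external scores whose designated channels
(e.g. cTP for plastid, NLS for nucleus) are Beta-shifted toward high values
at strength s. Dual-location records draw from the 50/50 mixture of their
parents' compositions and carry both parents' score biases. Default class
counts follow the imbalance shape of curated plant datasets at reduced
scale (plastid 100 … cell wall 8, three pair classes; 569 records), chosen
to keep a full 10-fold CV of the ensemble in the tens of seconds on one
CPU. The `null` fixture is balanced (20 per class) and signal-free, so
chance level is exactly 1/11.

What passing tests therefore show: the encoder, selectors, ensemble and
metrics recover planted, learnable structure and sit at chance when none
exists. What they do not show: performance on real proteomes — real transit
peptides, domain structure, homology families and realistic class overlap
are all absent from the generator, and the mock external scores are far
cleaner than real predictor outputs.

## External tools and the homology feature

The 18 external scores are consumed, never recomputed: a TSV file or the
mock provider supplies them. The single homology feature maps the best
similarity hit in a small user-annotated reference through a fixed 27-term
cellular-component GO map (sub-compartment terms map to their parent;
generic "membrane" maps to cell membrane) to a compartment code 1–11, with
0 when no hit passes the e-value cutoff (default 1e-5). The bundled search
backend ranks references by edit-distance similarity and emits a heuristic
e-value surrogate — adequate for tests and toy references; a real
BLAST-based backend can be plugged in through the same
`search(query) -> [(hit_id, evalue)]` contract. Multiple GO terms per hit
are resolved by taking the first term that maps to a compartment.

## Known limitations

- Surrogate multi-dimensional scales and distance matrices (above): per-value
  comparability with the published scale families is deliberately out of scope.
- The dual-label threshold θ=0.30 is a design choice, not a fitted value;
  sweep it against validation data before production use.
- The mock score provider's channel map is stylized; real TargetP/SignalP
  outputs correlate with more than one compartment.
- No probability calibration, stacking, or imbalance resampling.
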