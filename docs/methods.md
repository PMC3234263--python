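# Methods

## Problem and model

Given the 3D structure of a protein known (or suspected) to bind DNA, the
package predicts which of its surface residues contact the DNA. The method
combines four ideas:

1. **Surface and binding definitions.** A residue is a *surface residue*
   when its all-atom accessible surface area (ASA) is at least 10% of the
   maximum attained by that residue type in an extended ALA-X-ALA
   tripeptide; thresholds are inclusive. In a protein-DNA complex, a
   surface residue is a *binding residue* when any of its heavy atoms lies
   within 4.5 Å (inclusive) of any DNA heavy atom; the remaining surface
   residues are nonbinding. ASA for the surface rule is always computed on
   the isolated protein chain (DNA and all other chains removed), so that
   DNA-bound and DNA-free forms of the same protein receive identical
   surface annotations — the prediction task assumes the partner is
   unknown.

2. **Surface patches with distance-dependent weights.** For each surface
   residue (the *central* residue), its Cα distances to all other surface
   residues of the same chain are sorted ascending and the nearest L − 1
   join it in a *surface patch* (L = 25 by default; ties broken by
   ascending sequence index). Each member i at distance d_i receives a
   weighting factor w_i ∈ (0, 1], equal to 1 for the centre and strictly
   decreasing with distance. Patch features are weighted averages
   Σ w_i·x_i / Σ w_i, so nearer neighbours contribute more.

3. **A reduced 43-dimensional feature vector** per surface residue:
   - *RW-PSSM* (40): the central residue's 20 logistic-scaled PSSM
     log-odds (x → 1/(1+e^(−x))), then 20 per-column weighted averages
     over the patch **neighbours** (centre excluded from the averaged
     block, since its raw row already occupies the first block). Patches
     without neighbours get zeros in the averaged block. The length is 40
     regardless of L — unlike the concatenated C-PSSM encoding (20·L
     values, zero-padded), which is kept for comparison experiments.
   - *WIP* (1): weighted patch average of per-type interface propensity
     IP_a = log2[((N_Ba+ψ)/(N_B+20ψ)) / ((N_NBa+ψ)/(N_NB+20ψ))], a
     symmetric-pseudocount (ψ = 1) log-odds of amino-acid type a among
     binding vs nonbinding surface residues. Positive ⇔ interface-enriched;
     label swap exactly negates every value.
   - *WBC* (1): weighted patch average of normalized betweenness
     centrality on the Cα contact graph (edges at ≤ 8 Å), normalized by
     (n−1)(n−2)/2 over unordered pairs; unreachable pairs contribute 0.
   - *ScASA* (1): the central residue's own side-chain ASA (side-chain
     atoms including the alpha carbon), unweighted.
   WBC, WIP (and the optional WScASA) all share one weighted-average
   operation that **includes** the central residue in the sum.

4. **Class-imbalanced SVM protocol.** Binding residues are ~15% of
   surface residues, so training uses all positives plus an equal number
   of negatives sampled without replacement; test sets keep their natural
   imbalance. Cross-validation splits at the chain level (5 folds, sizes
   differing by at most one chain); per fold, the propensity table and
   the balanced sample are rebuilt from the four training folds only, and
   feature columns are z-scored with training-fold statistics before an
   RBF-kernel SVM (C = 1, γ = 1/43) is fitted. Evaluation reports recall,
   precision, F1 (0/0 → 0) and the area under the precision-recall curve.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| surface RSA threshold | 0.10 | inclusive fraction of tripeptide max ASA |
| binding cutoff | 4.5 Å | inclusive heavy-atom distance to DNA |
| contact cutoff | 8 Å | Cα-Cα edge threshold of the contact graph |
| patch size L | 25 | central residue + 24 nearest surface residues |
| weighting scheme | reciprocal | w = 1/(1+d); see below |
| pseudocount ψ | 1 | propensity smoothing; keeps IP finite and antisymmetric |
| probe radius | 1.4 Å | solvent probe for ASA |
| sphere points | 960 | Shrake–Rupley lattice size per atom |
| SVM C, γ | 1, 1/43 | cost and kernel width on z-scored features |
| decision threshold | 0 | on the signed SVM decision score |

**Weighting-scheme choice.** The original description of the weighting
factor constrains only its properties (maximum 1 at d = 0, decreasing
with distance), not its algebraic form. The package ships three schemes
satisfying the constraints — `reciprocal` w = 1/(1+d) (default),
`exponential` w = e^(−d/σ) (σ = 5 Å), and `linear` w = 1 − d/d_max
(d_max = 50 Å, valid for d < d_max) — selectable by configuration;
all downstream code is scheme-agnostic. The reciprocal form is the
default as the simplest parameter-free choice.

**Eq-ambiguity conventions.** The RW-PSSM weighted average normalizes by
Σ w_i (a true weighted mean), with the centre excluded from the averaged
block; WBC/WIP/WScASA include the centre. With a constant weighting
scheme the weighted average reduces to the arithmetic mean, and any
weighted average lies within [min, max] of its inputs.

## Numerical choices

- **ASA** is computed by the Shrake–Rupley method: each heavy atom's
  solvent-expanded sphere (van der Waals radius + probe; C 1.76, N 1.65,
  O 1.40, S 1.85, P 1.90, else 1.80 Å) carries a 960-point golden-spiral
  lattice, and a point is accessible when outside every other expanded
  sphere. Each atom's lattice is given a deterministic random orientation
  (fixed internal seed), because a shared orientation correlates with
  molecular symmetry axes and biases the boundary discretization.
  Measured accuracy against a 10×-density brute-force reference: ≤ 0.8%
  per residue for pairwise-occlusion geometry; typical 0.5% and worst
  ≈ 1.5–2% per residue for deeply grooved compact packing. Doubling the
  point count moves residue values by < 1.5% (pairwise) to < 2% (compact).
  Hydrogens never enter ASA or distance rules.
- **Reference maxima**: all-atom ALA-X-ALA tripeptide maxima
  (Hubbard–Thornton values as distributed with NACCESS) are bundled; only
  the all-atom component enters the surface rule. Per-component maxima
  are not bundled (no verifiable source); `compute_rsa` accepts a user
  table and reports NaN for components without a reference.
- **PR-AUC** uses the Davis–Goadrich non-linear interpolation: between
  achievable points, false positives are interpolated linearly in true
  positives at unit-TP steps (precision then follows a hyperbola, not a
  chord), and the curve is anchored at recall 0 with the precision of the
  earliest achievable point (one true positive). A perfect ranking scores
  1; random scores converge to the positive prevalence. This differs from
  scikit-learn's `average_precision_score` (a step-sum estimator), which
  is used only as an independent sanity check in tests.
- **Wilcoxon signed-rank** comparisons use the exact null distribution
  for small tie-free samples and the tie-corrected normal approximation
  otherwise; all-zero difference vectors return p = 1 with a warning.
- **Degenerate inputs**: residues without Cα are excluded from graphs and
  patches with a warning; graphs with < 3 vertices define all
  betweenness as 0; chains without positives are excluded from fold
  averages with a warning; fewer negatives than positives keeps all of
  both with a warning.
- **Parsing**: first MODEL only, first altloc per atom, insertion codes
  part of the residue key, author numbering preserved; MSE and similar
  nonstandard residues map to their parent type, anything unmappable is
  classified `other` and excluded; waters and ligands are `other`.

## What the synthetic generator emulates — and what it does not

Real benchmark sets for this task (non-redundant protein-DNA complex
chains with PSI-BLAST profiles) are not redistributable here, so the
package ships a generator whose defaults define the study conditions
used by the tests and the acceptance script: 20 chains of 60 residues
(idealized α-helix: 1.5 Å rise, 100° twist, 2.3 Å radius — adjacent Cα
3.8 Å apart and a contact-graph degree of ~8 at the 8 Å cutoff, like a
compact globular fold), 8 planted binding residues per chain at a random
contiguous site (prevalence ≈ 13%, matching the heavy imbalance of real
surface data), DNA pseudo-residues (heavy atoms P, C1′) placed 3 Å
outward from the site (inside the 4.5 Å rule; construction is validated
so no other residue falls within the cutoff), a 60% arginine/lysine
composition bias at binding sites (feeding the interface propensity),
and synthetic PSSMs with N(0,1) background log-odds shifted by 1.5 SD on
the R/K columns at binding positions.

The generator does **not** emulate: tertiary folds and real surface
topography (every helix residue is exposed, so the 10% rule rarely
buries anything), rotameric side chains (one CB/CG/tip pseudo-atom
chain), sequence-profile correlation structure along the chain, or
binding-site geometry beyond a contiguous helical face. Passing tests
therefore demonstrate that the pipeline recovers signals with the
statistical and geometric structure it assumes — not field performance
on real complexes, which requires real structures and profiles supplied
by the user.

## Problem sizes used by the test suite and acceptance script

Cross-validation and parameter-recovery experiments run on the default
20-chain generator conditions (~1200 surface residues); the
parameter-recovery check uses 20 independent replicates with a 25%
chain-level holdout and a permuted-label baseline per replicate;
betweenness is checked against a brute-force path-counting oracle on
random graphs of ≤ 20 vertices; Wilcoxon calibration uses 1000 null
replicates of 20 pairs; random-score PR-AUC uses 40 replicates of 1000
residues at prevalence 0.15.

## Known limitations

- The exact algebraic form of the original distance-weighting function
  is unknown; results can shift slightly between shipped schemes (all
  satisfy the stated constraints).
- Published headline numbers on the original training/test sets are not
  reproducible without those chain lists and PSI-BLAST runs; the
  single-structure Hin recombinase case study (`dbpsite casestudy`)
  reproduces the published experiment when the user supplies the PDB
  file `1JKO`, which cannot be redistributed with the package.
- ASA at 960 points carries ~1% worst-case per-residue discretization
  error (see above); raise `n_sphere_points` for tighter work.
- The SVM hyperparameters were never published; C = 1, γ = 1/43 are
  library-conventional defaults, with grid search left to the user and
  valid only if confined to training folds.
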