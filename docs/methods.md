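# Methods

`enscontact` predicts residue–residue contacts for a protein of length L
from an ensemble of *ab initio* structure-prediction decoys, on the
premise that native contacts are energetically favorable and therefore
recur — embedded in native-like physicochemical environments — inside
low-energy decoys, even when every decoy is globally wrong.

## Contact definition and candidate set

Two residues are in contact when their Cβ atoms (Cα for glycine, or as a
fallback when Cβ is absent) lie within 8 Å.  The structural contact
graph uses every such pair; *candidate* contacts submitted to the
classifier and to evaluation are restricted to sequence separation ≥ 12
(medium range 12–23, long range ≥ 24), because short-range contacts are
trivially present in any compact chain.

## Decoy selection

Decoys arrive as PDB files with a sidecar `decoy_id → energy` table.
The pipeline retains the lowest-energy fraction — 2 % for prediction,
3 % for building training labels — with `ceil(fraction · N)` so small
ensembles keep at least one decoy, and energy ties broken by decoy id.

## Contact graphs

The context of a candidate contact (i, j) in one decoy is described by
induced subgraphs of the decoy's contact graph:

* **N_i** — seed window {i−2…i+2} (for helical i: {i−4, i−3, i, i+3,
  i+4}, the positions facing the same direction on adjacent helix
  turns), plus every residue in contact with the window; edges are the
  contacts induced among those nodes.
* **SNG(i, j)** — induced graph on nodes(N_i) ∩ nodes(N_j); captures the
  shared environment.
* **ING(i, j)** — induced graph on {i, j} and all residues in direct
  contact with either; captures the immediate environment.

The induced-subgraph rule is the only parameter-free edge convention and
is enforced by a brute-force property test.

## Features (238 inputs)

Each candidate contact in each decoy becomes a fixed vector:

| group | inputs | content |
|---|---|---|
| pairwise | 49 | chemical class and ss3 one-hots, RSA, burial, solvation, hydropathy, H-bonds, sequence separation (raw + 4 bins), terminal distances, contact potential (raw + 3 bins), decoy distance, ensemble mean/sd distance, MI, APC-MI |
| topology (×2) | 10 | node/edge counts, mean degree/closeness/betweenness centrality, radius, diameter, mean eccentricity, end points, clustering |
| spectrum (×2) | 5 | two largest adjacency eigenvalues, #distinct eigenvalues, trace, graph energy |
| single node (×2) | 10 | degree, closeness, betweenness, conservation, neighborhood conservation for i and j |
| node statistics (×2) | 43 | chem/ss7 distributions, RSA, H-bonding, solvation (mean + 4 bins), label entropies, neighborhood impurity, centroid geometry, conservation summaries |
| edge statistics (×2) | 12 | link impurity, 5-bin APC-MI distribution, cumulative/mean MI, 3-bin potential distribution, mean potential |
| whole protein | 29 | amino-acid composition, ss3 composition, 6-class length one-hot |

Graph groups are computed once on the SNG and once on the ING, giving
49 + 29 + 2·80 = 238.  Group sizes are asserted at construction; the
full input ordering is exported by `feature_schema()`.

### Structure annotations

External assignment programs are replaced by internal approximations
with stated, testable rules:

* **Secondary structure** — dihedral windows (helix φ∈[−90,−30],
  ψ∈[−77,−17] in runs ≥ 4; strand φ∈[−170,−70], ψ∈[90,180]∪[−180,−170]
  in runs ≥ 3) with 3₁₀/π/turn states inferred from (i,i+3)/(i,i+5)
  backbone H-bonds.
* **SASA/RSA** — Shrake–Rupley sampling with 92 golden-spiral points and
  a 1.4 Å probe; RSA normalizes by theoretical per-residue maxima and is
  clamped to [0, 1.2]; buried means RSA < 0.25.  The fixed point
  directions make sampled areas only approximately rotation invariant
  (≲ a few %), which the invariance test acknowledges.
* **H-bonds** — backbone N···O ≤ 3.5 Å with |i−j| ≥ 2.
* **Solvation energy** — Σ_atoms σ(type)·SASA(atom) with σ values for
  apolar C, neutral N/O, charged O, charged N and S shipped as data.
* **Contact potential** — a 20×20 table shipped as data; the default is
  a synthetic hydrophobic-attraction surrogate derived from
  Kyte–Doolittle values (see the file header), swappable in config.
* **Conservation** — per-column 1 − H/log 20 with Henikoff sequence
  weights.  Smoothing adds one pseudo-observation per *observed* symbol
  type, so pure columns (and depth-1 alignments) are exactly 1.0.
* **MI/APC** — 21-symbol mutual information with pseudocount 0.05 per
  joint cell; the average product correction subtracts
  mean_i·mean_j/mean.  The pseudocount leaves a small positive floor on
  independent columns (~0.01–0.03 at depth 3000), which tests treat as
  the expected residual rather than coupling.

All bin edges (MI, solvation, potential, RSA, conservation, separation,
length classes) are fixed constants in `config.py` so vectors are stable
across runs.

## Classifier

Native contacts are a minority among decoy contacts, so training uses
random undersampling inside an ensemble: proteins are split (seeded)
into five disjoint subsets; per protein, 50 native and 150 non-native
instances are sampled without replacement (all, if fewer); one
soft-margin Gaussian-kernel SVM is trained per subset on z-normalized
inputs (normalizer fitted on the union; sd floor 1e−8).

Raw margins become probabilities by **bin calibration**: ten equal-width
bins between the 5th and 95th percentile of out-of-fold margins
(internal 5-fold split of the member's subset); each bin's probability
is its native fraction; values outside the window clamp to the end bins
and empty bins inherit the nearest populated bin.  The count-weighted
mean of bin probabilities equals the calibration native fraction by
construction, which is asserted to 1e−12.

The ensemble probability is the mean of the five calibrated members.
Defaults C = 10, γ = 1/238 can be replaced by
`tune_hyperparameters` (k-fold CV over proteins maximizing long-range
top-L/5 precision; candidate order is shuffled with a fixed RNG before
the score sort so a constant scorer cannot profit from label-ordered
ties; ties prefer smaller C then smaller γ).

## Scoring and combination

Every candidate contact of every selected decoy is scored; per pair,
S = mean probability over the decoys containing it, n = occurrence
count, f = n/N.  The final score is

    combined(i, j) = S + α·f + β·g ,

where g is an external evolutionary-coupling score, min-max rescaled to
[0, 1] per protein (coupling programs scale differently between
alignments), and β switches between a shallow- and deep-alignment value
at 5·L sequences.  Pairs with couplings but no decoy occurrence enter
with S = f = 0 so deep-alignment recall is not capped by decoy
coverage.  Defaults α = 1, β = 0.2/1.0 (shallow/deep);
`tune_combination_weights` grid-searches both strata by CV.  The
**Counting baseline** ranks pairs by f alone.

## Restraints

Ranked contacts export as bounded-Lorentz restraints: energy −w for
d ∈ [lb, ub] = [1.5, 8] Å, −w / (1 + ((violation)/hw)²) outside with
hw = 1 Å — continuous, −w/2 at one half-width, asymptotically 0, never
positive, so false-positive predictions are never penalized.  The d < lb
branch cannot trigger at the default lb but is kept for general
parameter choices.  Default emission is the top L contacts.

## Evaluation

Acc = TP/(TP+FP) and Cov = TP_frac/TP_total over the top max(1, ⌊L/k⌋)
in-range predictions for k ∈ {10, 5, 2}; TP_total counts in-range native
contacts, and Cov is reported as missing when there are none.  Proteins
stratify by alignment depth into (1, 1L], (1L, 5L], > 5L.

## Synthetic data

The generator reproduces the premises the method relies on, seeded end
to end:

* **Natives** — full-backbone chains built by natural-extension
  (NeRF) geometry from ideal bond lengths/angles; helix (−57, −47) and
  strand (−120, 130) segments joined by coils whose dihedrals are chosen
  greedily, with a roll-out through the next rigid segment, to pull the
  chain toward its centroid while avoiding CA clashes; 8 restarts keep
  the build with the most medium/long-range contacts.  Consecutive CA
  distances are 3.80 Å by construction.  The sequence is then designed
  inside-out for the chosen fold (hydrophobic pools at buried positions,
  polar/charged at exposed ones, per secondary-structure state), so
  native contacts are chemically favorable — the physicochemical signal
  the classifier is supposed to exploit exists by construction, and
  contacts of any *alternative* packing of the same sequence pair the
  wrong residue types.
* **Decoys** — each decoy samples a basin (the native, or one of 2
  misfold attractors: same sequence and secondary-structure segments,
  alternative packing) plus AR(1)-correlated per-residue Gaussian noise
  at an amplitude drawn from the ladder (1, 2, 4 Å), emulating decoys
  very close, relatively close and far from their basin.  Energy =
  RMSD-to-own-basin + basin offset + Gaussian noise, so low-energy
  selection retains mostly near-native decoys with a minority of
  persistently misfolded ones.  The misfold basins exist because real
  decoy sets contain systematic, recurrent errors; without them,
  occurrence frequency is an oracle and context adds nothing.
* **Alignments** — rows mutate within small per-column pools; a subset
  of native medium/long contacts (a disjoint column matching, capped by
  `covary_fraction`) is planted as jointly switching column pairs, so
  APC-MI recovers them at depth; the coupling-score file is exactly that
  APC-MI matrix.
* What the generator does **not** emulate: real force-field energetics,
  side chains beyond Cβ, sequence–structure consistency (sequences are
  drawn from per-state residue pools), alignment phylogeny, or
  chain-break/multi-chain pathology.  Passing tests therefore show the
  pipeline's machinery and its qualitative premises, not performance on
  real proteins.

## Study conditions and problem sizes

The end-to-end study (`run_synthetic_study`, also behind
`scripts/acceptance.py`) uses 12 proteins of L = 60 with 200 decoys and
depth-500 alignments — 8 train / 4 held out; these sizes keep the full
study at desk scale while leaving every pipeline stage non-trivial.
The study tunes (C, γ) by 10-fold cross-validation over the training
proteins on a small grid around the defaults ({10, 100} ×
{3·10⁻⁴, 1/238}) before training the final ensemble, mirroring the
standard protocol.  Reported quantities: mean per-protein ROC AUC of S
(and of f, and of S against permuted labels) over held-out candidate
pairs, and mean long-range top-L/5 accuracy/coverage of the combined
ranking versus the Counting baseline.  Per-protein averaging follows
standard practice for contact-prediction evaluation.

## Numerical choices and degenerate inputs

Eigenvalues via symmetric eigendecomposition; distinct-eigenvalue
tolerance 1e−8.  Single-node graphs yield zero topology/spectrum
descriptors except the node count; edgeless graphs yield zero edge
statistics; disconnected graphs take radius/diameter/eccentricity on
the largest component (ties: larger size, then smaller minimum node).
Ranking ties break by higher f then lexicographic pair; selection ties
by decoy id.  Chains shorter than 3 residues are all-coil; structures
without an alignment get conservation 1.0 and zero MI.

With 8 training and 4 held-out proteins the study's AUC comparisons
carry substantial seed-to-seed variance: whether the ensemble score
beats the frequency baseline can flip between seeds at this scale,
while the absolute AUC level, the chance-level permuted control, and
the combined-versus-Counting ranking comparison are stable.  The
published protocol used two orders of magnitude more training proteins.

## Known limitations

The 49/43/12 within-group breakdowns are this package's canonical
choice; only the group totals and named items are external contracts,
and the schema is versioned so a different breakdown can replace it.
The SASA sampler trades exact rotation invariance for determinism.  The
synthetic misfold model produces basin-shaped decoy heterogeneity only;
real decoy error is richer.  Hyperparameter and weight tuning are
provided but the defaults are used in the study for runtime reasons.
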