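# enscontact

Residue–residue contact prediction from low-energy *ab initio* decoy
ensembles, for structural bioinformaticians who have decoys (and ideally
a deep alignment) but no solved structure.

Even globally wrong decoys contain native contacts, because native
contacts are energetically favorable and recur inside low-energy
conformations.  Counting how often a contact occurs across the decoy
ensemble is already a usable predictor, but the energy criterion favors
*all* contacts of a low-energy decoy equally — including its persistent
non-native ones.  `enscontact` scores each contact by its **structural
context**: the shared neighborhood graph (SNG) and immediate
neighborhood graph (ING) around the contact are encoded, together with
pairwise physicochemistry and whole-protein descriptors, into a fixed
238-input vector and classified by an ensemble of five Gaussian-kernel
SVMs trained with per-protein random undersampling (50 native / 150
non-native instances) and calibrated by ten-bin percentile binning.

For a pair (i, j) — in contact when the Cβ atoms (Cα for glycine) are
within 8 Å — the final score combines three signals:

    score(i, j) = S_ij + α · f_ij + β · g_ij

where `S_ij` is the mean calibrated ensemble probability over the
selected decoys containing the pair, `f_ij = n_ij / N` its occurrence
frequency over the N lowest-energy decoys (top 2 %), and `g_ij` an
external evolutionary-coupling score (min-max rescaled per protein),
with β switched between a shallow- and deep-alignment value at 5·L
sequences.  Ranked contacts are written in CASP RR format and can be
exported as non-penalizing bounded-Lorentz distance restraints
(full bonus −w for d ∈ [1.5, 8] Å, Lorentzian decay of half width 1 Å
outside) for contact-guided folding.

A fully seeded synthetic generator (natives with ideal-geometry
backbones, decoy ensembles with misfold basins and RMSD-linked
energies, alignments with planted covariation) lets every stage train
and test without any external data; see `docs/methods.md` for the model
and its limitations.

## Worked example

A small self-contained run (a few minutes on one CPU):

```bash
# simulate a corpus of 8 proteins (5 train / 3 held out)
enscontact simulate --n-proteins 8 --length 40 --n-decoys 40 \
    --depth 60 --seed 11 --out demo/

# train the SVM ensemble on the training split
enscontact train --corpus demo/train --seed 11 --model demo/model.pkl

# predict long-range contacts for one held-out protein
enscontact predict \
    --decoys demo/test/syn005_decoys \
    --energies demo/test/syn005_energies.tsv \
    --model demo/model.pkl \
    --msa demo/test/syn005.a3m \
    --evo-scores demo/test/syn005_evo.tsv \
    --range long --out demo/syn005.rr
# -> 79 ranked contacts written to demo/syn005.rr

head -4 demo/syn005.rr
# PFRMAT RR
# AEMLLQKQDNDGIFIFTYSSDDNNEEEQEKAAMALALLVL
# 5 35 0 8 1.994234
# 2 39 0 8 1.972481

# evaluate against the (here known) native structure
enscontact evaluate --rr demo/syn005.rr \
    --native demo/test/syn005_native.pdb \
    --msa demo/test/syn005.a3m
```

The `evaluate` step prints, per range and top fraction, the accuracy
Acc = TP/(TP+FP) and coverage Cov = TP_frac/TP_total; for this protein
it prints (long-range rows shown):

```json
{
  "L": 40,
  "rows": {
    "long_L10": {"acc": 1.0, "cov": 0.0727, "tp": 4,  "fp": 0,
                 "tp_total": 55, "n": 4},
    "long_L5":  {"acc": 1.0, "cov": 0.1455, "tp": 8,  "fp": 0,
                 "tp_total": 55, "n": 8},
    "long_L2":  {"acc": 1.0, "cov": 0.3636, "tp": 20, "fp": 0,
                 "tp_total": 55, "n": 20}
  },
  "depth": 60,
  "stratum": "(1L,5L]"
}
```

meaning all 8 of the top L/5 = 8 long-range predictions are native
contacts (accuracy 1.0), recovering 14.6 % of the 55 long-range native
contacts, for a protein whose 60-row alignment falls in the (1L, 5L]
depth stratum.  The RR rows are `i j 0 8 score`: residue pair, the 0–8 Å
distance window of the contact definition, and the combined score.

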