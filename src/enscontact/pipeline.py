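"""End-to-end orchestration: instances -> ensemble model -> ranked contacts.

Ties the modules together for the CLI, the reproduction script and the
tests.  A "protein bundle" here is anything exposing the attributes of
:class:`enscontact.synthetic.SyntheticProtein` (native, native_cm,
ensemble, msa, evo); loaders for on-disk inputs build the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import config
from .config import CombinationWeights
from .features import build_ensemble_context, build_labels, compute_msa_stats
from .ml import (SvmEnsembleModel, TrainingInstance, make_training_set,
                 predict_batch, train_ensemble)
from .scoring import (ContactScoreTable, PairScore, candidate_contacts,
                      combine_scores, counting_baseline,
                      extract_decoy_features, rank_contacts)
from .structio import (DecoyEnsemble, EvolutionaryScores, Msa,
                       ProteinStructure, compute_contact_map, read_energy_table,
                       read_evolutionary_scores, read_msa, read_structure,
                       select_low_energy)

__all__ = [
    "ProteinBundle",
    "load_protein_bundle",
    "collect_instances",
    "train_from_corpus",
    "score_protein",
    "predict_protein",
    "run_synthetic_study",
]


@dataclass
class ProteinBundle:
    """Inputs for one protein loaded from disk."""

    id: str
    native: ProteinStructure | None
    native_cm: object | None
    ensemble: DecoyEnsemble
    msa: Msa | None
    evo: EvolutionaryScores


def load_protein_bundle(
    decoy_dir: str | Path,
    energies_path: str | Path,
    native_path: str | Path | None = None,
    msa_path: str | Path | None = None,
    evo_path: str | Path | None = None,
    protein_id: str | None = None,
) -> ProteinBundle:
    """Read decoys + energies (and optional native / MSA / coupling file)."""
    decoy_dir = Path(decoy_dir)
    decoys = [read_structure(p) for p in sorted(decoy_dir.glob("*.pdb"))]
    if not decoys:
        raise ValueError(f"no decoy PDB files in {decoy_dir}")
    energies = read_energy_table(energies_path)
    ensemble = DecoyEnsemble(decoys, energies)
    native = read_structure(native_path) if native_path else None
    native_cm = compute_contact_map(native) if native else None
    msa = read_msa(msa_path) if msa_path else None
    L = decoys[0].L
    evo = (
        read_evolutionary_scores(evo_path, L=L)
        if evo_path
        else EvolutionaryScores({})
    )
    return ProteinBundle(
        id=protein_id or decoy_dir.name,
        native=native,
        native_cm=native_cm,
        ensemble=ensemble,
        msa=msa,
        evo=evo,
    )


def _selected_labels(protein, fraction: float):
    """Select low-energy decoys and annotate them (shared MSA stats)."""
    ens = select_low_energy(protein.ensemble, fraction)
    msa_stats = compute_msa_stats(protein.msa) if protein.msa else None
    labels = [build_labels(d, msa_stats=msa_stats) for d in ens.selected]
    return ens.selected, labels


def collect_instances(
    protein, fraction: float = config.TRAIN_ENERGY_FRACTION
) -> list[TrainingInstance]:
    """All labeled candidate instances of one protein's selected decoys."""
    selected, labels_list = _selected_labels(protein, fraction)
    ctx = build_ensemble_context(selected)
    out: list[TrainingInstance] = []
    for decoy, labels in zip(selected, labels_list):
        pairs, x = extract_decoy_features(decoy, labels, ctx)
        for (i, j), row in zip(pairs, x):
            out.append(
                TrainingInstance(
                    protein_id=protein.id if hasattr(protein, "id") else decoy.id,
                    pair=(i, j),
                    features=row,
                    native=(i, j) in protein.native_cm,
                )
            )
    return out


def train_from_corpus(
    proteins: list,
    seed: int = 0,
    C: float = config.SVM_DEFAULT_C,
    gamma: float = config.SVM_DEFAULT_GAMMA,
    fraction: float = config.TRAIN_ENERGY_FRACTION,
) -> SvmEnsembleModel:
    """Undersample, split five ways and train the calibrated ensemble."""
    corpus = [(p.id, collect_instances(p, fraction)) for p in proteins]
    subsets = make_training_set(corpus, seed=seed)
    return train_ensemble(subsets, C=C, gamma=gamma, seed=seed)


def score_protein(
    model: SvmEnsembleModel,
    protein,
    fraction: float = config.PREDICT_ENERGY_FRACTION,
) -> ContactScoreTable:
    """S_svm / n / f for every pair observed in the selected decoys."""
    selected, labels_list = _selected_labels(protein, fraction)
    ctx = build_ensemble_context(selected)
    N = len(selected)
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for decoy, labels in zip(selected, labels_list):
        pairs, x = extract_decoy_features(decoy, labels, ctx)
        if not pairs:
            continue
        probs = predict_batch(model, x)
        for (i, j), prob in zip(pairs, probs):
            sums[(i, j)] = sums.get((i, j), 0.0) + float(prob)
            counts[(i, j)] = counts.get((i, j), 0) + 1
    table = ContactScoreTable(L=selected[0].L, N=N)
    for pair, n in counts.items():
        table.pairs[pair] = PairScore(svm=sums[pair] / n, n=n, f=n / N)
    return table


#: Hyperparameter grid of the in-silico study: the default cost and one
#: order larger; the default 1/n_inputs kernel width and one order finer.
STUDY_C_GRID = (10.0, 100.0)
STUDY_GAMMA_GRID = (3e-4, config.SVM_DEFAULT_GAMMA)


def run_synthetic_study(
    seed: int = 1,
    n_proteins: int = 12,
    template=None,
    weights: CombinationWeights = CombinationWeights(),
) -> dict:
    """The package's end-to-end in-silico study, fully seeded.

    Generates a synthetic corpus, tunes (C, gamma) by cross-validation
    over the training proteins, trains the SVM ensemble on the training
    split, and evaluates the held-out proteins:

    * per-pair discrimination (native vs non-native decoy contacts) as
      mean per-protein ROC AUC of the ensemble score, of the occurrence
      frequency alone (the Counting signal), and of the ensemble score
      against permuted labels (negative control);
    * ranking quality as mean long-range top-L/5 accuracy and coverage of
      the combined score versus the Counting baseline.
    """
    from sklearn.metrics import roc_auc_score

    from .evaluate import evaluate_predictions
    from .synthetic import SyntheticProteinSpec, make_corpus

    from .ml import tune_hyperparameters

    template = template or SyntheticProteinSpec()
    train, test = make_corpus(n_proteins, template, seed=seed)
    corpus = [(p.id, collect_instances(p)) for p in train]
    subsets = make_training_set(corpus, seed=seed)
    lengths = {p.id: p.native.L for p in train}
    C, gamma = tune_hyperparameters(
        subsets, list(STUDY_C_GRID), list(STUDY_GAMMA_GRID),
        k=10, seed=seed, lengths=lengths,
    )
    model = train_ensemble(subsets, C=C, gamma=gamma, seed=seed)

    rng = np.random.default_rng(seed + 1000)
    auc_svm, auc_freq, auc_perm = [], [], []
    acc_comb, acc_count, cov_comb, cov_count = [], [], [], []
    n_pairs = 0
    for protein in test:
        table = score_protein(model, protein)
        pairs = sorted(table.pairs)
        y = np.array([(i, j) in protein.native_cm for i, j in pairs])
        s = np.array([table.pairs[p].svm for p in pairs])
        f = np.array([table.pairs[p].f for p in pairs])
        n_pairs += len(pairs)
        if y.any() and not y.all():
            auc_svm.append(roc_auc_score(y, s))
            auc_freq.append(roc_auc_score(y, f))
            auc_perm.append(roc_auc_score(rng.permutation(y), s))
        L = table.L
        combined = combine_scores(table, protein.evo, weights,
                                  protein.msa.depth, L)
        ranked = rank_contacts(combined, "long")
        row = evaluate_predictions(ranked, protein.native_cm, L, 5, "long")
        acc_comb.append(row.acc)
        cov_comb.append(row.cov if row.cov is not None else 0.0)
        counting = counting_baseline(
            select_low_energy(protein.ensemble,
                              config.PREDICT_ENERGY_FRACTION).selected
        )
        row_c = evaluate_predictions(counting, protein.native_cm, L, 5, "long")
        acc_count.append(row_c.acc)
        cov_count.append(row_c.cov if row_c.cov is not None else 0.0)
    return {
        "n_test_proteins": len(test),
        "n_scored_pairs": n_pairs,
        "tuned_C": C,
        "tuned_gamma": gamma,
        "auc_svm": float(np.mean(auc_svm)),
        "auc_frequency": float(np.mean(auc_freq)),
        "auc_permuted": float(np.mean(auc_perm)),
        "combined_long_L5_accuracy": float(np.mean(acc_comb)),
        "counting_long_L5_accuracy": float(np.mean(acc_count)),
        "combined_long_L5_coverage": float(np.mean(cov_comb)),
        "counting_long_L5_coverage": float(np.mean(cov_count)),
    }


def predict_protein(
    model: SvmEnsembleModel,
    protein,
    weights: CombinationWeights = CombinationWeights(),
    fraction: float = config.PREDICT_ENERGY_FRACTION,
    range_name: str = "all",
) -> tuple[ContactScoreTable, list[tuple[int, int, float]]]:
    """Full prediction: SVM scores + frequency + evolutionary couplings,
    combined and ranked."""
    table = score_protein(model, protein, fraction)
    depth = protein.msa.depth if protein.msa else 1
    L = table.L
    table = combine_scores(table, protein.evo, weights, depth, L)
    return table, rank_contacts(table, range_name)
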