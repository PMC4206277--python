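"""Per-pair score aggregation, the Counting baseline, and score combination.

Every contact observed in any selected decoy is scored by the SVM
ensemble in every decoy that contains it; the physicochemical score of a
pair is the mean over those decoys.  The final score adds the pair's
occurrence frequency across the decoy ensemble and an (externally
produced) evolutionary-coupling score:

    combined(i, j) = S_svm + alpha * f + beta(depth) * g

with ``beta`` switching between a shallow- and deep-alignment weight at
five sequences per residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import config
from .config import CombinationWeights
from .features import (EnsembleContext, Labels, assemble_feature_vector,
                       build_ensemble_context, build_labels,
                       whole_protein_features)
from .graphs import immediate_neighborhood_graph, shared_neighborhood_graph
from .ml import SvmEnsembleModel, predict_batch
from .structio import (ContactMap, EvolutionaryScores, ProteinStructure,
                       compute_contact_map)

__all__ = [
    "PairScore",
    "ContactScoreTable",
    "CombinationWeights",
    "candidate_contacts",
    "score_contacts_over_decoys",
    "counting_baseline",
    "combine_scores",
    "rank_contacts",
    "tune_combination_weights",
]


@dataclass
class PairScore:
    """All score components of one candidate pair."""

    svm: float = 0.0
    n: int = 0
    f: float = 0.0
    g: float = 0.0
    combined: float = 0.0


@dataclass
class ContactScoreTable:
    """Scores per candidate pair plus the ensemble size N."""

    L: int
    N: int
    pairs: dict[tuple[int, int], PairScore] = field(default_factory=dict)

    def items(self):
        return self.pairs.items()


def candidate_contacts(cm: ContactMap) -> list[tuple[int, int]]:
    """Medium- and long-range contacts of a decoy (separation >= 12)."""
    return sorted(
        (i, j) for i, j in cm.pairs if j - i >= config.CANDIDATE_MIN_SEPARATION
    )


def extract_decoy_features(
    decoy: ProteinStructure,
    labels: Labels,
    ens: EnsembleContext,
    pairs: list[tuple[int, int]] | None = None,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Feature matrix for the candidate contacts of one decoy."""
    cm = compute_contact_map(decoy)
    if pairs is None:
        pairs = candidate_contacts(cm)
    whole = whole_protein_features(decoy, labels.ss3)
    rows = []
    for i, j in pairs:
        sng = shared_neighborhood_graph(cm, labels.ss3, i, j)
        ing = immediate_neighborhood_graph(cm, i, j)
        fv = assemble_feature_vector(i, j, sng, ing, labels, ens, whole, decoy.L)
        rows.append(fv.flat)
    if not rows:
        return pairs, np.zeros((0, 238))
    return pairs, np.array(rows)


def score_contacts_over_decoys(
    model: SvmEnsembleModel,
    decoys: list[ProteinStructure],
    labels_per_decoy: list[Labels],
) -> ContactScoreTable:
    """SVM-score every candidate contact of every selected decoy and
    aggregate: S_svm = mean probability over the decoys containing the
    pair, f = occurrence frequency over the N selected decoys."""
    if not decoys:
        raise ValueError("no selected decoys")
    N = len(decoys)
    ens = build_ensemble_context(decoys)
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for decoy, labels in zip(decoys, labels_per_decoy):
        pairs, x = extract_decoy_features(decoy, labels, ens)
        if not pairs:
            continue
        probs = predict_batch(model, x)
        for (i, j), p in zip(pairs, probs):
            sums[(i, j)] = sums.get((i, j), 0.0) + float(p)
            counts[(i, j)] = counts.get((i, j), 0) + 1
    table = ContactScoreTable(L=decoys[0].L, N=N)
    for pair, n in counts.items():
        table.pairs[pair] = PairScore(svm=sums[pair] / n, n=n, f=n / N)
    return table


def counting_baseline(
    decoys: list[ProteinStructure],
) -> list[tuple[int, int, float]]:
    """Rank candidate pairs purely by occurrence frequency across decoys
    (descending; ties by ascending pair)."""
    if not decoys:
        raise ValueError("no selected decoys")
    counts: dict[tuple[int, int], int] = {}
    for decoy in decoys:
        for pair in candidate_contacts(compute_contact_map(decoy)):
            counts[pair] = counts.get(pair, 0) + 1
    N = len(decoys)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(i, j, n / N) for (i, j), n in ranked]


def combine_scores(
    table: ContactScoreTable,
    g: EvolutionaryScores,
    w: CombinationWeights,
    depth: int,
    L: int,
) -> ContactScoreTable:
    """Fill the combined score S + alpha*f + beta*g.

    Evolutionary scores are min-max rescaled to [0, 1] per protein first
    (coupling methods scale differently between alignments).  Pairs that
    carry an evolutionary score but never occur in a decoy are admitted
    with S = f = 0 so decoy coverage does not cap deep-alignment recall.
    """
    beta = w.beta(depth, L)
    g = g.rescaled()
    for (i, j), gval in g.scores.items():
        if j - i < config.CANDIDATE_MIN_SEPARATION:
            continue
        if (i, j) not in table.pairs:
            table.pairs[(i, j)] = PairScore()
    for (i, j), ps in table.pairs.items():
        ps.g = g.get(i, j)
        ps.combined = ps.svm + w.alpha * ps.f + beta * ps.g
    return table


def rank_contacts(
    table: ContactScoreTable, range_filter: str = "all"
) -> list[tuple[int, int, float]]:
    """Pairs in descending combined score (ties: higher f, then lower
    (i, j)), restricted to the requested separation range."""
    from .evaluate import in_range

    rows = [
        ((i, j), ps)
        for (i, j), ps in table.pairs.items()
        if in_range(i, j, range_filter)
    ]
    rows.sort(key=lambda r: (-r[1].combined, -r[1].f, r[0]))
    return [(i, j, ps.combined) for (i, j), ps in rows]


def tune_combination_weights(
    corpus: list[dict],
    alpha_grid: list[float],
    beta_grid: list[float],
    k: int = 5,
    seed: int = 0,
) -> CombinationWeights:
    """Grid-search alpha and the two beta weights by k-fold CV over
    proteins, maximizing long-range top-L/5 precision; beta is tuned
    separately for the shallow (depth <= 5L) and deep (depth > 5L)
    strata.  An empty stratum inherits the other stratum's beta.

    Each corpus entry is a dict with keys ``table`` (ContactScoreTable
    with S and f filled), ``evo`` (EvolutionaryScores), ``native_cm``,
    ``depth`` and ``L``.
    """
    from .evaluate import evaluate_predictions

    if not alpha_grid or not beta_grid:
        raise ValueError("empty grid")

    def stratum_of(entry) -> str:
        return "deep" if entry["depth"] > 5.0 * entry["L"] else "shallow"

    def accuracy(entry, alpha, beta) -> float:
        w = CombinationWeights(alpha=alpha, beta_low=beta, beta_high=beta)
        table = combine_scores(
            entry["table"], entry["evo"], w, entry["depth"], entry["L"]
        )
        ranked = rank_contacts(table, "long")
        report = evaluate_predictions(
            ranked, entry["native_cm"], entry["L"], divisor=5, range_name="long"
        )
        return report.acc

    rng = np.random.default_rng(seed)
    best: dict[str, tuple[float, float, float]] = {}
    for stratum in ("shallow", "deep"):
        entries = [e for e in corpus if stratum_of(e) == stratum]
        if not entries:
            continue
        order = rng.permutation(len(entries))
        folds = np.array_split(order, min(k, len(entries)))
        for alpha in sorted(alpha_grid):
            for beta in sorted(beta_grid):
                accs = []
                for fold in folds:
                    # CV over proteins: the held-out fold is evaluated
                    accs.extend(
                        accuracy(entries[e], alpha, beta) for e in fold
                    )
                mean_acc = float(np.mean(accs))
                if stratum not in best or mean_acc > best[stratum][0] + 1e-12:
                    best[stratum] = (mean_acc, alpha, beta)
    if not best:
        raise ValueError("no proteins in any stratum")
    if "shallow" not in best:
        import warnings

        warnings.warn("shallow stratum empty; inheriting deep beta")
        best["shallow"] = best["deep"]
    if "deep" not in best:
        import warnings

        warnings.warn("deep stratum empty; inheriting shallow beta")
        best["deep"] = best["shallow"]
    alpha = best["deep"][1] if len(
        [e for e in corpus if stratum_of(e) == "deep"]
    ) >= len(corpus) / 2 else best["shallow"][1]
    return CombinationWeights(
        alpha=alpha,
        beta_low=best["shallow"][2],
        beta_high=best["deep"][2],
    )
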