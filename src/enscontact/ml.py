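"""Undersampled SVM ensemble with percentile-bin probability calibration.

Native contacts are rare among decoy contacts, so each ensemble member
trains on a random undersample (50 native / 150 non-native instances per
protein).  Proteins are split into five disjoint subsets, one Gaussian-
kernel SVM per subset; raw margins are mapped to probabilities through
ten equal-width bins spanning the 5th-95th percentile of the member's
out-of-fold margins.  The ensemble prediction is the mean of the five
calibrated member probabilities.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from . import config
from .features import SCHEMA_VERSION, TOTAL_INPUTS, FeatureVector

__all__ = [
    "TrainingInstance",
    "Normalizer",
    "BinCalibrator",
    "SvmEnsembleModel",
    "make_training_set",
    "train_ensemble",
    "calibrate_bins",
    "predict_contact_probability",
    "tune_hyperparameters",
]


@dataclass
class TrainingInstance:
    """One candidate contact in one decoy, labeled from the native map."""

    protein_id: str
    pair: tuple[int, int]
    features: np.ndarray
    native: bool


@dataclass
class Normalizer:
    """Per-input z-normalization fitted on the training union."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "Normalizer":
        sd = x.std(axis=0)
        return cls(mean=x.mean(axis=0), sd=np.maximum(sd, 1e-8))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


@dataclass
class BinCalibrator:
    """Maps raw SVM margins to native-contact probabilities.

    Ten equal-width bins span [p5, p95] of the calibration margins; each
    bin's probability is its native fraction.  Margins below p5 (above
    p95) clamp to the first (last) bin; empty bins inherit the nearest
    populated bin's probability.
    """

    edges: np.ndarray  # 11 edges of 10 bins
    probabilities: np.ndarray  # 10 values
    counts: np.ndarray  # 10 values

    def __call__(self, raw: np.ndarray | float) -> np.ndarray | float:
        raw = np.asarray(raw, dtype=float)
        idx = np.clip(
            np.digitize(raw, self.edges[1:-1]), 0, config.CALIBRATION_N_BINS - 1
        )
        out = self.probabilities[idx]
        return float(out) if out.ndim == 0 else out


def calibrate_bins(raw_scores: np.ndarray, labels: np.ndarray) -> BinCalibrator:
    """Fit the percentile-bin calibrator on raw margins and labels."""
    raw_scores = np.asarray(raw_scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if raw_scores.size < 20:
        raise ValueError("need at least 20 calibration scores")
    if labels.all() or not labels.any():
        raise ValueError("calibration requires both classes")
    lo, hi = np.percentile(raw_scores, config.CALIBRATION_PERCENTILES)
    if hi <= lo:
        hi = lo + 1e-8
    edges = np.linspace(lo, hi, config.CALIBRATION_N_BINS + 1)
    idx = np.clip(np.digitize(raw_scores, edges[1:-1]), 0,
                  config.CALIBRATION_N_BINS - 1)
    probs = np.full(config.CALIBRATION_N_BINS, np.nan)
    counts = np.zeros(config.CALIBRATION_N_BINS)
    for b in range(config.CALIBRATION_N_BINS):
        mask = idx == b
        counts[b] = mask.sum()
        if counts[b]:
            probs[b] = labels[mask].mean()
    # empty bins inherit the nearest populated bin
    filled = np.nonzero(~np.isnan(probs))[0]
    for b in np.nonzero(np.isnan(probs))[0]:
        probs[b] = probs[filled[np.argmin(np.abs(filled - b))]]
    return BinCalibrator(edges=edges, probabilities=probs, counts=counts)


@dataclass
class SvmEnsembleModel:
    """Normalizer + five calibrated Gaussian-kernel SVMs."""

    normalizer: Normalizer
    members: list[tuple[SVC, BinCalibrator]]
    C: float
    gamma: float
    seed: int
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if len(self.members) != config.N_ENSEMBLE_MEMBERS:
            raise ValueError(
                f"expected {config.N_ENSEMBLE_MEMBERS} members, "
                f"got {len(self.members)}"
            )

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path: str | Path) -> "SvmEnsembleModel":
        model = pickle.loads(Path(path).read_bytes())
        if not isinstance(model, cls):
            raise ValueError(f"{path} is not an ensemble model file")
        return model


def make_training_set(
    corpus: list[tuple[str, list[TrainingInstance]]],
    seed: int,
    n_subsets: int = config.N_ENSEMBLE_MEMBERS,
    n_native: int = config.UNDERSAMPLE_NATIVE,
    n_nonnative: int = config.UNDERSAMPLE_NONNATIVE,
) -> list[list[TrainingInstance]]:
    """Split proteins into disjoint subsets and undersample per protein.

    ``corpus`` maps each protein to all its candidate instances.  Each
    protein contributes at most ``n_native`` native and ``n_nonnative``
    non-native instances, sampled without replacement; proteins without
    any native decoy contact are skipped.
    """
    if len(corpus) < n_subsets:
        raise ValueError(f"need at least {n_subsets} proteins")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    subsets: list[list[TrainingInstance]] = [[] for _ in range(n_subsets)]
    for pos, ci in enumerate(order):
        pid, instances = corpus[ci]
        natives = [t for t in instances if t.native]
        others = [t for t in instances if not t.native]
        if not natives:
            import warnings

            warnings.warn(f"protein {pid}: no native decoy contacts, skipped")
            continue
        take_nat = (
            natives if len(natives) <= n_native
            else [natives[k] for k in rng.choice(len(natives), n_native,
                                                 replace=False)]
        )
        take_non = (
            others if len(others) <= n_nonnative
            else [others[k] for k in rng.choice(len(others), n_nonnative,
                                                replace=False)]
        )
        subsets[pos % n_subsets].extend(take_nat + take_non)
    return subsets


def _fit_member(
    instances: list[TrainingInstance],
    normalizer: Normalizer,
    C: float,
    gamma: float,
    seed: int,
) -> tuple[SVC, BinCalibrator]:
    """Train one SVM and calibrate it on internal out-of-fold margins."""
    x = normalizer.transform(np.array([t.features for t in instances]))
    y = np.array([t.native for t in instances])
    if y.all() or not y.any():
        raise ValueError("degenerate single-class training subset")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = np.array_split(order, config.CALIBRATION_CV_FOLDS)
    oof_scores = np.zeros(len(y))
    for fold in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[fold] = False
        if y[mask].all() or not y[mask].any():
            raise ValueError("degenerate fold during calibration")
        m = SVC(C=C, gamma=gamma, kernel="rbf")
        m.fit(x[mask], y[mask])
        oof_scores[fold] = m.decision_function(x[fold])
    calibrator = calibrate_bins(oof_scores, y)
    final = SVC(C=C, gamma=gamma, kernel="rbf")
    final.fit(x, y)
    return final, calibrator


def train_ensemble(
    subsets: list[list[TrainingInstance]],
    C: float = config.SVM_DEFAULT_C,
    gamma: float = config.SVM_DEFAULT_GAMMA,
    seed: int = 0,
) -> SvmEnsembleModel:
    """Fit the normalizer on the union and one calibrated SVM per subset."""
    if any(not s for s in subsets):
        raise ValueError("empty training subset")
    union = np.array([t.features for s in subsets for t in s])
    normalizer = Normalizer.fit(union)
    members = [
        _fit_member(s, normalizer, C, gamma, seed + k)
        for k, s in enumerate(subsets)
    ]
    return SvmEnsembleModel(
        normalizer=normalizer, members=members, C=C, gamma=gamma, seed=seed
    )


def predict_contact_probability(
    model: SvmEnsembleModel, fv: FeatureVector | np.ndarray
) -> float:
    """Mean of the five calibrated member probabilities, in [0, 1]."""
    flat = fv.flat if isinstance(fv, FeatureVector) else np.asarray(fv)
    if flat.size != TOTAL_INPUTS:
        raise ValueError(f"schema mismatch: {flat.size} != {TOTAL_INPUTS}")
    x = model.normalizer.transform(flat[None, :])
    return float(
        np.mean([cal(svm.decision_function(x)[0]) for svm, cal in model.members])
    )


def predict_batch(model: SvmEnsembleModel, x: np.ndarray) -> np.ndarray:
    """Vectorized ensemble probabilities for an (n, 238) feature matrix."""
    xn = model.normalizer.transform(x)
    probs = [cal(svm.decision_function(xn)) for svm, cal in model.members]
    return np.mean(probs, axis=0)


def _long_range_topk_accuracy(
    instances: list[TrainingInstance], scores: np.ndarray, divisor: int = 5,
    lengths: dict[str, int] | None = None,
) -> float:
    """Mean per-protein precision among the top L/divisor long-range
    candidates, with L taken from ``lengths`` (or the max index seen).

    Candidates are shuffled with a fixed RNG before the score sort so that
    score ties do not inherit the (label-ordered) pool order and reward a
    degenerate constant scorer.
    """
    by_protein: dict[str, list[int]] = {}
    for k, t in enumerate(instances):
        i, j = t.pair
        if j - i >= config.LONG_RANGE_MIN:
            by_protein.setdefault(t.protein_id, []).append(k)
    shuffler = np.random.default_rng(0)
    accs = []
    for pid, idxs in by_protein.items():
        if lengths and pid in lengths:
            L = lengths[pid]
        else:
            L = max(max(instances[k].pair) for k in idxs)
        n = max(1, L // divisor)
        idxs = [idxs[k] for k in shuffler.permutation(len(idxs))]
        top = sorted(idxs, key=lambda k: -scores[k])[:n]
        accs.append(np.mean([instances[k].native for k in top]))
    return float(np.mean(accs)) if accs else 0.0


def tune_hyperparameters(
    subsets: list[list[TrainingInstance]],
    C_grid: list[float],
    gamma_grid: list[float],
    k: int = 10,
    seed: int = 0,
    lengths: dict[str, int] | None = None,
) -> tuple[float, float]:
    """Grid-search (C, gamma) by k-fold cross-validation over proteins,
    maximizing long-range top-L/5 precision; ties prefer the smaller C,
    then the smaller gamma."""
    if not C_grid or not gamma_grid:
        raise ValueError("empty grid")
    pool = [t for s in subsets for t in s]
    proteins = sorted({t.protein_id for t in pool})
    rng = np.random.default_rng(seed)
    prot_order = rng.permutation(len(proteins))
    folds = np.array_split(prot_order, min(k, len(proteins)))
    x_all = np.array([t.features for t in pool])
    normalizer = Normalizer.fit(x_all)
    xn = normalizer.transform(x_all)
    y_all = np.array([t.native for t in pool])
    best = None
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            fold_accs = []
            for fold in folds:
                held = {proteins[p] for p in fold}
                test_idx = [k_ for k_, t in enumerate(pool) if t.protein_id in held]
                train_idx = [k_ for k_, t in enumerate(pool)
                             if t.protein_id not in held]
                if not test_idx or not train_idx:
                    continue
                ytr = y_all[train_idx]
                if ytr.all() or not ytr.any():
                    continue
                m = SVC(C=C, gamma=gamma, kernel="rbf")
                m.fit(xn[train_idx], ytr)
                scores = m.decision_function(xn[test_idx])
                fold_accs.append(
                    _long_range_topk_accuracy(
                        [pool[k_] for k_ in test_idx], scores, lengths=lengths
                    )
                )
            mean_acc = float(np.mean(fold_accs)) if fold_accs else 0.0
            if best is None or mean_acc > best[0] + 1e-12:
                best = (mean_acc, C, gamma)
    return best[1], best[2]
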