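"""Central configuration: thresholds, bin edges and data-table locations.

Every tunable constant of the pipeline lives here so that feature vectors
are stable across runs and alternative parameterizations (e.g. a different
contact potential table) can be swapped in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

#: Distance threshold defining a residue-residue contact (Angstrom, Cb/Ca).
CONTACT_THRESHOLD = 8.0

#: Minimum sequence separation for edges of the structural contact graph.
GRAPH_MIN_SEPARATION = 1

#: Minimum sequence separation of candidate contacts submitted to the
#: classifier (medium range and beyond; short-range pairs are trivial).
CANDIDATE_MIN_SEPARATION = 12

#: Sequence-separation windows of the standard contact-range classes.
MEDIUM_RANGE = (12, 23)
LONG_RANGE_MIN = 24

#: Chain break: consecutive CA-CA distance above this many Angstrom.
CHAIN_BREAK_CA_DISTANCE = 4.2

#: Fraction of lowest-energy decoys retained for prediction / training.
PREDICT_ENERGY_FRACTION = 0.02
TRAIN_ENERGY_FRACTION = 0.03

#: Relative solvent accessibility below which a residue counts as buried.
BURIED_RSA_THRESHOLD = 0.25

#: Backbone hydrogen bond: N...O distance cutoff (A) and min separation.
HBOND_NO_CUTOFF = 3.5
HBOND_MIN_SEPARATION = 2

#: Solvent probe radius and sphere sampling density for SASA.
SASA_PROBE_RADIUS = 1.4
SASA_N_POINTS = 92

#: van der Waals radii per element for SASA (A).
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
VDW_DEFAULT = 1.70

#: Pseudocount per cell of the pairwise-column frequency tables (MI).
MI_PSEUDOCOUNT = 0.05

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3, "X": 0.0,
}

# ---------------------------------------------------------------------------
# Fixed bin edges used by distribution-type features.  Inner edges only;
# implicit outer edges are -inf / +inf.
# ---------------------------------------------------------------------------

#: APC-corrected mutual information, 5 bins.
MI_BIN_EDGES = (0.05, 0.1, 0.2, 0.4)

#: Per-residue free solvation energy (kcal/mol), 4 bins.
SOLVATION_BIN_EDGES = (-1.0, 0.0, 1.0)

#: Contact potential values, 3 bins.
POTENTIAL_BIN_EDGES = (-4.0, -2.0)

#: Relative solvent accessibility, 3 bins.
RSA_BIN_EDGES = (0.25, 0.6)

#: Sequence conservation, 4 bins.
CONSERVATION_BIN_EDGES = (0.25, 0.5, 0.75)

#: Sequence-separation classes of the pairwise feature block.
SEPARATION_BIN_EDGES = (12, 24, 51)  # <12, 12-23, 24-50, >50

#: Protein length classes (upper bounds; last class open).
LENGTH_CLASS_EDGES = (50, 100, 150, 250, 400)

# ---------------------------------------------------------------------------
# SVM ensemble defaults
# ---------------------------------------------------------------------------

#: Number of ensemble members == number of disjoint protein subsets.
N_ENSEMBLE_MEMBERS = 5

#: Per-protein undersampling counts (native / non-native instances).
UNDERSAMPLE_NATIVE = 50
UNDERSAMPLE_NONNATIVE = 150

#: Soft-margin cost and Gaussian-kernel width used when tuning is skipped.
SVM_DEFAULT_C = 10.0
SVM_DEFAULT_GAMMA = 1.0 / 238.0

#: Calibration: percentile window and bin count for raw SVM margins.
CALIBRATION_PERCENTILES = (5.0, 95.0)
CALIBRATION_N_BINS = 10
CALIBRATION_CV_FOLDS = 5

# ---------------------------------------------------------------------------
# Score combination defaults
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CombinationWeights:
    """Weights of the linear score combination S + alpha*f + beta*g.

    ``beta`` switches between a shallow- and a deep-alignment value at
    ``depth_factor * L`` sequences, reflecting that evolutionary-coupling
    scores are only reliable for deep alignments.
    """

    alpha: float = 1.0
    beta_low: float = 0.2
    beta_high: float = 1.0
    depth_factor: float = 5.0

    def beta(self, depth: int, L: int) -> float:
        return self.beta_high if depth > self.depth_factor * L else self.beta_low


# ---------------------------------------------------------------------------
# Data tables shipped with the package
# ---------------------------------------------------------------------------


def _read_simple_tsv(name: str) -> dict[str, str]:
    out: dict[str, str] = {}
    text = resources.files("enscontact.data").joinpath(name).read_text()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t")
        out[key] = value
    return out


def load_max_sasa() -> dict[str, float]:
    """Per-residue maximum SASA (A^2) for RSA normalization."""
    return {k: float(v) for k, v in _read_simple_tsv("max_sasa.tsv").items()}


def load_chem_classes() -> dict[str, str]:
    """Seven-way chemical class per one-letter amino acid code."""
    return _read_simple_tsv("chem_classes.tsv")


def load_solvation_sigma() -> dict[str, float]:
    """Atomic solvation parameters per atom class (kcal/mol/A^2)."""
    return {k: float(v) for k, v in _read_simple_tsv("solvation_sigma.tsv").items()}


def load_contact_potential() -> dict[tuple[str, str], float]:
    """20x20 contact potential; symmetric lookup keyed by letter pairs."""
    text = (
        resources.files("enscontact.data")
        .joinpath("contact_potential_synthetic.tsv")
        .read_text()
    )
    rows = [l.split("\t") for l in text.splitlines() if l and not l.startswith("#")]
    header = rows[0][1:]
    table: dict[tuple[str, str], float] = {}
    for row in rows[1:]:
        a = row[0]
        for b, val in zip(header, row[1:]):
            table[(a, b)] = float(val)
    return table


CHEM_CLASSES = ("hydrophobic", "aromatic", "polar", "positive", "negative",
                "glycine", "proline")
SS3_CLASSES = ("H", "E", "C")
SS7_CLASSES = ("H", "G", "I", "E", "B", "T", "C")
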