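"""The six peptide descriptor families and the frozen 643-column feature matrix.

Per sequence: amino-acid composition (20), dipeptide composition (400),
pseudo amino-acid composition (30, Chou type I, lambda=10), amphiphilic
pseudo amino-acid composition (40, Chou type II, lambda=10), CTD over seven
physicochemical properties (7 x 21 = 147), and six secondary-structure
summary features.  20 + 400 + 30 + 40 + 147 + 6 = 643, in a fixed,
documented column order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence_io import AMINO_ACIDS, LabeledDataset, ProteinRecord

# ---------------------------------------------------------------------------
# Physicochemical scales (canonical PseAAC tables).
# H1: hydrophobicity; H2: hydrophilicity (Hopp-Woods); M: side-chain mass.
# ---------------------------------------------------------------------------
HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}
HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}
SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}


def _standardize(scale: dict[str, float]) -> dict[str, float]:
    vals = np.array([scale[a] for a in AMINO_ACIDS])
    return dict(zip(AMINO_ACIDS, (vals - vals.mean()) / vals.std()))


_H1 = _standardize(HYDROPHOBICITY)
_H2 = _standardize(HYDROPHILICITY)
_M = _standardize(SIDE_CHAIN_MASS)

# ---------------------------------------------------------------------------
# Chou-Fasman conformational propensities (helix / strand / turn-coil),
# used by the deterministic secondary-structure predictor.
# ---------------------------------------------------------------------------
HELIX_PROPENSITY = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
    "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
    "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
    "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
}
SHEET_PROPENSITY = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
}
COIL_PROPENSITY = {
    "A": 0.66, "R": 0.95, "N": 1.56, "D": 1.46, "C": 1.19,
    "Q": 0.98, "E": 0.74, "G": 1.56, "H": 0.95, "I": 0.47,
    "L": 0.59, "K": 1.01, "M": 0.60, "F": 0.60, "P": 1.52,
    "S": 1.43, "T": 0.96, "W": 0.96, "Y": 1.14, "V": 0.50,
}

# ---------------------------------------------------------------------------
# CTD: the standard three-group partitions for seven properties.
# ---------------------------------------------------------------------------
CTD_PROPERTIES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ACFGHILMNPQSTVWY", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}


def property_group_map(property_name: str) -> dict[str, int]:
    """residue -> group index in {1, 2, 3} for one CTD property."""
    groups = CTD_PROPERTIES[property_name]
    return {aa: g + 1 for g, members in enumerate(groups) for aa in members}


@dataclass(frozen=True)
class DescriptorConfig:
    """Tunable descriptor parameters.

    pseaac_lambda / apaac_lambda set the sequence-order correlation depth
    (defaults 10, giving the 30D and 40D vectors); the weights balance
    composition against correlation terms; ss_window is the smoothing
    window of the secondary-structure predictor (odd).
    """

    pseaac_lambda: int = 10
    pseaac_weight: float = 0.05
    apaac_lambda: int = 10
    apaac_weight: float = 0.05
    ss_window: int = 5

    def __post_init__(self):
        if self.pseaac_lambda < 1 or self.apaac_lambda < 1:
            raise ValueError("lambda must be a positive integer")
        if self.pseaac_weight <= 0 or self.apaac_weight <= 0:
            raise ValueError("weights must be positive")
        if self.ss_window < 1 or self.ss_window % 2 == 0:
            raise ValueError("ss_window must be an odd positive integer")

    @property
    def min_length(self) -> int:
        return max(self.pseaac_lambda, self.apaac_lambda) + 1


# ---------------------------------------------------------------------------
# Composition descriptors
# ---------------------------------------------------------------------------

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
DIPEPTIDES = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)


def aac(record: ProteinRecord) -> np.ndarray:
    """Amino-acid composition: fraction of each residue type (sums to 1)."""
    seq = record.sequence
    counts = np.zeros(20)
    for ch in seq:
        counts[_AA_INDEX[ch]] += 1
    return counts / len(seq)


def dipeptide_composition(record: ProteinRecord) -> np.ndarray:
    """Fractions of the 400 adjacent residue pairs; denominator L-1."""
    seq = record.sequence
    if len(seq) < 2:
        raise ValueError(f"record {record.id!r}: dipeptide composition needs L >= 2")
    counts = np.zeros(400)
    for i in range(len(seq) - 1):
        counts[_AA_INDEX[seq[i]] * 20 + _AA_INDEX[seq[i + 1]]] += 1
    return counts / (len(seq) - 1)


def pseaac(record: ProteinRecord, config: DescriptorConfig = DescriptorConfig()) -> np.ndarray:
    """Chou type-I pseudo amino-acid composition (20 + lambda components).

    The correlation factor theta_j averages, over residue pairs j apart, the
    mean squared difference of standardized hydrophobicity, hydrophilicity
    and side-chain mass; composition and correlation terms are jointly
    normalized so the vector sums to 1.
    """
    lam, w = config.pseaac_lambda, config.pseaac_weight
    seq = record.sequence
    L = len(seq)
    if L <= lam:
        raise ValueError(
            f"record {record.id!r}: length {L} too short for pseaac "
            f"(minimum {lam + 1} residues)"
        )
    h1 = np.array([_H1[a] for a in seq])
    h2 = np.array([_H2[a] for a in seq])
    m = np.array([_M[a] for a in seq])
    theta = np.empty(lam)
    for j in range(1, lam + 1):
        d = (
            (h1[:-j] - h1[j:]) ** 2
            + (h2[:-j] - h2[j:]) ** 2
            + (m[:-j] - m[j:]) ** 2
        ) / 3.0
        theta[j - 1] = d.mean()
    f = aac(record)
    denom = f.sum() + w * theta.sum()
    return np.concatenate([f / denom, w * theta / denom])


def apaac(record: ProteinRecord, config: DescriptorConfig = DescriptorConfig()) -> np.ndarray:
    """Chou type-II amphiphilic pseudo AAC (20 + 2*lambda components).

    tau_{2j-1} and tau_{2j} are lag-j autocorrelations of standardized
    hydrophobicity and hydrophilicity respectively.
    """
    lam, w = config.apaac_lambda, config.apaac_weight
    seq = record.sequence
    L = len(seq)
    if L <= lam:
        raise ValueError(
            f"record {record.id!r}: length {L} too short for apaac "
            f"(minimum {lam + 1} residues)"
        )
    h1 = np.array([_H1[a] for a in seq])
    h2 = np.array([_H2[a] for a in seq])
    tau = np.empty(2 * lam)
    for j in range(1, lam + 1):
        tau[2 * j - 2] = (h1[:-j] * h1[j:]).mean()
        tau[2 * j - 1] = (h2[:-j] * h2[j:]).mean()
    f = aac(record)
    denom = f.sum() + w * tau.sum()
    return np.concatenate([f / denom, w * tau / denom])


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

def _groups_of(seq: str, gmap: dict[str, int]) -> np.ndarray:
    return np.array([gmap[a] for a in seq])


def ctd_composition(record: ProteinRecord, property_name: str) -> np.ndarray:
    """Fraction of residues in each of the 3 groups; sums to 1."""
    g = _groups_of(record.sequence, property_group_map(property_name))
    return np.array([(g == k).mean() for k in (1, 2, 3)])


def ctd_transition(record: ProteinRecord, property_name: str) -> np.ndarray:
    """For each unordered group pair {g,h}, the fraction of adjacent
    positions whose groups are exactly {g,h}; denominator L-1."""
    seq = record.sequence
    if len(seq) < 2:
        raise ValueError(f"record {record.id!r}: transition needs L >= 2")
    g = _groups_of(seq, property_group_map(property_name))
    a, b = g[:-1], g[1:]
    out = np.empty(3)
    for i, (p, q) in enumerate(((1, 2), (1, 3), (2, 3))):
        out[i] = (((a == p) & (b == q)) | ((a == q) & (b == p))).sum()
    return out / (len(seq) - 1)


def ctd_distribution(record: ProteinRecord, property_name: str) -> np.ndarray:
    """Per group: 100*position/L of the first residue and of the residues at
    the 25/50/75/100% fractiles of the group's occurrences (index
    max(1, floor(q*n_g)) into the ascending positions); zeros if absent."""
    seq = record.sequence
    L = len(seq)
    g = _groups_of(seq, property_group_map(property_name))
    out = np.zeros(15)
    for k in (1, 2, 3):
        pos = np.flatnonzero(g == k) + 1  # 1-based
        n = len(pos)
        if n == 0:
            continue
        idx = [1] + [max(1, int(np.floor(q * n))) for q in (0.25, 0.5, 0.75, 1.0)]
        out[(k - 1) * 5 : k * 5] = [100.0 * pos[i - 1] / L for i in idx]
    return out


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

def predict_secondary_structure(
    record: ProteinRecord, config: DescriptorConfig = DescriptorConfig()
) -> str:
    """Deterministic propensity-based three-state prediction over {H, E, C}.

    Per residue the state with the highest Chou-Fasman propensity is taken
    (ties resolved C, then H, then E), then smoothed by majority vote over a
    sliding window of ss_window residues centred on each position (window
    truncated at the termini; vote ties resolved C, then H, then E).
    """
    seq = record.sequence
    order = ("C", "H", "E")  # tie preference
    raw = []
    for a in seq:
        scores = {"H": HELIX_PROPENSITY[a], "E": SHEET_PROPENSITY[a], "C": COIL_PROPENSITY[a]}
        best = max(order, key=lambda s: scores[s])
        raw.append(best)
    half = config.ss_window // 2
    smoothed = []
    for i in range(len(raw)):
        window = raw[max(0, i - half) : i + half + 1]
        counts = {s: window.count(s) for s in "HEC"}
        smoothed.append(max(order, key=lambda s: counts[s]))
    return "".join(smoothed)


def ss_features(state_string: str) -> np.ndarray:
    """Six summary features of an {H,E,C} state string: per state, the
    composition (count/L) and the longest-run fraction (longest maximal
    consecutive run / L), ordered H, E, C."""
    if not state_string:
        raise ValueError("empty state string")
    L = len(state_string)
    out = np.empty(6)
    for i, s in enumerate("HEC"):
        out[2 * i] = state_string.count(s) / L
        longest = run = 0
        for ch in state_string:
            run = run + 1 if ch == s else 0
            longest = max(longest, run)
        out[2 * i + 1] = longest / L
    return out


# ---------------------------------------------------------------------------
# Frozen feature-name inventory and matrix assembly
# ---------------------------------------------------------------------------

def feature_names(config: DescriptorConfig = DescriptorConfig()) -> list[str]:
    """The frozen 643-column order: AAC, DPC, PseAAC, APAAC, CTD, SS."""
    names = [f"AAC_{a}" for a in AMINO_ACIDS]
    names += [f"DPC_{d}" for d in DIPEPTIDES]
    names += [f"PAAC_{a}" for a in AMINO_ACIDS]
    names += [f"PAAC_lam{j}" for j in range(1, config.pseaac_lambda + 1)]
    names += [f"APAAC_{a}" for a in AMINO_ACIDS]
    for j in range(1, config.apaac_lambda + 1):
        names += [f"APAAC_H1_lam{j}", f"APAAC_H2_lam{j}"]
    for prop in CTD_PROPERTIES:
        names += [f"CTD_{prop}_C_g{k}" for k in (1, 2, 3)]
        names += [f"CTD_{prop}_T_{p}{q}" for p, q in ((1, 2), (1, 3), (2, 3))]
        for k in (1, 2, 3):
            names += [
                f"CTD_{prop}_D_g{k}_{tag}" for tag in ("first", "q25", "q50", "q75", "q100")
            ]
    names += [f"SS_comp_{s}" for s in "HEC"] + [f"SS_run_{s}" for s in "HEC"]
    return names


def descriptor_vector(record: ProteinRecord, config: DescriptorConfig = DescriptorConfig()) -> np.ndarray:
    parts = [aac(record), dipeptide_composition(record), pseaac(record, config), apaac(record, config)]
    for prop in CTD_PROPERTIES:
        parts += [
            ctd_composition(record, prop),
            ctd_transition(record, prop),
            ctd_distribution(record, prop),
        ]
    parts.append(ss_features(predict_secondary_structure(record, config)))
    return np.concatenate(parts)


def build_feature_matrix(
    dataset: LabeledDataset, config: DescriptorConfig = DescriptorConfig()
) -> pd.DataFrame:
    """One row per record, 643 named columns in frozen order; raises with the
    offending ids if any sequence is shorter than the PseAAC minimum."""
    too_short = [r.id for r in dataset if r.length < config.min_length]
    if too_short:
        raise ValueError(
            f"sequences shorter than {config.min_length} residues cannot be "
            f"encoded: {', '.join(too_short)}"
        )
    names = feature_names(config)
    rows = np.vstack([descriptor_vector(r, config) for r in dataset])
    if not np.isfinite(rows).all():
        raise ValueError("non-finite descriptor values")  # pragma: no cover
    return pd.DataFrame(rows, index=[r.id for r in dataset], columns=names)


def labels_vector(dataset: LabeledDataset) -> np.ndarray:
    return np.array([r.label for r in dataset])
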