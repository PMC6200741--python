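"""Compositional molecular descriptors for peptide sequences.

Five descriptor sets:

* AAC — amino-acid composition: fraction of each of the 20 residues (20 dims).
* DC  — dipeptide composition: fraction of each adjacent residue pair over
  the L-1 windows (400 dims).
* TC  — tripeptide composition: fraction of each adjacent residue triple
  over the L-2 windows (8000 dims).
* PC-PseAAC — type-1 (parallel-correlation) pseudo-amino-acid composition:
  AAC augmented with lambda sequence-order correlation factors computed
  from three standardized physicochemical residue properties
  (hydrophobicity, hydrophilicity, side-chain mass); 20 + lambda dims.
* SC-PseAAC — type-2 (series-correlation) variant with per-property
  correlation factors for hydrophobicity and hydrophilicity; 20 + 2*lambda
  dims.

Plus matrix-level operations: dataset featurization with namespaced feature
names, all-zero column removal, and train-set standardization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, LabeledDataset

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DIPEPTIDES = ["".join(p) for p in itertools.product(AMINO_ACIDS, repeat=2)]
TRIPEPTIDES = ["".join(p) for p in itertools.product(AMINO_ACIDS, repeat=3)]
_DI_INDEX = {d: i for i, d in enumerate(DIPEPTIDES)}
_TRI_INDEX = {t: i for i, t in enumerate(TRIPEPTIDES)}

DESCRIPTOR_SETS = ("aac", "dc", "tc", "pc_pseaac", "sc_pseaac")
_PREFIX = {
    "aac": "AAC",
    "dc": "DC",
    "tc": "TC",
    "pc_pseaac": "PCPSE",
    "sc_pseaac": "SCPSE",
}

# Canonical residue property values used throughout the pseudo-amino-acid
# composition literature: hydrophobicity (Tanford scale as adopted by Chou),
# hydrophilicity (Hopp-Woods) and side-chain mass, per residue A..Y in the
# fixed alphabetical order.
_RAW_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_RAW_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_RAW_SIDECHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


@dataclass(frozen=True)
class PropertyTable:
    """Residue property vectors standardized over the 20 amino acids.

    Each row of ``values`` is one property (hydrophobicity, hydrophilicity,
    side-chain mass), zero mean and unit population variance over the 20
    residues, columns in the fixed alphabetical residue order.
    """

    values: np.ndarray  # shape (3, 20)
    names: tuple[str, ...] = ("hydrophobicity", "hydrophilicity", "sidechain_mass")

    @classmethod
    def default(cls) -> "PropertyTable":
        raw = np.array(
            [
                [_RAW_HYDROPHOBICITY[aa] for aa in AMINO_ACIDS],
                [_RAW_HYDROPHILICITY[aa] for aa in AMINO_ACIDS],
                [_RAW_SIDECHAIN_MASS[aa] for aa in AMINO_ACIDS],
            ]
        )
        std = (raw - raw.mean(axis=1, keepdims=True)) / raw.std(axis=1, keepdims=True)
        return cls(values=std)

    def prop(self, which: int, residue: str) -> float:
        return float(self.values[which, _AA_INDEX[residue]])


@dataclass
class DescriptorMatrix:
    """n x p feature table with namespaced feature names.

    Feature names carry a descriptor prefix ("AAC:", "DC:", "TC:",
    "PCPSE:", "SCPSE:") so per-descriptor provenance survives merging,
    selection and reordering.
    """

    peptide_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.peptide_ids), len(self.feature_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.peptide_ids)} ids x {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")

    @property
    def n(self) -> int:
        return len(self.peptide_ids)

    @property
    def p(self) -> int:
        return len(self.feature_names)

    def provenance(self) -> dict[str, str]:
        """Map feature name -> descriptor set prefix."""
        return {name: name.split(":", 1)[0] for name in self.feature_names}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.peptide_ids, columns=self.feature_names)

    def to_csv(self, path, labels: dict[str, str] | None = None) -> None:
        df = self.to_frame()
        df.insert(0, "id", self.peptide_ids)
        if labels is not None:
            df["label"] = [labels[i] for i in self.peptide_ids]
        df.to_csv(path, index=False)

    def subset_columns(self, names: list[str]) -> "DescriptorMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return DescriptorMatrix(
            peptide_ids=list(self.peptide_ids),
            feature_names=list(names),
            values=self.values[:, idx],
        )


def compute_aac(sequence: str) -> np.ndarray:
    """Amino-acid composition: count of each residue / sequence length."""
    if len(sequence) < 1:
        raise ValueError("empty sequence")
    vec = np.zeros(20)
    for ch in sequence:
        vec[_AA_INDEX[ch]] += 1
    return vec / len(sequence)


def compute_dc(sequence: str) -> np.ndarray:
    """Dipeptide composition over the L-1 adjacent windows."""
    L = len(sequence)
    if L < 2:
        raise ValueError(f"sequence length {L} < 2; dipeptides undefined")
    vec = np.zeros(400)
    for i in range(L - 1):
        vec[_DI_INDEX[sequence[i : i + 2]]] += 1
    return vec / (L - 1)


def compute_tc(sequence: str) -> np.ndarray:
    """Tripeptide composition over the L-2 adjacent windows (8000 dims)."""
    L = len(sequence)
    if L < 3:
        raise ValueError(f"sequence length {L} < 3; tripeptides undefined")
    vec = np.zeros(8000)
    for i in range(L - 2):
        vec[_TRI_INDEX[sequence[i : i + 3]]] += 1
    return vec / (L - 2)


def compute_pc_pseaac(
    sequence: str,
    lam: int = 3,
    w: float = 0.05,
    props: PropertyTable | None = None,
) -> np.ndarray:
    """Type-1 (parallel-correlation) pseudo-amino-acid composition.

    The correlation factor for gap j averages, over the three properties,
    the squared property difference between residues j apart:

        theta_j = (1/(L-j)) * sum_i Theta(R_i, R_{i+j}),
        Theta(a, b) = mean_g (P_g(a) - P_g(b))^2.

    Components 1..20 are f_u / (sum f + w sum theta); components 20+j are
    w theta_j / the same denominator, so the vector is nonnegative and
    sums to 1.
    """
    if props is None:
        props = PropertyTable.default()
    L = len(sequence)
    if lam < 1:
        raise ValueError(f"lambda must be >= 1, got {lam}")
    if L <= lam:
        raise ValueError(f"sequence length {L} must exceed lambda {lam}")
    if w <= 0:
        raise ValueError(f"weight must be positive, got {w}")

    pv = props.values[:, [_AA_INDEX[c] for c in sequence]]  # (3, L)
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        diffs = pv[:, :-j] - pv[:, j:]
        thetas[j - 1] = np.mean(diffs**2, axis=0).sum() / (L - j)

    f = compute_aac(sequence)
    denom = f.sum() + w * thetas.sum()
    return np.concatenate([f / denom, w * thetas / denom])


def compute_sc_pseaac(
    sequence: str,
    lam: int = 3,
    w: float = 0.05,
    props: PropertyTable | None = None,
) -> np.ndarray:
    """Type-2 (series-correlation) pseudo-amino-acid composition.

    Correlation factors are kept per property for hydrophobicity (g=1) and
    hydrophilicity (g=2):

        tau_{2(j-1)+g} = (1/(L-j)) * sum_i H_g(R_i) * H_g(R_{i+j}),

    giving 2*lambda pseudo components; normalization divides by
    sum f + w sum tau. Because the standardized property values take both
    signs, tau (hence pseudo components) may be negative; the vector still
    sums to 1.
    """
    if props is None:
        props = PropertyTable.default()
    L = len(sequence)
    if lam < 1:
        raise ValueError(f"lambda must be >= 1, got {lam}")
    if L <= lam:
        raise ValueError(f"sequence length {L} must exceed lambda {lam}")
    if w <= 0:
        raise ValueError(f"weight must be positive, got {w}")

    pv = props.values[:2, [_AA_INDEX[c] for c in sequence]]  # (2, L)
    taus = np.empty(2 * lam)
    for j in range(1, lam + 1):
        prod = pv[:, :-j] * pv[:, j:]
        mean = prod.sum(axis=1) / (L - j)
        taus[2 * (j - 1)] = mean[0]
        taus[2 * (j - 1) + 1] = mean[1]

    f = compute_aac(sequence)
    denom = f.sum() + w * taus.sum()
    return np.concatenate([f / denom, w * taus / denom])


def _feature_names(set_name: str, lam: int) -> list[str]:
    prefix = _PREFIX[set_name]
    if set_name == "aac":
        return [f"{prefix}:{aa}" for aa in AMINO_ACIDS]
    if set_name == "dc":
        return [f"{prefix}:{d}" for d in DIPEPTIDES]
    if set_name == "tc":
        return [f"{prefix}:{t}" for t in TRIPEPTIDES]
    if set_name == "pc_pseaac":
        return [f"{prefix}:{aa}" for aa in AMINO_ACIDS] + [
            f"{prefix}:theta{j}" for j in range(1, lam + 1)
        ]
    if set_name == "sc_pseaac":
        return [f"{prefix}:{aa}" for aa in AMINO_ACIDS] + [
            f"{prefix}:tau{j}.{g}" for j in range(1, lam + 1) for g in (1, 2)
        ]
    raise ValueError(f"unknown descriptor set {set_name!r}")


def featurize_dataset(
    dataset: LabeledDataset,
    sets: tuple[str, ...] = ("aac", "dc", "tc"),
    pseaac_lambda: int = 3,
    pseaac_w: float = 0.05,
    props: PropertyTable | None = None,
) -> DescriptorMatrix:
    """Compute and column-concatenate the requested descriptor sets.

    Rows follow dataset record order; column blocks follow the requested
    set order with namespace prefixes. A sequence too short for a requested
    set raises an error naming the record.
    """
    unknown = set(sets) - set(DESCRIPTOR_SETS)
    if unknown:
        raise ValueError(f"unknown descriptor sets {sorted(unknown)}")
    if props is None:
        props = PropertyTable.default()

    fns = {
        "aac": lambda s: compute_aac(s),
        "dc": lambda s: compute_dc(s),
        "tc": lambda s: compute_tc(s),
        "pc_pseaac": lambda s: compute_pc_pseaac(s, pseaac_lambda, pseaac_w, props),
        "sc_pseaac": lambda s: compute_sc_pseaac(s, pseaac_lambda, pseaac_w, props),
    }
    blocks = []
    names: list[str] = []
    for set_name in sets:
        rows = []
        for rec in dataset.records:
            try:
                rows.append(fns[set_name](rec.sequence))
            except ValueError as exc:
                raise ValueError(f"record {rec.id!r}: {exc}") from exc
        blocks.append(np.vstack(rows))
        names.extend(_feature_names(set_name, pseaac_lambda))
    return DescriptorMatrix(
        peptide_ids=dataset.ids,
        feature_names=names,
        values=np.hstack(blocks),
    )


def remove_zero_features(matrix: DescriptorMatrix) -> DescriptorMatrix:
    """Drop columns whose value is zero in every row, preserving order."""
    keep = ~(matrix.values == 0).all(axis=0)
    return DescriptorMatrix(
        peptide_ids=list(matrix.peptide_ids),
        feature_names=[n for n, k in zip(matrix.feature_names, keep) if k],
        values=matrix.values[:, keep],
    )


@dataclass
class Standardizer:
    """Per-feature z-scoring with statistics learned from a fitting subset.

    Features with zero spread on the fitting rows map to 0. The sd
    convention (ddof) is recorded so transforms are reproducible.
    """

    mean: np.ndarray
    sd: np.ndarray
    ddof: int = 1

    def transform(self, values: np.ndarray) -> np.ndarray:
        sd = np.where(self.sd == 0, 1.0, self.sd)
        out = (values - self.mean) / sd
        out[:, self.sd == 0] = 0.0
        return out

    def transform_matrix(self, matrix: DescriptorMatrix) -> DescriptorMatrix:
        return DescriptorMatrix(
            peptide_ids=list(matrix.peptide_ids),
            feature_names=list(matrix.feature_names),
            values=self.transform(matrix.values),
        )


def fit_standardizer(
    matrix: DescriptorMatrix, fit_rows: np.ndarray | list[int] | None = None, ddof: int = 1
) -> Standardizer:
    """Learn per-feature mean/sd on ``fit_rows`` only (default: all rows)."""
    rows = matrix.values if fit_rows is None else matrix.values[np.asarray(fit_rows)]
    if rows.shape[0] == 0:
        raise ValueError("fit_rows is empty")
    if ddof >= rows.shape[0]:
        raise ValueError(f"need more than {ddof} fitting rows for ddof={ddof}")
    return Standardizer(
        mean=rows.mean(axis=0), sd=rows.std(axis=0, ddof=ddof), ddof=ddof
    )
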