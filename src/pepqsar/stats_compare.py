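"""Significance cascade for comparing model performance vectors.

Given an N-blocks x k-models matrix of AUC values, the cascade first
checks the preconditions of parametric ANOVA — Shapiro-Wilk normality of
the pooled values and Bartlett homoscedasticity across models — and, when
either fails (the usual outcome for bounded performance metrics), proceeds
nonparametrically: the Friedman rank test with the Iman-Davenport F
extension for an omnibus difference, followed by Finner step-down adjusted
pairwise comparisons of every model against the best-ranked control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PerformanceBlockMatrix:
    """N x k performance values: rows are replicated experiments (blocks),
    columns are the compared models."""

    values: np.ndarray
    model_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (blocks x models)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError(f"need N >= 2 blocks and k >= 2 models, got {n} x {k}")
        if len(self.model_labels) != k:
            raise ValueError("one label per model column required")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PerformanceBlockMatrix":
        return cls(values=frame.to_numpy(), model_labels=list(frame.columns))

    @property
    def n_blocks(self) -> int:
        return self.values.shape[0]

    @property
    def k_models(self) -> int:
        return self.values.shape[1]


@dataclass
class ComparisonReport:
    shapiro_W: float
    shapiro_p: float
    normality_rejected: bool
    bartlett_K2: float
    bartlett_df: int
    bartlett_p: float
    homoscedasticity_rejected: bool
    friedman_chi2: float
    iman_davenport_F: float
    df1: int
    df2: int
    friedman_p: float
    degenerate_concordance: bool
    average_ranks: dict[str, float]
    control: str
    posthoc: pd.DataFrame  # columns: model, z, p_raw, p_adjusted, rejected
    alpha: float

    def indistinguishable_from_control(self) -> list[str]:
        """Models not significantly different from the control."""
        return self.posthoc.loc[~self.posthoc["rejected"], "model"].tolist()

    def summary(self) -> str:
        lines = [
            f"Shapiro-Wilk: W={self.shapiro_W:.4f}, p={self.shapiro_p:.4g} "
            f"({'normality rejected' if self.normality_rejected else 'normality not rejected'})",
            f"Bartlett: K2={self.bartlett_K2:.4f}, df={self.bartlett_df}, "
            f"p={self.bartlett_p:.4g}",
            f"Friedman chi2={self.friedman_chi2:.4f}; Iman-Davenport "
            f"F({self.df1},{self.df2})={self.iman_davenport_F:.4f}, p={self.friedman_p:.4g}",
            f"Control model (best mean rank): {self.control}",
        ]
        for _, row in self.posthoc.iterrows():
            verdict = "rejected" if row["rejected"] else "not rejected"
            lines.append(
                f"  vs {row['model']}: p_raw={row['p_raw']:.4g}, "
                f"p_adj={row['p_adjusted']:.4g} ({verdict})"
            )
        return "\n".join(lines)


def gate_normality(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk test; verdict True means normality rejected (p < alpha)."""
    values = np.asarray(values, dtype=float).ravel()
    if not 3 <= len(values) <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {len(values)}")
    if np.ptp(values) == 0:
        raise ValueError("constant input: normality test undefined")
    W, p = stats.shapiro(values)
    return float(W), float(p), bool(p < alpha)


def gate_homoscedasticity(
    matrix: PerformanceBlockMatrix, alpha: float = 0.05
) -> tuple[float, int, float, bool]:
    """Bartlett's test across model columns; df = k - 1.

    Returns (K2, df, p, rejected) where rejected=True means equal variances
    are rejected at alpha.
    """
    cols = [matrix.values[:, j] for j in range(matrix.k_models)]
    for j, c in enumerate(cols):
        if len(c) < 2 or np.var(c) == 0:
            raise ValueError(f"column {matrix.model_labels[j]!r} has zero variance")
    K2, p = stats.bartlett(*cols)
    return float(K2), matrix.k_models - 1, float(p), bool(p < alpha)


def _block_ranks(values: np.ndarray) -> np.ndarray:
    """Within-block ranks of models; larger value -> better (higher) rank
    number is NOT assumed: ranks are assigned ascending so the best model
    has the LOWEST average rank, the standard Friedman convention for
    performance where we rank descending. Here we rank descending values
    (rank 1 = best AUC), ties get mean ranks."""
    # rankdata ranks ascending; negate so the largest value gets rank 1
    return np.vstack([stats.rankdata(-row) for row in values])


def friedman_iman_davenport(
    matrix: PerformanceBlockMatrix,
) -> tuple[float, float, int, int, float, dict[str, float], bool]:
    """Friedman chi-square with tie correction and the Iman-Davenport F.

    chi2_F = [12N/(k(k+1))] * [sum_j Rbar_j^2 - k(k+1)^2/4], corrected for
    within-block ties; F_ID = (N-1) chi2_F / (N(k-1) - chi2_F) with
    (k-1, (k-1)(N-1)) degrees of freedom. Perfect concordance makes the
    F denominator zero; that case is flagged and reported as p below
    machine precision rather than a division error.
    """
    N, k = matrix.n_blocks, matrix.k_models
    ranks = _block_ranks(matrix.values)
    rbar = ranks.mean(axis=0)
    chi2 = 12.0 * N / (k * (k + 1)) * (np.sum(rbar**2) - k * (k + 1) ** 2 / 4.0)
    # standard tie correction: divide by 1 - sum(t^3 - t) / (N k (k^2 - 1))
    tie_sum = 0.0
    for row in matrix.values:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (N * k * (k**2 - 1))
    if correction <= 0:
        # every block entirely tied: no evidence of any difference
        chi2_c = 0.0
    else:
        chi2_c = chi2 / correction
    df1, df2 = k - 1, (k - 1) * (N - 1)
    denom = N * (k - 1) - chi2_c
    degenerate = bool(np.isclose(denom, 0.0) or denom < 0)
    if degenerate:
        F = np.inf
        p = float(np.nextafter(0, 1))
    else:
        F = (N - 1) * chi2_c / denom
        p = float(stats.f.sf(F, df1, df2))
    avg_ranks = dict(zip(matrix.model_labels, rbar))
    return float(chi2_c), float(F), df1, df2, p, avg_ranks, degenerate


def finner_posthoc(
    matrix: PerformanceBlockMatrix, control: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Finner step-down adjusted comparisons of each model vs the control.

    z_i = (Rbar_i - Rbar_control) / sqrt(k(k+1)/(6N)); raw p two-sided
    normal; adjusted p_(i) = max_{j<=i} min(1, 1 - (1 - p_(j))^((k-1)/j)).
    """
    if control not in matrix.model_labels:
        raise ValueError(f"control {control!r} not among models {matrix.model_labels}")
    N, k = matrix.n_blocks, matrix.k_models
    ranks = _block_ranks(matrix.values)
    rbar = dict(zip(matrix.model_labels, ranks.mean(axis=0)))
    se = np.sqrt(k * (k + 1) / (6.0 * N))

    rows = []
    for label in matrix.model_labels:
        if label == control:
            continue
        z = (rbar[label] - rbar[control]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append({"model": label, "z": z, "p_raw": min(1.0, p_raw)})
    df = pd.DataFrame(rows).sort_values("p_raw", kind="mergesort").reset_index(drop=True)

    m = k - 1  # number of comparisons
    adjusted = []
    running_max = 0.0
    for i, p in enumerate(df["p_raw"], start=1):
        adj = min(1.0, 1.0 - (1.0 - p) ** (m / i))
        running_max = max(running_max, adj)
        adjusted.append(running_max)
    df["p_adjusted"] = adjusted
    df["rejected"] = df["p_adjusted"] < alpha
    return df


def run_cascade(matrix: PerformanceBlockMatrix, alpha: float = 0.05) -> ComparisonReport:
    """Full comparison: parametric gates, then the nonparametric cascade.

    The control is the model with the best (lowest) Friedman mean rank,
    ties broken by higher column mean, then label order.
    """
    W, p_sw, norm_rej = gate_normality(matrix.values.ravel(), alpha)
    K2, df_b, p_b, homo_rej = gate_homoscedasticity(matrix, alpha)
    chi2, F, df1, df2, p_f, avg_ranks, degenerate = friedman_iman_davenport(matrix)

    means = matrix.values.mean(axis=0)
    order = sorted(
        range(matrix.k_models),
        key=lambda j: (avg_ranks[matrix.model_labels[j]], -means[j], matrix.model_labels[j]),
    )
    control = matrix.model_labels[order[0]]
    posthoc = finner_posthoc(matrix, control, alpha)
    return ComparisonReport(
        shapiro_W=W,
        shapiro_p=p_sw,
        normality_rejected=norm_rej,
        bartlett_K2=K2,
        bartlett_df=df_b,
        bartlett_p=p_b,
        homoscedasticity_rejected=homo_rej,
        friedman_chi2=chi2,
        iman_davenport_F=F,
        df1=df1,
        df2=df2,
        friedman_p=p_f,
        degenerate_concordance=degenerate,
        average_ranks=avg_ranks,
        control=control,
        posthoc=posthoc,
        alpha=alpha,
    )
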