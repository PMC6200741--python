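"""Univariate two-sample t-test filter feature selection.

Features are ranked by the p-value of a per-feature two-sample t test
between the two activity classes (Welch's unequal-variance test by
default, pooled-variance behind a flag). Ties in p are broken by larger
|t|, then by feature name, so rankings are deterministic across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import DescriptorMatrix
from .io import ANTI, NON_ANTI

#: Subset sizes explored per descriptor configuration.
DEFAULT_SUBSET_SCHEDULE: dict[str, list[int]] = {
    "aac": [5, 10, 15],
    "dc": [25, 50, 75, 100],
    "tc": [75, 100, 125, 150],
    "merged": [50, 100, 150, 200],
}


@dataclass
class FeatureRanking:
    """Features ordered by ascending p-value with 1-based ranks."""

    entries: pd.DataFrame  # columns: feature, t, p, rank
    grouping_label: str = f"{ANTI} vs {NON_ANTI}"

    @property
    def ordered_features(self) -> list[str]:
        return self.entries["feature"].tolist()

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def rank_features_ttest(
    matrix: DescriptorMatrix, labels: list[str] | np.ndarray, equal_var: bool = False
) -> FeatureRanking:
    """Rank features by a per-feature two-sample t test between classes.

    Features with an undefined statistic (zero variance in both groups)
    receive the worst ranks. Raises if either class has fewer than 2 rows.
    """
    labels = np.asarray(labels)
    mask_a = labels == ANTI
    mask_b = labels == NON_ANTI
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(
            f"both classes need >= 2 rows (got {int(mask_a.sum())} {ANTI}, "
            f"{int(mask_b.sum())} {NON_ANTI})"
        )
    a = matrix.values[mask_a]
    b = matrix.values[mask_b]
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance columns
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)

    df = pd.DataFrame({"feature": matrix.feature_names, "t": t, "p": p})
    # undefined t (both groups constant with equal means, 0/0) -> worst
    # rank; infinite t (zero variance, different means) is a perfect
    # separator with p = 0 and keeps its top rank
    undefined = np.isnan(t)
    df.loc[undefined, "p"] = np.inf
    df.loc[undefined, "t"] = 0.0
    df["abs_t"] = df["t"].abs()
    df = df.sort_values(
        ["p", "abs_t", "feature"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["p"] = df["p"].replace(np.inf, np.nan)
    return FeatureRanking(entries=df[["feature", "t", "p", "rank"]])


def select_top_k(
    ranking: FeatureRanking, matrix: DescriptorMatrix, k: int
) -> DescriptorMatrix:
    """Restrict the matrix to the k best-ranked features, in rank order."""
    p = matrix.p
    if not 1 <= k <= p:
        raise ValueError(f"k={k} outside [1, {p}]")
    top = ranking.ordered_features[:k]
    missing = set(top) - set(matrix.feature_names)
    if missing:
        raise ValueError(f"ranking refers to features absent from matrix: {sorted(missing)}")
    return matrix.subset_columns(top)
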