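"""Elastic-net coefficient importance aggregated across CV fold models.

Each outer fold of the nested CV fits one elastic-net logistic model; a
feature's importance is the sum of its coefficients over all (repeat,
fold) models (mean available behind a flag). Under the package's class
encoding (ANTI positive), a POSITIVE beta sum pushes the score toward the
anti-angiogenic class, so ``anti_associated`` is True for positive sums;
the encoding is recorded in the table so the direction is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .io import ANTI

CLASS_ENCODING = f"positive class = {ANTI}; positive beta -> anti-angiogenic-associated"


@dataclass
class ImportanceTable:
    """Per-feature aggregated betas with provenance and sign interpretation.

    ``entries`` columns: feature, source (descriptor prefix), beta_sum,
    beta_mean, selection_frequency (fraction of fold models with a nonzero
    beta), anti_associated.
    """

    entries: pd.DataFrame
    n_fold_models: int
    class_encoding: str = CLASS_ENCODING

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def aggregate_betas(coefficients: pd.DataFrame) -> ImportanceTable:
    """Group the long (repeat, fold, feature, beta) table per feature.

    A fold model that did not include a feature contributes beta = 0 to
    that feature's sum and does not count toward its selection frequency.
    Duplicate (repeat, fold, feature) rows are an input error.
    """
    required = {"repeat", "fold", "feature", "beta"}
    if coefficients.empty or required - set(coefficients.columns):
        raise ValueError(f"coefficient table must be nonempty with columns {sorted(required)}")
    dup = coefficients.duplicated(subset=["repeat", "fold", "feature"])
    if dup.any():
        raise ValueError(
            f"duplicate (repeat, fold, feature) rows: "
            f"{coefficients.loc[dup, ['repeat', 'fold', 'feature']].to_dict('records')[:3]}"
        )
    n_models = coefficients[["repeat", "fold"]].drop_duplicates().shape[0]
    grouped = coefficients.groupby("feature")["beta"]
    entries = pd.DataFrame(
        {
            "beta_sum": grouped.sum(),
            "selection_frequency": grouped.apply(lambda b: float(np.sum(b != 0)) / n_models),
        }
    ).reset_index()
    entries["beta_mean"] = entries["beta_sum"] / n_models
    entries["source"] = entries["feature"].str.split(":").str[0]
    entries["anti_associated"] = entries["beta_sum"] > 0
    entries = entries[
        ["feature", "source", "beta_sum", "beta_mean", "selection_frequency", "anti_associated"]
    ]
    return ImportanceTable(entries=entries, n_fold_models=n_models)


def top_k_report(table: ImportanceTable, k: int, use_mean: bool = False) -> pd.DataFrame:
    """Top-k features by |beta_sum| (or |beta_mean|), descending.

    Features never selected by any fold model (all-zero betas) are excluded
    before ranking; ties break by feature name for a total deterministic
    order.
    """
    metric = "beta_mean" if use_mean else "beta_sum"
    df = table.entries.copy()
    nonzero = df[df["selection_frequency"] > 0]
    pool = nonzero if len(nonzero) else df
    if k > len(table.entries):
        raise ValueError(f"k={k} exceeds feature count {len(table.entries)}")
    pool = pool.assign(_mag=pool[metric].abs())
    pool = pool.sort_values(["_mag", "feature"], ascending=[False, True], kind="mergesort")
    return pool.drop(columns="_mag").head(k).reset_index(drop=True)


def descriptor_composition(
    before: DescriptorMatrix, after_selection: DescriptorMatrix
) -> pd.DataFrame:
    """Per-descriptor feature shares before/after selection.

    Returns one row per source descriptor with the percentage of features
    it contributes before and after selection (each column sums to 100)
    and the proportion of its features discarded by the selection.
    """
    before_set = set(before.feature_names)
    extra = set(after_selection.feature_names) - before_set
    if extra:
        raise ValueError(f"selected features absent from the pre-selection matrix: {sorted(extra)}")

    def counts(names: list[str]) -> pd.Series:
        return pd.Series([n.split(":", 1)[0] for n in names]).value_counts()

    cb = counts(before.feature_names)
    ca = counts(after_selection.feature_names).reindex(cb.index, fill_value=0)
    out = pd.DataFrame(
        {
            "source": cb.index,
            "n_before": cb.values,
            "n_after": ca.values,
        }
    )
    out["share_before_pct"] = 100.0 * out["n_before"] / out["n_before"].sum()
    out["share_after_pct"] = 100.0 * out["n_after"] / out["n_after"].sum()
    out["discarded_proportion"] = 1.0 - out["n_after"] / out["n_before"]
    return out.reset_index(drop=True)
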