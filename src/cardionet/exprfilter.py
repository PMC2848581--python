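"""Expression quality filtering, reference normalization and the volcano
differential filter for a single microarray platform.

The model of one platform is a replicated two-group design: a progenitor
condition measured against a designated reference condition (e.g. the
pluripotent starting population), three biological replicates each.
Genes carry per-sample presence calls -- Present (P), Marginal (M) or
Absent (A) -- produced upstream by the array-processing software; they
are taken as input here, never recomputed.

The stage contract is

1. :func:`flag_filter` -- keep a gene if it is called P or M in at least
   ``min_called`` replicates of at least one condition (reference counts
   as a condition),
2. :func:`normalize_to_reference` -- per-sample linear ratios against the
   per-gene median of the reference samples,
3. :func:`differential_test` -- fold change (mean of per-sample ratios)
   plus a two-sample t-test on log2 values,
4. :func:`volcano_filter` -- joint fold / p-value threshold producing a
   :class:`Signature` of up- and down-regulated gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

VALID_FLAGS = frozenset({"P", "M", "A"})
CALLED_FLAGS = frozenset({"P", "M"})


@dataclass
class ExpressionDataset:
    """Replicated linear-scale expression values with presence calls.

    Parameters
    ----------
    platform
        Free-text platform label (propagated into the Signature).
    values
        genes x samples DataFrame of strictly positive linear-scale
        intensities.
    flags
        genes x samples DataFrame of presence calls in ``{"P","M","A"}``,
        index/columns aligned with ``values``.
    conditions
        sample -> condition label mapping covering every column.
    reference
        The condition all others are normalized against.
    """

    platform: str
    values: pd.DataFrame
    flags: pd.DataFrame
    conditions: Mapping[str, str]
    reference: str

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.flags.index) or not self.values.columns.equals(
            self.flags.columns
        ):
            raise DataError("values and flags must share index and columns")
        missing = [s for s in self.values.columns if s not in self.conditions]
        if missing:
            raise DataError(f"samples without a condition label: {missing}")
        if self.reference not in set(self.conditions.values()):
            raise DataError(f"reference condition {self.reference!r} has no samples")
        bad_flags = set(np.unique(self.flags.to_numpy())) - VALID_FLAGS
        if bad_flags:
            raise DataError(f"invalid flag values {sorted(bad_flags)}; expected P/M/A")
        vals = self.values.to_numpy()
        if not np.all(vals > 0):
            bad = self.values.index[(vals <= 0).any(axis=1)]
            raise DataError(f"non-positive expression values for genes {list(bad[:5])}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]

    @property
    def condition_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.conditions[s]
            if c not in seen:
                seen.append(c)
        return seen

    def subset(self, genes: pd.Index) -> "ExpressionDataset":
        return ExpressionDataset(
            platform=self.platform,
            values=self.values.loc[genes],
            flags=self.flags.loc[genes],
            conditions=dict(self.conditions),
            reference=self.reference,
        )


@dataclass
class Signature:
    """Differential result of one platform: disjoint up/down gene sets."""

    platform: str
    up: frozenset[str]
    down: frozenset[str]
    universe: frozenset[str] = frozenset()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.up = frozenset(self.up)
        self.down = frozenset(self.down)
        self.universe = frozenset(self.universe)
        if self.up & self.down:
            raise DataError("up and down sets overlap")


def flag_filter(dataset: ExpressionDataset, min_called: int = 2) -> ExpressionDataset:
    """Retain genes called Present or Marginal in >= ``min_called``
    replicates within at least one condition.

    The reference condition participates like any other, so a gene absent
    in the progenitor state but expressed at the reference stage survives
    (it may be a down-regulated gene). Gene order is preserved and the
    operation is idempotent.
    """
    per_condition_n = [len(dataset.samples_of(c)) for c in dataset.condition_names]
    if min_called > min(per_condition_n):
        raise ConfigError(
            f"min_called={min_called} exceeds the replicate count "
            f"(smallest condition has {min(per_condition_n)} samples)"
        )
    called = dataset.flags.isin(CALLED_FLAGS)
    keep = pd.Series(False, index=dataset.genes)
    for cond in dataset.condition_names:
        cols = dataset.samples_of(cond)
        keep |= called[cols].sum(axis=1) >= min_called
    return dataset.subset(dataset.genes[keep])


def normalize_to_reference(dataset: ExpressionDataset) -> pd.DataFrame:
    """Per-sample linear ratios against the per-gene reference median.

    Returns a genes x samples DataFrame; the median of the reference-sample
    ratios is exactly 1 for every gene.
    """
    ref_cols = dataset.samples_of(dataset.reference)
    if not ref_cols:
        raise DataError(f"no samples for reference condition {dataset.reference!r}")
    ref_median = dataset.values[ref_cols].median(axis=1)
    bad = ref_median[ref_median <= 0]
    if len(bad):
        raise DataError(f"non-positive reference median for genes {list(bad.index[:5])}")
    return dataset.values.div(ref_median, axis=0)


def differential_test(
    ratios: pd.DataFrame,
    dataset: ExpressionDataset,
    condition: str | None = None,
    test: str = "welch",
    fold_method: str = "mean_ratio",
) -> pd.DataFrame:
    """Per-gene fold change and two-sided t-test p-value.

    Fold change is the mean of the per-sample condition ratios
    (``fold_method="mean_ratio"``, the default) or the ratio of group
    means (``"ratio_of_means"``). The p-value comes from a two-sample
    t-test on log2 values -- Welch by default, Student pooled-variance
    with ``test="student"``. A degenerate gene with zero variance in both
    groups gets p = 1 when the group means are equal and p = 0 otherwise.

    Returns a DataFrame indexed by gene with columns ``ratio`` (linear
    condition/reference, >= 0), ``fold`` (magnitude: reciprocal for
    ratios below 1), ``direction`` (up/down/unchanged) and ``p``.
    """
    if condition is None:
        non_ref = [c for c in dataset.condition_names if c != dataset.reference]
        if len(non_ref) != 1:
            raise ConfigError(
                f"condition must be given explicitly when the dataset has "
                f"{len(non_ref)} non-reference conditions"
            )
        condition = non_ref[0]
    if test not in ("welch", "student"):
        raise ConfigError(f"unknown test {test!r}; expected 'welch' or 'student'")
    if fold_method not in ("mean_ratio", "ratio_of_means"):
        raise ConfigError(f"unknown fold_method {fold_method!r}")

    cond_cols = dataset.samples_of(condition)
    ref_cols = dataset.samples_of(dataset.reference)
    if len(cond_cols) < 2 or len(ref_cols) < 2:
        raise DataError("differential test needs >= 2 samples per group")

    cond = ratios[cond_cols].to_numpy()
    ref = ratios[ref_cols].to_numpy()
    if fold_method == "mean_ratio":
        ratio = cond.mean(axis=1)
    else:
        ratio = cond.mean(axis=1) / ref.mean(axis=1)

    log_cond = np.log2(cond)
    log_ref = np.log2(ref)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(log_cond, log_ref, axis=1, equal_var=(test == "student"))
    # zero variance in both groups: p=1 on equal means, p=0 otherwise
    nan = ~np.isfinite(p)
    if nan.any():
        equal = np.isclose(log_cond.mean(axis=1), log_ref.mean(axis=1))
        p = np.where(nan, np.where(equal, 1.0, 0.0), p)

    with np.errstate(divide="ignore"):
        inv = np.divide(1.0, ratio, out=np.zeros_like(ratio), where=ratio > 0)
        fold = np.where(ratio >= 1.0, ratio, inv)
    direction = np.where(ratio > 1.0, "up", np.where(ratio < 1.0, "down", "unchanged"))
    return pd.DataFrame(
        {"ratio": ratio, "fold": fold, "direction": direction, "p": p},
        index=ratios.index,
    )


def volcano_filter(
    table: pd.DataFrame,
    platform: str = "",
    min_fold: float = 1.2,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> Signature:
    """Joint fold / significance filter selecting differential genes.

    A gene is up-regulated when its fold magnitude is >= ``min_fold``
    (inclusive, honoring the ">= 20% change" reading of the 1.2-fold
    cut), its ratio exceeds 1, and p < ``alpha`` (strict); down is
    symmetric. ``adjust="bh"`` applies Benjamini-Hochberg before
    thresholding; the default filters raw p-values.
    """
    if min_fold <= 0 or alpha <= 0:
        raise ConfigError("min_fold and alpha must be positive")
    p = table["p"].to_numpy(dtype=float)
    if adjust == "bh":
        p = _benjamini_hochberg(p)
    elif adjust is not None:
        raise ConfigError(f"unknown adjustment {adjust!r}; expected 'bh' or None")
    passing = (table["fold"].to_numpy() >= min_fold) & (p < alpha)
    ratio = table["ratio"].to_numpy()
    up = table.index[passing & (ratio > 1.0)]
    down = table.index[passing & (ratio < 1.0)]
    return Signature(
        platform=platform,
        up=frozenset(up),
        down=frozenset(down),
        universe=frozenset(table.index),
        provenance={"min_fold": min_fold, "alpha": alpha, "adjust": adjust},
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
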