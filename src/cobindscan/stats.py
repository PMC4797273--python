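"""Per-feature statistical contrasts between co-occupied and solo events.

Each feature column is compared between the positive (co-occupied) and
negative (solo) classes with a two-sample t-test. The default is Welch's
unequal-variance form, since group sizes and variances of the two event
classes typically differ substantially; the pooled-variance Student form is
available via ``equal_variance=True``. Raw p-values are reported (that is
how enrichment thresholds are conventionally quoted for these contrasts);
a Benjamini-Hochberg adjusted column is emitted alongside for convenience.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import ValidationError
from .features import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class ContrastResult:
    feature_name: str
    n_pos: int
    n_neg: int
    mean_pos: float
    mean_neg: float
    t_statistic: float
    p_value: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.mean_pos - self.mean_neg))


def t_test(x, y, equal_variance: bool = False) -> tuple[float, float]:
    """Two-sample t statistic and two-sided p-value (Welch by default).

    Degenerate zero-variance inputs follow the convention: equal means ->
    (t=0, p=1); unequal means with zero variance -> (signed inf, p=0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("t_test needs at least 2 observations per sample")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("t_test requires finite values")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return math.copysign(math.inf, np.mean(x) - np.mean(y)), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=equal_variance)
    return float(t), float(p)


def contrast_all(matrix: FeatureMatrix, equal_variance: bool = False) -> list[ContrastResult]:
    """One t-test per feature column, missing cells excluded pairwise.

    Columns where either class has no usable values are skipped with a
    warning. Raises when a class is entirely absent from the matrix.
    """
    pos_mask = matrix.labels == 1
    neg_mask = matrix.labels == 0
    if not pos_mask.any() or not neg_mask.any():
        raise ValidationError(
            "contrast requires both classes; got "
            f"{pos_mask.sum()} positive and {neg_mask.sum()} negative sites"
        )
    results = []
    for j, name in enumerate(matrix.feature_names):
        ok = ~matrix.missing_mask[:, j]
        x = matrix.values[pos_mask & ok, j]
        y = matrix.values[neg_mask & ok, j]
        if len(x) < 2 or len(y) < 2:
            logger.warning("feature %s skipped: fewer than 2 values in a class", name)
            continue
        t, p = t_test(x, y, equal_variance=equal_variance)
        results.append(
            ContrastResult(name, len(x), len(y), float(np.mean(x)), float(np.mean(y)), t, p)
        )
    return results


def contrasts_to_frame(results: list[ContrastResult]) -> pd.DataFrame:
    """Tabulate contrasts with a Benjamini-Hochberg adjusted p column."""
    df = pd.DataFrame(
        [
            (r.feature_name, r.n_pos, r.n_neg, r.mean_pos, r.mean_neg,
             r.t_statistic, r.p_value, r.direction)
            for r in results
        ],
        columns=["feature", "n_pos", "n_neg", "mean_pos", "mean_neg", "t", "p", "direction"],
    )
    if len(df):
        df["p_adj"] = sps.false_discovery_control(df["p"].clip(0, 1), method="bh")
    else:
        df["p_adj"] = []
    return df
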