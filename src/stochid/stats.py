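"""Within-subject comparison of a scalar outcome across conditions.

One-way repeated-measures ANOVA (sphericity assumed, no correction) with
Bonferroni-corrected paired t tests as post hoc — the standard design for
comparing total ID_obs (or velocity peaks) across objects within subjects.
The ANOVA is computed from its sums-of-squares decomposition:

    SS_total = SS_subjects + SS_conditions + SS_error
    F = MS_conditions / MS_error,  df = (k−1, (k−1)(n−1))
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError


@dataclass(frozen=True)
class ConditionMatrix:
    """Complete subjects x conditions table of one scalar outcome."""

    values: np.ndarray
    subjects: tuple[str, ...]
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if v.ndim != 2 or v.shape != (len(self.subjects), len(self.conditions)):
            raise ValidationError("values must be (n_subjects, n_conditions)")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValidationError("need >= 2 subjects and >= 2 conditions")
        if not np.isfinite(v).all():
            raise ValidationError("matrix has missing/non-finite cells (no imputation)")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConditionMatrix":
        """Wide CSV/DataFrame: rows = subjects (index or first column),
        columns = conditions."""
        if df.columns[0].lower() in ("subject", "subjects", "id"):
            df = df.set_index(df.columns[0])
        return cls(df.to_numpy(dtype=float),
                   tuple(str(i) for i in df.index),
                   tuple(str(c) for c in df.columns))


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def rm_anova(mat: ConditionMatrix) -> AnovaResult:
    """One-way repeated-measures ANOVA from sums of squares."""
    x = mat.values
    n, k = x.shape
    gm = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - gm) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - gm) ** 2)
    ss_total = np.sum((x - gm) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    tiny = 1e-12 * max(ss_total, 1.0)  # float-noise floor for exact-tie cases
    if ss_cond <= tiny:
        return AnovaResult(0.0, df1, df2, 1.0)  # identical condition means
    if ss_err <= tiny:
        return AnovaResult(float("inf"), df1, df2, 0.0)
    F = ms_cond / ms_err
    return AnovaResult(float(F), df1, df2, float(sps.f.sf(F, df1, df2)))


@dataclass(frozen=True)
class PairwiseResult:
    table: pd.DataFrame   # columns: a, b, t, p, significant, degenerate
    alpha: float
    critical_p: float


def bonferroni_pairs(mat: ConditionMatrix, alpha: float = 0.05) -> PairwiseResult:
    """All k(k−1)/2 two-sided paired t tests; significance at alpha/npairs.

    A pair whose difference vector has zero variance and nonzero mean has no
    defined t statistic: it is flagged ``degenerate`` with p = NaN.  Identical
    columns give t = 0, p = 1.
    """
    x = mat.values
    pairs = list(combinations(range(x.shape[1]), 2))
    critical = alpha / len(pairs)
    rows = []
    for i, j in pairs:
        d = x[:, i] - x[:, j]
        degenerate = False
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d, 0.0):
                t, p = 0.0, 1.0
            else:
                t, p, degenerate = float("nan"), float("nan"), True
        else:
            t, p = sps.ttest_rel(x[:, i], x[:, j])
        rows.append((mat.conditions[i], mat.conditions[j], float(t), float(p),
                     bool(p < critical) if np.isfinite(p) else False, degenerate))
    table = pd.DataFrame(rows, columns=["a", "b", "t", "p", "significant", "degenerate"])
    return PairwiseResult(table, alpha, critical)
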