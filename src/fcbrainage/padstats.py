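"""Predicted-age-difference (PAD) inference.

PAD = predicted brain age minus chronological age; positive values mean
an older-looking functional connectome.  Because brain-age models
overestimate young subjects and underestimate old ones, every group
contrast and correlation here is controlled for chronological age: group
comparisons are ordinary-least-squares GLMs of PAD on a group indicator
plus age (F test on the group term, optionally one-tailed), associations
with continuous measures (amyloid burden, estimated years to onset) are
partial Pearson correlations with age residualized out of both sides, and
a Mann-Whitney rank test is available as the nonparametric fallback for
small groups.  No multiple-testing adjustment is applied; contrasts are
reported individually.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PadTable",
    "GroupComparison",
    "compute_pad",
    "group_glm",
    "partial_correlation",
    "mann_whitney",
    "compute_eyo",
]


PAD_COLUMNS = [
    "subject_id",
    "chronological_age",
    "predicted_age",
    "pad",
    "group_label",
    "site",
    "amyloid_load",
    "amyloid_positive",
    "eyo",
]


@dataclass
class PadTable:
    """Per-subject PAD with group labels and optional covariates."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"subject_id", "chronological_age", "predicted_age", "pad"}
        missing = need - set(self.frame.columns)
        if missing:
            raise ValueError(f"PadTable missing column(s): {missing}")
        delta = self.frame["predicted_age"] - self.frame["chronological_age"]
        if not np.allclose(delta, self.frame["pad"], atol=1e-12, equal_nan=True):
            raise ValueError("pad must equal predicted_age - chronological_age")

    def to_tsv(self, path) -> None:
        cols = [c for c in PAD_COLUMNS if c in self.frame.columns]
        self.frame[cols].to_csv(path, sep="\t", index=False)


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    adjusted_mean_a: float
    adjusted_mean_b: float
    sided: str
    covariates: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "groups": [self.group_a, self.group_b],
            "n": [self.n_a, self.n_b],
            "F": self.f_statistic,
            "df": list(self.df),
            "p": self.p_value,
            "adjusted_means": [self.adjusted_mean_a, self.adjusted_mean_b],
            "sided": self.sided,
            "covariates": list(self.covariates),
        }


def compute_pad(predictions: pd.DataFrame) -> PadTable:
    """Build a PadTable from a predictions frame.

    Requires ``subject_id``, ``chronological_age`` and ``predicted_age``;
    all other columns (group, site, amyloid, eyo ...) pass through.
    """
    for col in ("subject_id", "chronological_age", "predicted_age"):
        if col not in predictions.columns:
            raise ValueError(f"predictions missing column {col}")
    if predictions[["chronological_age", "predicted_age"]].isna().any().any():
        raise ValueError("missing ages in predictions")
    frame = predictions.copy()
    frame["pad"] = frame["predicted_age"] - frame["chronological_age"]
    return PadTable(frame=frame)


def group_glm(
    pad_table: PadTable,
    group_a: str,
    group_b: str,
    covariates: tuple[str, ...] = ("chronological_age",),
    sided: str = "two",
    value_column: str = "pad",
    group_column: str = "group_label",
) -> GroupComparison:
    """Age-controlled OLS contrast of PAD between two groups.

    Fits ``value ~ 1 + group_indicator + covariates`` and F-tests the group
    term (df (1, n - p)).  ``sided='one'`` halves the p-value when group_b
    exceeds group_a after adjustment (the alternative is b > a) and reports
    ``1 - p/2`` otherwise.  Adjusted group means are evaluated at the
    sample means of the covariates.
    """
    df = pad_table.frame
    sub = df[df[group_column].isin([group_a, group_b])].copy()
    sub = sub.dropna(subset=[value_column, *covariates])
    n_a = int((sub[group_column] == group_a).sum())
    n_b = int((sub[group_column] == group_b).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    n = n_a + n_b
    p = 2 + len(covariates)
    if n < len(covariates) + 3:
        raise ValueError("too few subjects for the design")
    g = (sub[group_column] == group_b).to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(n), g] + [sub[c].to_numpy(dtype=float) for c in covariates]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design: group confounded with a covariate")
    y = sub[value_column].to_numpy(dtype=float)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se_g = math.sqrt(sigma2 * xtx_inv[1, 1])
    t = beta[1] / se_g
    f = t * t
    p_two = float(sps.f.sf(f, 1, dof))
    if sided == "one":
        p_val = p_two / 2.0 if beta[1] > 0 else 1.0 - p_two / 2.0
    elif sided == "two":
        p_val = p_two
    else:
        raise ValueError("sided must be 'one' or 'two'")
    cov_means = [sub[c].mean() for c in covariates]
    base = beta[0] + float(np.dot(beta[2:], cov_means))
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=n_a,
        n_b=n_b,
        f_statistic=float(f),
        df=(1, dof),
        p_value=p_val,
        adjusted_mean_a=float(base),
        adjusted_mean_b=float(base + beta[1]),
        sided=sided,
        covariates=tuple(covariates),
    )


def partial_correlation(
    pad_table: PadTable,
    x_column: str,
    covariate: str = "chronological_age",
    value_column: str = "pad",
) -> tuple[float, int, float]:
    """Partial Pearson correlation of PAD with x, controlling for age.

    Both variables are residualized on the covariate (with intercept); the
    Pearson correlation of the residuals is returned with df = n - 3 and a
    two-sided p-value from the t transform.
    """
    df = pad_table.frame.dropna(subset=[value_column, x_column, covariate])
    n = len(df)
    if n < 5:
        raise ValueError("need at least 5 complete cases")
    c = df[covariate].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), c])

    def _resid(v: np.ndarray) -> np.ndarray:
        beta, _, _, _ = np.linalg.lstsq(X, v, rcond=None)
        return v - X @ beta

    ry = _resid(df[value_column].to_numpy(dtype=float))
    rx = _resid(df[x_column].to_numpy(dtype=float))
    if ry.std() == 0 or rx.std() == 0:
        raise ValueError("zero residual variance")
    r = float(np.corrcoef(ry, rx)[0, 1])
    dof = n - 3
    t = r * math.sqrt(dof / max(1e-300, 1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return r, dof, p


_MAX_ENUM = 100_000


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: number of (a, b) pairs with a > b, ties count 1/2."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(
    values_a, values_b, sided: str = "two"
) -> tuple[float, float]:
    """Mann-Whitney U test with tie handling.

    The p-value is computed by exhaustive enumeration of group assignments
    when the number of distinct assignments is small enough (tie-exact);
    for no-tie samples with n_a * n_b <= 400 the exact U distribution is
    used; otherwise the tie-corrected normal approximation.  ``sided`` is
    "two" or "less" (alternative: a below b) or "greater".
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(a, b)
    n_a, n_b = a.size, b.size
    alt = {"two": "two-sided", "less": "less", "greater": "greater"}[sided]

    if math.comb(n_a + n_b, n_a) <= _MAX_ENUM:
        pooled = np.concatenate([a, b])
        idx = range(n_a + n_b)
        us = []
        for comb in itertools.combinations(idx, n_a):
            mask = np.zeros(n_a + n_b, dtype=bool)
            mask[list(comb)] = True
            us.append(_u_statistic(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        eps = 1e-9
        if alt == "less":
            p = float((us <= u + eps).mean())
        elif alt == "greater":
            p = float((us >= u - eps).mean())
        else:
            mu = n_a * n_b / 2.0
            dev = abs(u - mu)
            p = float((np.abs(us - mu) >= dev - eps).mean())
        return u, min(p, 1.0)

    has_ties = np.unique(np.concatenate([a, b])).size < n_a + n_b
    if not has_ties and n_a * n_b <= 400:
        res = sps.mannwhitneyu(a, b, alternative=alt, method="exact")
    else:
        res = sps.mannwhitneyu(a, b, alternative=alt, method="asymptotic")
    return u, float(res.pvalue)


def compute_eyo(chronological_age, parental_onset_age):
    """Estimated years to onset: chronological age minus parental onset age.

    Negative before the expected onset (a 50-year-old whose parent became
    symptomatic at 60 has EYO -10).  Missing parental onset yields NaN and
    the subject drops out of EYO analyses.
    """
    age = np.asarray(chronological_age, dtype=float)
    onset = np.asarray(parental_onset_age, dtype=float)
    return age - onset
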