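"""Two-predictor regression battery with Benjamini-Hochberg FDR.

Each criterion (a neuropsychological score or the ICV-normalized hippocampal
volume) is regressed on subject-average alpha relative power (x1) and alpha
peak frequency (x2) in a single step:

    y = b0 + b1 * x1 + b2 * x2 + e

Coefficient p-values from all criteria are pooled into one family (by
default both predictors together) and corrected with the BH step-up
procedure at rate q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateModelError, ParameterError, StructuralError

__all__ = ["RegressionResult", "subject_average", "bh_fdr", "fit_battery"]


@dataclass
class RegressionResult:
    criterion: str
    beta0: float
    beta1: float  # alpha relative power
    beta2: float  # alpha peak frequency
    se: tuple[float, float, float]
    p_values: tuple[float, float, float]
    fdr_significant: tuple[bool, bool]  # (beta1, beta2) at rate q


def subject_average(measure_matrix: np.ndarray,
                    subject_ids: list[str] | None = None) -> np.ndarray:
    """Average a subjects x sources matrix over non-missing sources per subject."""
    m = np.asarray(measure_matrix, dtype=float)
    if m.ndim != 2:
        raise StructuralError(f"expected a 2-D subjects x sources matrix, got {m.shape}")
    valid = ~np.isnan(m)
    bad = np.flatnonzero(~valid.any(axis=1))
    if bad.size:
        names = ([subject_ids[i] for i in bad] if subject_ids is not None
                 else bad.tolist())
        raise ParameterError(f"subjects with no non-missing sources: {names}")
    with np.errstate(invalid="ignore"):
        return np.nanmean(m, axis=1)


def bh_fdr(p_values, q: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up: flag the k smallest p with p(k) <= k q / m."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    passing = np.flatnonzero(p[order] <= thresh + 1e-15)
    flags = np.zeros(m, dtype=bool)
    if passing.size:
        k = passing[-1] + 1
        flags[order[:k]] = True
    return flags


def fit_battery(
    scores: pd.DataFrame,
    power: np.ndarray,
    peak: np.ndarray,
    criteria: list[str] | None = None,
    q: float = 0.1,
    family: str = "pooled",
    standardize: bool = False,
) -> list[RegressionResult]:
    """Fit the regression battery and apply BH FDR over the coefficient family.

    Parameters
    ----------
    scores
        One column per criterion, one row per subject.
    power, peak
        Per-subject predictor vectors (subject-average alpha relative power
        and alpha peak frequency).
    family
        "pooled" corrects all beta1 and beta2 p-values as one family
        (2 x n_criteria tests); "per-predictor" corrects each predictor's
        column separately.
    standardize
        Z-score the predictors before fitting (coefficients then per SD).
    """
    if criteria is None:
        criteria = list(scores.columns)
    x1 = np.asarray(power, dtype=float)
    x2 = np.asarray(peak, dtype=float)
    n = x1.size
    if x2.size != n or len(scores) != n:
        raise StructuralError("power, peak and scores must have matching length")
    if n <= 5:
        raise ParameterError(f"need n > 5 subjects, got {n}")
    if family not in ("pooled", "per-predictor"):
        raise ParameterError(f"unknown FDR family {family!r}")
    if standardize:
        x1 = (x1 - x1.mean()) / x1.std(ddof=1)
        x2 = (x2 - x2.mean()) / x2.std(ddof=1)
    design = np.column_stack([np.ones(n), x1, x2])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateModelError(
            "design is rank deficient: alpha power and peak frequency are collinear"
        )

    fits = []
    for crit in criteria:
        y = np.asarray(scores[crit], dtype=float)
        if np.any(np.isnan(y)):
            raise ParameterError(f"criterion {crit!r} has missing values")
        res = sm.OLS(y, design).fit()
        fits.append((crit, res))

    p1 = np.array([res.pvalues[1] for _, res in fits])
    p2 = np.array([res.pvalues[2] for _, res in fits])
    if family == "pooled":
        flags = bh_fdr(np.concatenate([p1, p2]), q=q)
        f1, f2 = flags[:len(fits)], flags[len(fits):]
    else:
        f1, f2 = bh_fdr(p1, q=q), bh_fdr(p2, q=q)

    out = []
    for i, (crit, res) in enumerate(fits):
        out.append(RegressionResult(
            criterion=crit,
            beta0=float(res.params[0]), beta1=float(res.params[1]),
            beta2=float(res.params[2]),
            se=tuple(float(s) for s in res.bse),
            p_values=tuple(float(p) for p in res.pvalues),
            fdr_significant=(bool(f1[i]), bool(f2[i])),
        ))
    return out


def battery_frame(results: list[RegressionResult]) -> pd.DataFrame:
    """Tabulate battery results in the conventional layout (one criterion per row)."""
    return pd.DataFrame([
        {
            "criterion": r.criterion,
            "beta_power": r.beta1,
            "beta_peak": r.beta2,
            "se_power": r.se[1],
            "se_peak": r.se[2],
            "p_power": r.p_values[1],
            "p_peak": r.p_values[2],
            "sig_power": r.fdr_significant[0],
            "sig_peak": r.fdr_significant[1],
        }
        for r in results
    ])
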