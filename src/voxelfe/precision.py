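"""Short-term precision statistics for repeat measurements.

The precision-error metric is the root-mean-square coefficient of
variation over participants,

    CV%_RMS = sqrt( (1/m) * sum_j [ 100 * SD_j / xbar_j ]^2 ),

where for a baseline/follow-up pair the two-point sample SD is
``|x1 - x2| / sqrt(2)`` and ``xbar_j`` their mean.  Per-participant CV%
samples are square-root transformed when their skewness z-score (Fisher
g1 over the large-sample standard error sqrt(6/n)) exceeds 1.96; model
comparison is an omnibus repeated-measures test followed by all three
pairwise paired comparisons with Bonferroni multiplication; covariate
screens use Spearman rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationResult:
    r_s: float
    p_value: float
    covariate: str = ""
    n: int = 0


def cv_percent(x1: float, x2: float) -> float:
    """Two-point CV%: ``100 * (|x1 - x2| / sqrt(2)) / mean``."""
    mean = 0.5 * (x1 + x2)
    if not mean > 0:
        raise ValueError("mean of the measurement pair must be positive")
    sd = abs(x1 - x2) / np.sqrt(2.0)
    return 100.0 * sd / mean


def cv_rms(pairs: Iterable[tuple[float, float]]) -> float:
    """Root-mean-square of per-participant CV% over m >= 2 pairs."""
    cvs = np.array([cv_percent(x1, x2) for x1, x2 in pairs])
    if cvs.size < 2:
        raise ValueError("need at least two participants")
    return float(np.sqrt(np.mean(cvs ** 2)))


def skewness_z(values: Sequence[float]) -> float:
    """Skewness z-score: Fisher g1 / sqrt(6/n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3 or np.allclose(v, v[0]):
        return np.nan
    return float(stats.skew(v) / np.sqrt(6.0 / v.size))


def normalize_if_skewed(values: Sequence[float], z_crit: float = 1.96,
                        ) -> tuple[np.ndarray, bool]:
    """Square-root transform a CV% sample when |skewness z| > 1.96.

    Returns (possibly transformed sample, transformed flag).  Degenerate
    samples (constant, or too few values) are returned unchanged with a
    warning.
    """
    v = np.asarray(values, dtype=float)
    z = skewness_z(v)
    if np.isnan(z):
        warnings.warn("skewness z-score undefined for degenerate sample; "
                      "no transform applied")
        return v, False
    if abs(z) > z_crit:
        if (v < 0).any():
            raise ValueError("cannot square-root transform negative values")
        return np.sqrt(v), True
    return v, False


def _paired_p(a: np.ndarray, b: np.ndarray, parametric: bool) -> float:
    d = a - b
    if np.allclose(d, 0.0):
        return 1.0
    if parametric:
        return float(stats.ttest_rel(a, b).pvalue)
    return float(stats.wilcoxon(a, b, zero_method="zsplit").pvalue)


def compare_models(cv_tables: dict[str, Sequence[float]], *,
                   parametric: bool = False,
                   transform: bool = True) -> pd.DataFrame:
    """Compare per-participant CV% of one outcome across model variants.

    Omnibus: Friedman test (nonparametric repeated measures; configurable
    to repeated-measures ANOVA via ``parametric``), then all pairwise
    paired comparisons (Wilcoxon signed-rank by default, paired t-test if
    ``parametric``) with Bonferroni multiplication by the number of pairs,
    capped at 1.  All models must cover the same participants in the same
    order.
    """
    names = list(cv_tables)
    arrays = [np.asarray(cv_tables[n], dtype=float) for n in names]
    if len({a.size for a in arrays}) != 1:
        raise ValueError("unequal participant sets across models")
    if transform:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            arrays = [normalize_if_skewed(a)[0] for a in arrays]

    if all(np.allclose(a, arrays[0]) for a in arrays[1:]):
        omnibus_p = 1.0
    elif parametric:
        # Delegated omnibus: repeated-measures ANOVA from statsmodels.
        from statsmodels.stats.anova import AnovaRM
        m = arrays[0].size
        long = pd.DataFrame({
            "subject": np.tile(np.arange(m), len(names)),
            "model": np.repeat(names, m),
            "cv": np.concatenate(arrays),
        })
        fit = AnovaRM(long, depvar="cv", subject="subject",
                      within=["model"]).fit()
        omnibus_p = float(fit.anova_table["Pr > F"].iloc[0])
    else:
        omnibus_p = float(stats.friedmanchisquare(*arrays).pvalue)

    pairs = list(combinations(range(len(names)), 2))
    rows = []
    for i, j in pairs:
        raw = _paired_p(arrays[i], arrays[j], parametric)
        rows.append({"model_a": names[i], "model_b": names[j],
                     "p_raw": raw,
                     "p_adjusted": min(1.0, len(pairs) * raw),
                     "omnibus_p": omnibus_p})
    return pd.DataFrame(rows)


def spearman_screen(cv: Sequence[float], covariate: Sequence[float],
                    name: str = "") -> CorrelationResult:
    """Spearman rank correlation (average ranks on ties) between
    per-participant precision errors and a scan covariate."""
    cv = np.asarray(cv, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if cv.size != cov.size or cv.size < 3:
        raise ValueError("need matched samples of length >= 3")
    res = stats.spearmanr(cv, cov)
    return CorrelationResult(r_s=float(res.statistic),
                             p_value=float(res.pvalue),
                             covariate=name, n=cv.size)


def precision_table(outcomes: pd.DataFrame,
                    value_col: str = "value") -> pd.DataFrame:
    """Per model x outcome precision from a long-format outcomes table.

    Expects columns ``participant_id, model, outcome, scan, value`` with
    ``scan`` in {1, 2}.  Returns one row per participant x model x outcome
    with the pair of values and the per-participant CV%, plus the
    aggregated CV%_RMS repeated per group for convenience.
    """
    required = {"participant_id", "model", "outcome", "scan", value_col}
    if not required <= set(outcomes.columns):
        raise ValueError(f"outcomes table must have columns {sorted(required)}")
    wide = outcomes.pivot_table(index=["model", "outcome", "participant_id"],
                                columns="scan", values=value_col).reset_index()
    wide = wide.rename(columns={1: "x1", 2: "x2"})
    wide["cv_pct"] = [cv_percent(a, b) for a, b in zip(wide.x1, wide.x2)]
    rms = wide.groupby(["model", "outcome"])["cv_pct"].apply(
        lambda c: float(np.sqrt(np.mean(np.square(c)))))
    wide = wide.merge(rms.rename("cv_rms_pct"), on=["model", "outcome"])
    return wide
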