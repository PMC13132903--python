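"""Genotype-level aggregation and cross-assay correlation.

The unit of the multidimensionality analysis is the line mean: each DGRP
genotype's trait value averaged over replicate trials, with a percentile
bootstrap for the 95% CI.  Traits are z-scored before regression, so the OLS
slope between two line-mean vectors equals their Pearson correlation and the
reported R-squared equals the slope squared.  Replicate-level noise
attenuates the observed between-line correlation below the latent one by the
factor sigma_L^2 / (sigma_L^2 + sigma_e^2 / n); the cross-assay matrix
reports raw and Benjamini-Hochberg adjusted p-values for every trait pair.

Line-effect inference with GLMM families is deliberately out of scope here:
this module stops at line means + bootstrap CIs + OLS correlation and exports
the tidy replicate table for external model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    slope_se: float
    F_stat: float
    p_value: float
    r_squared: float
    n_lines: int


def zscore(values) -> np.ndarray:
    """Mean-center and scale to unit sample variance (denominator n-1)."""
    v = np.asarray(values, dtype=float)
    if len(np.unique(v)) < 2:
        raise ValidationError("z-scoring needs at least two distinct values")
    return (v - v.mean()) / v.std(ddof=1)


def line_means(
    panel: pd.DataFrame,
    trait: str,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-line trait mean with a 95% percentile-bootstrap CI.

    ``panel`` is tidy: columns line_id, trait, value, one row per replicate.
    Resampling is within line; lines with a single replicate get a degenerate
    CI equal to the point.  Deterministic given ``seed``.
    """
    if trait not in set(panel["trait"]):
        raise ValidationError(f"unknown trait {trait!r}")
    sub = panel[panel["trait"] == trait]
    rng = np.random.default_rng(seed)
    rows = []
    for line_id in sorted(sub["line_id"].unique()):
        vals = sub.loc[sub["line_id"] == line_id, "value"].to_numpy(dtype=float)
        mean = float(np.mean(vals))
        if len(vals) == 1:
            lo = hi = mean
        else:
            idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
            boot = vals[idx].mean(axis=1)
            lo, hi = np.percentile(boot, [2.5, 97.5])
        rows.append(
            {"line_id": line_id, "trait": trait, "mean": mean,
             "ci_low": float(lo), "ci_high": float(hi), "n": len(vals)}
        )
    return pd.DataFrame(rows)


def regress_line_means(x, y) -> RegressionResult:
    """OLS between two paired line-mean vectors, both z-scored first.

    Reported as slope, SE of the slope, F statistic (= t-squared), two-sided
    p-value from F(1, n-2), and R-squared.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must pair over the same lines")
    n = len(x)
    if n < 3:
        raise ValidationError(f"need at least 3 lines, got {n}")
    zx, zy = zscore(x), zscore(y)
    fit = stats.linregress(zx, zy)
    t = fit.slope / fit.stderr if fit.stderr > 0 else np.inf
    F = float(t * t)
    p = float(stats.f.sf(F, 1, n - 2))
    return RegressionResult(
        slope=float(fit.slope),
        slope_se=float(fit.stderr),
        F_stat=F,
        p_value=p,
        r_squared=float(fit.rvalue**2),
        n_lines=n,
    )


def cross_assay_matrix(panel: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Regressions between line means of every unordered trait pair.

    Lines missing either trait are dropped pairwise, with the n used
    reported per pair.  Raw p-values are supplemented with a
    Benjamini-Hochberg adjusted column across the matrix.
    """
    means = {
        t: panel[panel["trait"] == t].groupby("line_id")["value"].mean()
        for t in traits
    }
    rows = []
    for a, b in combinations(traits, 2):
        joined = pd.concat([means[a].rename("x"), means[b].rename("y")], axis=1).dropna()
        if len(joined) < 3:
            raise ValidationError(
                f"traits {a!r},{b!r}: only {len(joined)} lines complete in both"
            )
        res = regress_line_means(joined["x"], joined["y"])
        rows.append(
            {"trait_x": a, "trait_y": b, "slope": res.slope, "slope_se": res.slope_se,
             "F_stat": res.F_stat, "p_value": res.p_value,
             "r_squared": res.r_squared, "n_lines": res.n_lines}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def grand_means(panel: pd.DataFrame, trait: str) -> dict[str, float]:
    """Both readings of a trait's grand mean, explicitly labelled.

    ``of_line_means`` averages the per-line means (every genotype weighted
    equally); ``of_trials`` averages all replicates pooled.
    """
    sub = panel[panel["trait"] == trait]
    if sub.empty:
        raise ValidationError(f"unknown trait {trait!r}")
    return {
        "of_line_means": float(sub.groupby("line_id")["value"].mean().mean()),
        "of_trials": float(sub["value"].mean()),
    }
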