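"""Statistical stages of the analysis.

Covers the saturation test of the functional-richness vs species-richness
relationship (quadratic OLS), Spearman associations, non-parametric group
comparisons (Kruskal-Wallis omnibus plus pairwise rank tests with Bonferroni
correction and compact letter display), and the one-sided test that SES
values fall below zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "SaturationFit",
    "GroupComparison",
    "saturation_regression",
    "spearman_association",
    "group_comparison",
    "ses_sign_test",
]


@dataclass
class SaturationFit:
    """Quadratic OLS fit FD ~ SR + SR^2 and its saturation diagnosis.

    ``saturating`` is True when the quadratic coefficient is significant
    *and* the fitted curve is concave (negative quadratic coefficient), i.e.
    supplementary species contribute less and less functional richness.
    """

    intercept: float
    linear: float
    quadratic: float
    p_quadratic: float
    r_squared: float
    n: int
    alpha: float = 0.05

    @property
    def concave(self) -> bool:
        return self.quadratic < 0

    @property
    def significant_quadratic(self) -> bool:
        return self.p_quadratic < self.alpha

    @property
    def saturating(self) -> bool:
        return self.significant_quadratic and self.concave

    def predict(self, sr: np.ndarray) -> np.ndarray:
        sr = np.asarray(sr, dtype=float)
        return self.intercept + self.linear * sr + self.quadratic * sr**2


def saturation_regression(richness: Sequence[float], fd: Sequence[float], alpha: float = 0.05) -> SaturationFit:
    """Test for a saturating FD-richness relationship.

    Fits ordinary least squares ``FD = b0 + b1*SR + b2*SR^2`` and reports the
    two-sided t-test p-value of the quadratic term (equivalent to the partial
    F-test with one restriction).
    """
    sr = np.asarray(richness, dtype=float)
    y = np.asarray(fd, dtype=float)
    if sr.shape != y.shape or sr.ndim != 1:
        raise ValueError("richness and FD must be matching 1-d sequences")
    if len(sr) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(sr) == 0:
        raise ValueError("species richness is constant; design matrix singular")
    X = sm.add_constant(np.column_stack([sr, sr**2]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("singular design matrix (too few distinct richness values)")
    res = sm.OLS(y, X).fit()
    return SaturationFit(
        intercept=float(res.params[0]),
        linear=float(res.params[1]),
        quadratic=float(res.params[2]),
        p_quadratic=float(res.pvalues[2]),
        r_squared=float(res.rsquared),
        n=len(sr),
        alpha=alpha,
    )


def spearman_association(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need matching 1-d sequences with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class GroupComparison:
    """Kruskal-Wallis omnibus plus Bonferroni-corrected pairwise rank tests."""

    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group1, group2, p_raw, p_adjusted, significant
    letters: dict[str, str]
    alpha: float


def _letter_display(groups: list[str], different: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly
    different.  Insert-and-absorb construction over the difference relation."""
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in different:
        new_sets: list[set[str]] = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb subsets
        letter_sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if not any(s <= t for t in letter_sets):
                letter_sets.append(s)
    letter_sets.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        for g in groups:
            if g in s:
                out[g] += alphabet[i % len(alphabet)]
    return out


def group_comparison(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare a metric across >= 2 groups.

    Kruskal-Wallis omnibus test, then pairwise Wilcoxon rank-sum
    (Mann-Whitney) tests with Bonferroni adjustment, summarised as a compact
    letter display (groups sharing a letter are indistinguishable at
    ``alpha``).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    names = sorted(set(groups.tolist()))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = {g: values[groups == g] for g in names}
    for g, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    stat, omni_p = sps.kruskal(*[samples[g] for g in names])
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    rows = []
    different: set[tuple[str, str]] = set()
    for a, b in pairs:
        p_raw = float(sps.mannwhitneyu(samples[a], samples[b], alternative="two-sided").pvalue)
        p_adj = min(1.0, p_raw * m)
        sig = p_adj < alpha
        if sig:
            different.add((a, b))
        rows.append({"group1": a, "group2": b, "p_raw": p_raw, "p_adjusted": p_adj, "significant": sig})
    return GroupComparison(
        omnibus_statistic=float(stat),
        omnibus_p=float(omni_p),
        pairwise=pd.DataFrame(rows),
        letters=_letter_display(names, different),
        alpha=alpha,
    )


def ses_sign_test(ses_values: Sequence[float]) -> float:
    """One-sided Wilcoxon signed-rank p-value for SES < 0.

    Tests whether standardised effect sizes are shifted below zero, i.e.
    whether a directional extinction scenario erodes functional richness
    faster than random expectation across assemblages.
    """
    v = np.asarray(ses_values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 5:
        raise ValueError("need at least 5 non-missing SES values")
    if np.all(v == 0):
        raise ValueError("all SES values are zero; test undefined")
    return float(sps.wilcoxon(v, alternative="less").pvalue)
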