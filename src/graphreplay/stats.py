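"""Statistical primitives: permutation p-values, correlation, paired t,
one-way repeated-measures ANOVA and cluster-based permutation tests.

The closed-form tests use the classical formulas with tail probabilities from
scipy's t/F distributions; the permutation machinery (add-one p-value rule,
max-statistic thresholds, cluster mass test) is implemented here because the
exact variants used by the pipeline are not standard library calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "AnovaTable",
    "rm_anova_oneway",
    "pearson",
    "paired_t",
    "permutation_pvalue",
    "cluster_permutation",
]


@dataclass
class AnovaTable:
    """One-way within-subject ANOVA decomposition."""

    F: float
    df_effect: int
    df_error: int
    p: float
    level_means: np.ndarray
    ss_effect: float
    ss_error: float
    ss_subject: float


def rm_anova_oneway(table: np.ndarray) -> AnovaTable:
    """One-way repeated-measures ANOVA on a (participants x levels) table.

    Classical within-subject decomposition: the subject main effect is removed
    from the residual, F = MS_effect / MS_error with df = (k-1, (k-1)(n-1)).
    """
    table = np.asarray(table, float)
    if table.ndim != 2:
        raise ValueError("table must be participants x levels")
    n, k = table.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 levels")
    if np.isnan(table).any():
        raise ValueError("missing cells; drop incomplete participants first")
    grand = table.mean()
    col_means = table.mean(axis=0)
    row_means = table.mean(axis=1)
    ss_effect = n * np.sum((col_means - grand) ** 2)
    ss_subject = k * np.sum((row_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_error = ss_total - ss_effect - ss_subject
    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    ms_error = ss_error / df_error
    if ms_error <= 0:
        F = 0.0 if ss_effect == 0 else np.inf
    else:
        F = (ss_effect / df_effect) / ms_error
    p = float(sps.f.sf(F, df_effect, df_error)) if np.isfinite(F) else 0.0
    return AnovaTable(float(F), df_effect, df_error, p, col_means,
                      float(ss_effect), float(max(ss_error, 0.0)),
                      float(ss_subject))


def pearson(x, y):
    """Sample Pearson correlation with two-sided p from the t distribution
    (n-2 degrees of freedom)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    n = len(x)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return r, p


def paired_t(x, y):
    """Paired two-sided t-test; t = mean(d) / (sd(d)/sqrt(n)), d = x - y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        warnings.warn("zero-variance differences; t is infinite")
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return t, p


def permutation_pvalue(observed: float, null, sided: str = "two-sided") -> float:
    """Permutation p-value with the add-one rule (p is never 0).

    ``sided``: 'greater', 'less', or 'two-sided' (by absolute value).
    """
    null = np.asarray(null, float)
    if null.size < 1:
        raise ValueError("need at least one null sample")
    if sided == "greater":
        hits = np.sum(null >= observed)
    elif sided == "less":
        hits = np.sum(null <= observed)
    elif sided == "two-sided":
        hits = np.sum(np.abs(null) >= abs(observed))
    else:
        raise ValueError(f"unknown sidedness: {sided!r}")
    return float((1 + hits) / (null.size + 1))


def _max_cluster_mass(m: np.ndarray, thresh: np.ndarray, structure) -> float:
    supra = m > thresh
    if not supra.any():
        return 0.0
    lab, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return 0.0
    masses = ndimage.sum_labels(m, lab, index=np.arange(1, n + 1))
    return float(masses.max())


def cluster_permutation(stat_map: np.ndarray, null_maps, cluster_alpha: float = 0.05,
                        alpha: float = 0.05, n_perm: int | None = None,
                        rng: np.random.Generator | None = None):
    """Cluster-based permutation test on a 1-D or 2-D statistic map.

    ``null_maps`` is either an array (n_perm, *map shape) of exchangeable null
    maps or a callable ``f(rng) -> map`` invoked ``n_perm`` times.  The
    cluster-forming threshold is the pointwise (1 - cluster_alpha) quantile of
    the null at each position; supra-threshold samples are grouped into
    contiguous (1-D) or 4-connected (2-D) clusters scored by summed statistic,
    and cluster p-values come from the null distribution of the maximum
    cluster mass.  Returns ``(mask, cluster_pvalues)`` with ``mask`` marking
    clusters significant at ``alpha``.
    """
    stat_map = np.asarray(stat_map, float)
    if stat_map.ndim not in (1, 2):
        raise ValueError("map must be 1-D or 2-D")
    if callable(null_maps):
        if n_perm is None:
            raise ValueError("n_perm required with a null generator")
        rng = np.random.default_rng() if rng is None else rng
        null_maps = np.stack([null_maps(rng) for _ in range(n_perm)])
    else:
        null_maps = np.asarray(null_maps, float)
    if null_maps.shape[1:] != stat_map.shape:
        raise ValueError("null map shape mismatch")
    if null_maps.shape[0] < 100:
        warnings.warn("fewer than 100 permutations: cluster p-values unstable")
    thresh = np.quantile(null_maps, 1 - cluster_alpha, axis=0)
    structure = (np.ones(3) if stat_map.ndim == 1
                 else ndimage.generate_binary_structure(2, 1))  # 4-connectivity
    null_mass = np.array([_max_cluster_mass(m, thresh, structure)
                          for m in null_maps])
    supra = stat_map > thresh
    mask = np.zeros_like(stat_map, dtype=bool)
    pvals = []
    if supra.any():
        lab, n = ndimage.label(supra, structure=structure)
        for ci in range(1, n + 1):
            mass = float(ndimage.sum_labels(stat_map, lab, index=ci))
            p = permutation_pvalue(mass, null_mass, sided="greater")
            pvals.append(p)
            if p < alpha:
                mask |= lab == ci
    return mask, pvals
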