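"""Statistical battery: normality screen, group tests, feature relevance,
and method-agreement analysis.

* Kolmogorov-Smirnov normality screen (plain KS on z-scored data by default;
  a Lilliefors-corrected variant is available, since estimating mean/sd from
  the sample inflates plain-KS p-values).
* Mann-Whitney U (exact enumeration for small tie-free samples, tie-corrected
  normal approximation otherwise) comparing control vs MS per feature and
  OGTT stage.
* Point-biserial Pearson correlation of each feature with MS status, with
  the conventional |r| relevance bins [0, 0.20), [0.20, 0.50), [0.50, 0.75).
* PCA relevance filter: principal components of the z-scored feature table;
  a feature is retained when it loads at >= ``coefficient_threshold`` (in
  absolute value) on at least one retained component.
* Bland-Altman agreement between two sets of fiducial marks paired by
  nearest-within-tolerance, reporting mean difference and mean +/- 1.96 sd
  limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _ss
from sklearn.decomposition import PCA

from .features import FEATURE_NAMES

__all__ = [
    "ks_normality",
    "mann_whitney",
    "feature_screen",
    "pca_relevance",
    "bland_altman",
    "BlandAltmanResult",
]

#: |r| bin edges used when summarising feature relevance
R_BINS = ((0.0, 0.20), (0.20, 0.50), (0.50, 0.75), (0.75, 1.0 + 1e-12))


def ks_normality(sample: np.ndarray, lilliefors: bool = False) -> float:
    """Two-sided p-value for departure from normality.

    The sample is z-scored with its own mean/sd and compared to the standard
    normal.  ``lilliefors=True`` applies the small-sample correction for the
    estimated parameters (via statsmodels); the plain screen is the default.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations for the normality screen")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("constant sample: normality test undefined (sd = 0)")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        return float(_lf(x, dist="norm")[1])
    z = (x - x.mean()) / sd
    return float(_ss.kstest(z, "norm").pvalue)


def mann_whitney(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Uses exact enumeration of the U null distribution when the combined
    sample has at most 12 tie-free observations, and the tie-corrected
    normal approximation (with continuity correction) otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    return float(_ss.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def feature_screen(
    features: pd.DataFrame,
    group_col: str = "group",
    stage_col: str = "stage",
    positive: str = "ms",
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-feature, per-stage association screen against MS status.

    ``features`` is a cohort feature table (one row per subject-stage with
    ``f01..f30`` columns plus group/stage).  For each feature and stage the
    table reports the Mann-Whitney p (control vs MS), the point-biserial
    Pearson r with the 0/1 group indicator and its p, significance flags at
    ``alpha`` (raw p-values by default; ``holm=True`` adjusts within the full
    grid) and the |r| relevance bin.  Constant features yield NaN r with an
    ``r_defined=False`` flag rather than an error.
    """
    feat_cols = [c for c in FEATURE_NAMES if c in features.columns]
    if not feat_cols:
        raise ValueError("no feature columns (f01..f30) found in the table")
    rows = []
    for stage, sub in features.groupby(stage_col, sort=False):
        y = (sub[group_col] == positive).to_numpy().astype(float)
        if y.sum() < 2 or (1 - y).sum() < 2:
            raise ValueError(f"need >= 2 subjects per group in stage {stage!r}")
        for name in feat_cols:
            x = sub[name].to_numpy(dtype=float)
            mw_p = mann_whitney(x[y == 1], x[y == 0])
            if np.ptp(x) == 0.0 or not np.all(np.isfinite(x)):
                r, r_p, defined = np.nan, np.nan, False
            else:
                r, r_p = _ss.pearsonr(x, y)
                defined = True
            rows.append(
                {
                    "feature": name,
                    "stage": stage,
                    "mw_p": mw_p,
                    "pearson_r": r,
                    "pearson_p": r_p,
                    "r_defined": defined,
                    "r_bin": _r_bin(r),
                }
            )
    out = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests

        out["mw_p_adj"] = multipletests(out["mw_p"], method="holm")[1]
        ok = out["pearson_p"].notna()
        out["pearson_p_adj"] = np.nan
        out.loc[ok, "pearson_p_adj"] = multipletests(out.loc[ok, "pearson_p"], method="holm")[1]
        out["mw_significant"] = out["mw_p_adj"] < alpha
        out["pearson_significant"] = out["pearson_p_adj"] < alpha
    else:
        out["mw_significant"] = out["mw_p"] < alpha
        out["pearson_significant"] = out["pearson_p"] < alpha
    return out


def _r_bin(r: float) -> str:
    if not np.isfinite(r):
        return "undefined"
    for lo, hi in R_BINS:
        if lo <= abs(r) < hi:
            return f"[{lo:.2f}, {hi if hi <= 1 else 1.0:.2f})"
    return "undefined"


@dataclass
class PCARelevance:
    retained_features: list[str]
    loadings: np.ndarray  # (n_components, n_features), rows orthonormal
    explained_variance_ratio: np.ndarray
    n_components: int


def pca_relevance(
    features: pd.DataFrame,
    coefficient_threshold: float = 0.2,
    n_components: int | None = 13,
    cumulative_variance: float | None = None,
) -> PCARelevance:
    """PCA-based feature relevance on the z-scored feature table.

    Components are eigenvectors of the feature correlation structure, sorted
    by eigenvalue.  By default the top 13 components are retained; pass
    ``cumulative_variance`` (e.g. 0.95) to retain the smallest leading set
    reaching that explained-variance fraction instead.  A feature is relevant
    if some retained component loads on it with |coefficient| >=
    ``coefficient_threshold``.
    """
    feat_cols = [c for c in FEATURE_NAMES if c in features.columns]
    x = features[feat_cols].to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0.0] = 1.0  # constant features carry zero loading either way
    z = (x - x.mean(axis=0)) / sd
    pca = PCA(svd_solver="full")
    pca.fit(z)
    if cumulative_variance is not None:
        k = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), cumulative_variance) + 1)
    else:
        k = min(n_components or 13, pca.components_.shape[0])
    k = min(k, pca.components_.shape[0])
    load = pca.components_[:k]
    keep = np.any(np.abs(load) >= coefficient_threshold, axis=0)
    return PCARelevance(
        retained_features=[c for c, k_ in zip(feat_cols, keep) if k_],
        loadings=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_components=k,
    )


@dataclass
class BlandAltmanResult:
    """Agreement between two mark sequences (test - reference, in ms)."""

    mean_difference: float
    limits_of_agreement: tuple[float, float]
    differences: np.ndarray = field(repr=False)
    n_matched: int = 0
    n_reference_unmatched: int = 0
    n_test_unmatched: int = 0


def bland_altman(
    reference_marks: np.ndarray,
    test_marks: np.ndarray,
    sample_rate: float = 1000.0,
    matching_tolerance: float = 50.0,
) -> BlandAltmanResult:
    """Bland-Altman agreement between two fiducial mark lists.

    Marks (sample indices) are paired greedily by nearest neighbour within
    ``matching_tolerance`` ms; unmatched marks are counted as misses/false
    alarms and excluded from the differences.  Limits of agreement are
    mean(d) +/- 1.96 * sample sd(d).
    """
    ref = np.sort(np.asarray(reference_marks, dtype=float))
    tst = np.sort(np.asarray(test_marks, dtype=float))
    tol = matching_tolerance * sample_rate / 1000.0
    diffs = []
    used = np.zeros(len(tst), dtype=bool)
    j = 0
    for r in ref:
        while j < len(tst) - 1 and abs(tst[j + 1] - r) <= abs(tst[j] - r):
            j += 1
        if j < len(tst) and not used[j] and abs(tst[j] - r) <= tol:
            used[j] = True
            diffs.append((tst[j] - r) * 1000.0 / sample_rate)
    if not diffs:
        raise ValueError("no marks matched within tolerance; agreement undefined")
    d = np.asarray(diffs)
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    if np.ptp(d) == 0.0:
        sd = 0.0
    return BlandAltmanResult(
        mean_difference=mean,
        limits_of_agreement=(mean - 1.96 * sd, mean + 1.96 * sd),
        differences=d,
        n_matched=int(d.size),
        n_reference_unmatched=int(len(ref) - d.size),
        n_test_unmatched=int(len(tst) - used.sum()),
    )
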