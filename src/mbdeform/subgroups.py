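"""Molecular-subgroup association statistics (Experiment-1 style analyses).

Band features are pruned for collinearity, z-scored, and tested for
differences across the four consensus medulloblastoma subgroups (WNT, SHH,
Group 3, Group 4) with one-way ANOVA and Tukey-HSD post-hoc pairwise
comparisons. Categorical semantic tumor features (location, necrosis,
brainstem involvement, contrast uptake) are tested one-vs-all across five
groups (including transitional G3/G4) with Fisher's exact test (two-level
features) or Pearson's chi-square (more levels). Significant features can
be summarized by Ward hierarchical clustering of subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "CANONICAL_SUBGROUPS",
    "FIVE_GROUPS",
    "prune_correlated",
    "FeatureScaler",
    "anova_subgroups",
    "posthoc_pairwise",
    "semantic_association",
    "hierarchical_cluster",
    "run_subgroup_analysis",
]

CANONICAL_SUBGROUPS = ("WNT", "SHH", "G3", "G4")
FIVE_GROUPS = CANONICAL_SUBGROUPS + ("G3/G4",)


def prune_correlated(features: pd.DataFrame, threshold: float = 0.95) -> pd.DataFrame:
    """Greedy collinearity pruning in canonical column order.

    Columns are visited left to right; a column is dropped if its absolute
    Pearson correlation with any already-retained column exceeds the
    threshold. Constant columns are excluded (with a warning) before any
    correlation is computed. Deterministic for a fixed column order.
    """
    if features.shape[1] < 2:
        raise ValueError("need at least 2 feature columns to prune")
    X = features.astype(float)
    sds = X.std(ddof=0)
    constant = sds[sds == 0].index.tolist()
    if constant:
        warnings.warn(f"excluding constant column(s) {constant} from pruning", stacklevel=2)
        X = X.drop(columns=constant)
    corr = X.corr().abs().to_numpy()
    cols = list(X.columns)
    kept: list[int] = []
    for j in range(len(cols)):
        if all(corr[j, i] <= threshold for i in kept):
            kept.append(j)
    return X.iloc[:, kept]


@dataclass
class FeatureScaler:
    """Per-column z-scoring with stored training parameters.

    ``fit`` learns the mean and population SD on the training cohort;
    ``transform`` reuses them (e.g. on a held-out test set) rather than
    refitting.
    """

    means_: pd.Series | None = None
    sds_: pd.Series | None = None

    def fit(self, features: pd.DataFrame) -> "FeatureScaler":
        X = features.astype(float)
        sds = X.std(ddof=0)
        if (sds == 0).any():
            bad = sds[sds == 0].index.tolist()
            raise ValueError(f"zero-variance column(s) {bad}: prune before scaling")
        self.means_ = X.mean()
        self.sds_ = sds
        return self

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        if self.means_ is None:
            raise RuntimeError("scaler not fitted")
        X = features[self.means_.index].astype(float)
        return (X - self.means_) / self.sds_

    def fit_transform(self, features: pd.DataFrame) -> pd.DataFrame:
        return self.fit(features).transform(features)


def _groups_for_anova(
    feature: np.ndarray, labels: np.ndarray, min_size: int = 2
) -> dict[str, np.ndarray]:
    groups: dict[str, np.ndarray] = {}
    for g in CANONICAL_SUBGROUPS:
        vals = feature[labels == g]
        if 0 < len(vals) < min_size:
            warnings.warn(f"excluding subgroup {g} with {len(vals)} member(s)", stacklevel=3)
        elif len(vals) >= min_size:
            groups[g] = vals
    return groups


def anova_subgroups(feature, labels) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of a feature across the four subgroups.

    Only the canonical subgroups enter; groups with fewer than 2 members
    are excluded with a warning. Returns (F, p).
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    groups = _groups_for_anova(feature, labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 subgroups with >= 2 members")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=stats.ConstantInputWarning)
        f, p = stats.f_oneway(*groups.values())
    if np.isnan(f):  # zero within-group variance with unequal means
        return float("inf"), 0.0
    return float(f), float(p)


def posthoc_pairwise(feature, labels) -> pd.DataFrame:
    """Tukey HSD over all subgroup pairs; family-wise adjusted p per pair."""
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    groups = _groups_for_anova(feature, labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 subgroups with >= 2 members")
    names = list(groups)
    res = stats.tukey_hsd(*groups.values())
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(np.mean(groups[names[i]]) - np.mean(groups[names[j]])),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def semantic_association(values, labels, groups: tuple[str, ...] = FIVE_GROUPS) -> pd.DataFrame:
    """One-vs-all association of a categorical semantic feature per subgroup.

    For each group a (group vs rest) x levels contingency table is built;
    two-level features use Fisher's exact test, features with more levels
    Pearson's chi-square. Degenerate features (a single observed level)
    are skipped with an explicit status.
    """
    values = np.asarray(values)
    labels = np.asarray(labels)
    levels = np.unique(values)
    rows = []
    for g in groups:
        in_g = labels == g
        if not in_g.any() or in_g.all():
            raise ValueError(f"group {g} is empty (or is the whole cohort)")
        if len(levels) < 2:
            rows.append({"group": g, "test": "none", "p": np.nan, "status": "single-level"})
            continue
        table = np.array(
            [[(in_g & (values == lv)).sum() for lv in levels],
             [(~in_g & (values == lv)).sum() for lv in levels]]
        )
        if len(levels) == 2:
            _, p = stats.fisher_exact(table)
            test = "fisher"
        else:
            chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
            if (expected < 5).any():
                warnings.warn(
                    f"chi-square expected cell count < 5 for group {g}", stacklevel=2
                )
            test = "chi2"
        rows.append({"group": g, "test": test, "p": float(p), "status": "ok"})
    return pd.DataFrame(rows)


def hierarchical_cluster(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Ward/Euclidean agglomerative clustering of subjects on z-scored features.

    Returns (scipy linkage matrix, 2-cluster cut labels). A single subject
    yields a trivial empty linkage and the label array [1].
    """
    X = features.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need at least one feature column")
    if X.shape[0] < 2:
        return np.empty((0, 4)), np.ones(X.shape[0], dtype=int)
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    cut = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return Z, cut


def run_subgroup_analysis(
    features: pd.DataFrame,
    subgroups,
    alpha: float = 0.05,
    prune_threshold: float = 0.95,
) -> pd.DataFrame:
    """Prune -> z-score -> per-feature ANOVA (+ post-hoc where significant).

    Rows with non-canonical subgroup labels (transitional G3/G4, missing)
    are excluded from the four-group test. Returns a tidy table with one
    row per (feature, comparison): the omnibus ANOVA row has comparison
    'omnibus'; significant features additionally get one row per Tukey
    pair. No correction is applied across features (per-feature p-values
    are reported as-is; apply Benjamini-Hochberg downstream if desired).
    """
    labels = np.asarray(subgroups)
    keep = np.isin(labels, CANONICAL_SUBGROUPS)
    X = features.loc[keep]
    labels = labels[keep]
    pruned = prune_correlated(X, threshold=prune_threshold)
    z = FeatureScaler().fit_transform(pruned)
    rows = []
    for col in z.columns:
        f, p = anova_subgroups(z[col].to_numpy(), labels)
        rows.append(
            {"feature": col, "comparison": "omnibus", "statistic": f, "p": p, "p_adj": np.nan}
        )
        if p < alpha:
            ph = posthoc_pairwise(z[col].to_numpy(), labels)
            for _, r in ph.iterrows():
                rows.append(
                    {
                        "feature": col,
                        "comparison": f"{r.group_a} vs {r.group_b}",
                        "statistic": r.mean_diff,
                        "p": np.nan,
                        "p_adj": r.p_adj,
                    }
                )
    return pd.DataFrame(rows)
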