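"""PRS normalisation, hierarchical patient clustering and clinical
group comparisons with family-wise Bonferroni control."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .datatypes import validate_clinical_table, warn


def normalize_prs(scores: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Standardise each pathway column by the control mean and SD
    (sample SD, ddof=1).  Zero-variance pathways are dropped with a
    warning; an error is raised if nothing remains."""
    clinical = validate_clinical_table(clinical)
    status = clinical.set_index("sample_id")["status"].reindex(scores.index)
    controls = scores.loc[status == "control"]
    if controls.empty:
        raise ValueError("control group is empty")
    mean = controls.mean()
    sd = controls.std(ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all pathways have zero control variance")
    if (~keep).any():
        warn(f"dropping zero-variance pathways: {list(sd.index[~keep])}")
    return (scores.loc[:, keep] - mean[keep]) / sd[keep]


def cluster_patients(
    matrix: pd.DataFrame,
    k: int = 4,
    linkage_method: str = "ward",
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Agglomerative clustering of patients, cut at exactly k clusters.

    Deterministic given the input order (scipy's smallest-index merge tie
    break).  Cluster labels are 1..k ordered by descending cluster size
    (ties by first occurrence) for reproducible reporting.
    """
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in clustering input")
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} samples")
    if k == 1:
        labels = np.ones(n, dtype=int)
    else:
        Z = linkage(X, method=linkage_method, metric=metric)
        labels = fcluster(Z, t=k, criterion="maxclust")
    # relabel by descending size
    sizes = pd.Series(labels).value_counts()
    rank = {old: i + 1 for i, old in enumerate(sizes.index)}
    labels = np.array([rank[v] for v in labels], dtype=int)
    return pd.DataFrame(
        {
            "sample_id": matrix.index,
            "cluster": labels,
            "k": k,
            "linkage": linkage_method,
            "metric": metric,
        }
    )


def _is_categorical(values: pd.Series) -> bool:
    v = values.dropna()
    if v.dtype == bool or v.dtype == object:
        return True
    return v.nunique() <= 2


def _test_one(values: pd.Series, groups: pd.Series) -> tuple:
    """(test name, statistic, p) for one clinical variable across groups."""
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    level_groups = [sub["v"] for _, sub in df.groupby("g")]
    if any(len(g) == 0 for g in level_groups) or len(level_groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if df["v"].nunique() <= 1:
        return "constant", np.nan, 1.0
    if _is_categorical(df["v"]):
        table = pd.crosstab(df["g"], df["v"]).to_numpy()
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
        if (expected < 5).any() and table.shape == (2, 2):
            _, p = stats.fisher_exact(table)
            return "fisher_exact", np.nan, float(p)
        return "chi_square", float(chi2), float(p)
    vals = [g.to_numpy(dtype=float) for g in level_groups]
    if len(vals) == 2:
        stat, p = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
        return "mann_whitney_u", float(stat), float(p)
    stat, p = stats.kruskal(*vals)
    return "kruskal_wallis", float(stat), float(p)


def compare_groups_clinical(
    groups: pd.Series,
    clinical: pd.DataFrame,
    variables: list,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Test clinical variables across patient groups with Bonferroni control.

    Two groups with an ordinal/continuous variable use Mann-Whitney U,
    more than two Kruskal-Wallis; categorical variables use chi-square
    (Fisher exact for 2x2 tables with small expected cells).  The
    family-wise threshold is 0.05 / family size (default: the number of
    variables tested); constant variables report p = 1 with a note.
    """
    clinical = validate_clinical_table(clinical).set_index("sample_id")
    missing = [v for v in variables if v not in clinical.columns]
    if missing:
        raise ValueError(f"unknown clinical variables: {missing}")
    groups = groups.dropna()
    family = family_size or len(variables)
    threshold = 0.05 / family
    rows = []
    for var in variables:
        values = clinical[var].reindex(groups.index)
        test, stat, p = _test_one(values, groups)
        rows.append(
            {
                "variable": var,
                "test": test,
                "statistic": stat,
                "p_value": p,
                "bonferroni_threshold": threshold,
                "significant": p < threshold,
                "note": "constant variable" if test == "constant" else "",
            }
        )
    return pd.DataFrame(rows)


def prs_case_control_tests(scores: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-pathway case vs control PRS comparison (Mann-Whitney U), with
    the Bonferroni threshold over the pathway family."""
    clinical = validate_clinical_table(clinical)
    status = clinical.set_index("sample_id")["status"].reindex(scores.index)
    cases = scores.loc[status == "case"]
    ctrls = scores.loc[status == "control"]
    if cases.empty or ctrls.empty:
        raise ValueError("need both cases and controls")
    threshold = 0.05 / scores.shape[1]
    rows = []
    for pid in scores.columns:
        if scores[pid].nunique() <= 1:
            rows.append((pid, np.nan, 1.0, threshold, False))
            continue
        stat, p = stats.mannwhitneyu(
            cases[pid].to_numpy(), ctrls[pid].to_numpy(), alternative="two-sided"
        )
        rows.append((pid, float(stat), float(p), threshold, p < threshold))
    return pd.DataFrame(
        rows, columns=["pathway_id", "statistic", "p_value", "bonferroni_threshold", "significant"]
    )
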