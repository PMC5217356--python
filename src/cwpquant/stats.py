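"""Stage-effect statistics on the protein abundance matrix.

Operates on a proteins x lanes matrix of log10 abundances with explicit
missingness. Statistical testing follows the published analysis scheme:
within-stage missing values are imputed with the lane minimum, one-way
fixed-effects ANOVA flags proteins with a developmental-stage effect at a
raw p-value threshold, lanes are inspected by PCA, and the significant
proteins are hierarchically clustered with a fixed-height dendrogram cut
from which each cluster's preferential stage(s) are extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .io import PipelineConfig

__all__ = [
    "build_matrix",
    "impute_within_stage",
    "anova_stage_effect",
    "pca_lanes",
    "cluster_and_cut",
    "preferential_stages",
    "ClusterAssignment",
]


def build_matrix(protein_abundances: pd.DataFrame,
                 config: PipelineConfig) -> pd.DataFrame:
    """Pivot per-lane protein abundances into a log10 matrix.

    Columns are a (stage, replicate) MultiIndex ordered by the configured
    stage order; absent observations become NaN. Every configured lane gets
    a column even if no protein was quantified in it.
    """
    reps = sorted(protein_abundances["replicate"].unique()) \
        if len(protein_abundances) else []
    full_cols = pd.MultiIndex.from_product(
        [config.stages, reps], names=["stage", "replicate"])
    if protein_abundances.empty:
        return pd.DataFrame(index=pd.Index([], name="accession"),
                            columns=full_cols, dtype=float)
    wide = protein_abundances.pivot_table(
        index="accession", columns=["stage", "replicate"],
        values="abundance", aggfunc="sum")
    wide = wide.reindex(columns=full_cols)
    return np.log10(wide)


def stage_of_columns(matrix: pd.DataFrame) -> np.ndarray:
    return matrix.columns.get_level_values("stage").to_numpy()


def impute_within_stage(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace within-stage missing values by the lane minimum.

    A missing entry of protein *i* in lane *L* is replaced by the minimum
    over the values present in lane *L* (its column), but only when protein
    *i* is present in at least one other replicate of the same stage.
    Missing values spanning a whole stage are left missing — those proteins
    are analysed on the stages where they occur. A lane with no present
    value at all cannot donate a minimum; such entries stay missing.
    """
    out = matrix.copy()
    stages = stage_of_columns(matrix)
    col_min = matrix.min(axis=0, skipna=True)
    for stage in pd.unique(stages):
        cols = matrix.columns[stages == stage]
        block = matrix[cols]
        present_in_stage = block.notna().any(axis=1)
        for col in cols:
            if np.isnan(col_min[col]):
                continue  # empty lane: imputation impossible
            target = block[col].isna() & present_in_stage
            out.loc[target, col] = col_min[col]
    return out


def anova_stage_effect(matrix: pd.DataFrame,
                       p_threshold: float = 0.001) -> pd.DataFrame:
    """Per-protein one-way fixed-effects ANOVA across stage groups.

    Proteins present in only two stages are tested as a two-group ANOVA;
    proteins with fewer than two stages carrying data, or with fewer than
    two values in every stage, are reported untestable (``testable``
    False, NaN statistics). Returns a table (accession, n_stages_tested,
    F, p, significant, testable) with ``significant`` ⇔ p < p_threshold.

    The F statistic is computed vectorised over proteins (between-group
    over within-group mean squares, compared to the F distribution), which
    makes null-calibration runs over 1e5 proteins cheap.
    """
    values = matrix.to_numpy(float)
    stages = stage_of_columns(matrix)
    uniq = pd.unique(stages)
    present = ~np.isnan(values)

    # per-protein per-stage counts, sums, sums of squares
    n_g = np.stack([present[:, stages == s].sum(axis=1) for s in uniq], axis=1)
    sum_g = np.stack([np.nansum(values[:, stages == s], axis=1)
                      for s in uniq], axis=1)
    ss_g = np.stack([np.nansum(values[:, stages == s] ** 2, axis=1)
                     for s in uniq], axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        mean_g = sum_g / n_g
    k = (n_g > 0).sum(axis=1)                      # groups with data
    n_tot = n_g.sum(axis=1)
    grand = sum_g.sum(axis=1) / np.where(n_tot > 0, n_tot, 1)
    ss_between = np.nansum(n_g * (mean_g - grand[:, None]) ** 2, axis=1)
    ss_within = np.nansum(ss_g - n_g * mean_g ** 2, axis=1)
    ss_within = np.maximum(ss_within, 0.0)         # guard rounding
    df_between = k - 1
    df_within = n_tot - k

    testable = (k >= 2) & (df_within > 0)
    F = np.full(len(matrix), np.nan)
    p = np.full(len(matrix), np.nan)
    t = testable
    with np.errstate(divide="ignore", invalid="ignore"):
        msb = ss_between[t] / df_between[t]
        msw = ss_within[t] / df_within[t]
        F_t = np.where(msw > 0, msb / np.where(msw > 0, msw, 1.0), np.inf)
        F_t = np.where((msw == 0) & (msb == 0), 0.0, F_t)
    p_t = sps.f.sf(F_t, df_between[t], df_within[t])
    p_t = np.where(np.isinf(F_t), 0.0, p_t)
    F[t], p[t] = F_t, p_t

    return pd.DataFrame({
        "accession": matrix.index,
        "n_stages_tested": k,
        "F": F,
        "p": p,
        "significant": testable & (p < p_threshold),
        "testable": testable,
    }).set_index("accession")


def pca_lanes(matrix: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Centered PCA of the lanes (lanes as points, proteins as variables).

    Restricted to proteins present in every lane used. Returns one row per
    lane with component coordinates; variance fractions are attached as
    ``.attrs['explained_variance_ratio']``.
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA needs at least 3 lanes")
    complete = matrix.dropna(axis=0)
    if complete.empty:
        raise ValueError("no protein present in all lanes")
    n_components = min(n_components, *complete.T.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(complete.T.to_numpy())
    out = pd.DataFrame(coords, index=complete.columns,
                       columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    return out


@dataclass
class ClusterAssignment:
    """Flat clusters from a fixed-height dendrogram cut.

    ``labels`` maps accession -> cluster id (1-based, ordered by
    decreasing cluster size); ``merge_heights`` are the dendrogram's
    linkage heights; ``preferential`` (filled by
    :func:`preferential_stages`) maps cluster id -> stage tuple.
    """

    labels: pd.Series
    linkage: np.ndarray
    cut_height: float
    preferential: dict | None = None

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_frame(self) -> pd.DataFrame:
        df = self.labels.rename("cluster").reset_index()
        if self.preferential is not None:
            df["preferential_stages"] = df["cluster"].map(
                lambda c: ";".join(self.preferential[c]))
        return df


def _row_distance(values: np.ndarray, metric: str) -> np.ndarray:
    if metric == "correlation":
        # 1 - Pearson correlation of stage-replicate profiles
        return pdist(values, metric="correlation")
    if metric == "euclidean_std":
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        return pdist((values - mu) / sd, metric="euclidean")
    raise ValueError(f"unknown distance {metric!r}")


def cluster_and_cut(matrix: pd.DataFrame, cut_height: float = 1.1,
                    metric: str = "correlation",
                    method: str = "complete") -> ClusterAssignment:
    """Hierarchical clustering of protein rows, cut at a fixed height.

    Rows are clustered on the configured row-profile distance (default
    1 - Pearson correlation) with the configured linkage (default
    complete). Flat clusters are the connected groups below ``cut_height``
    in the dendrogram. Cluster ids are assigned by decreasing cluster size
    (ties broken by first row appearance). A cut above the dendrogram root
    yields a single cluster; a cut below every merge yields all singletons.
    """
    complete_rows = matrix.dropna(axis=0)
    if len(complete_rows) < 2:
        raise ValueError("need at least 2 proteins with complete profiles")
    values = complete_rows.to_numpy(float)
    dist = _row_distance(values, metric)
    Z = hierarchy.linkage(dist, method=method)
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=complete_rows.index, name="cluster")
    # relabel by decreasing size
    sizes = labels.value_counts()
    order = sorted(sizes.index,
                   key=lambda c: (-sizes[c], int(np.argmax(raw == c))))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = labels.map(remap)
    return ClusterAssignment(labels=labels, linkage=Z, cut_height=cut_height)


def preferential_stages(assignment: ClusterAssignment, matrix: pd.DataFrame,
                        margin: float = 0.1) -> dict[int, tuple[str, ...]]:
    """Extrapolate each cluster's preferential developmental stage(s).

    For each cluster, protein profiles are averaged into per-stage means;
    the preferential set contains every stage whose mean lies within
    ``margin`` x (maximum stage mean) of the maximum stage mean. A flat
    profile is preferential for all stages.
    """
    stages = stage_of_columns(matrix)
    uniq = list(pd.unique(stages))
    prefs: dict[int, tuple[str, ...]] = {}
    for cid in sorted(assignment.labels.unique()):
        accs = assignment.labels.index[assignment.labels == cid]
        block = matrix.loc[accs]
        means = np.array([np.nanmean(block.loc[:, stages == s].to_numpy())
                          for s in uniq])
        top = np.nanmax(means)
        cutoff = top - margin * abs(top)
        prefs[cid] = tuple(s for s, m in zip(uniq, means) if m >= cutoff)
    assignment.preferential = prefs
    return prefs
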