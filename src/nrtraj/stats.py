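"""Group comparisons, distribution summaries and unsupervised classification.

The feature table assembled from trajectory descriptors is compared across
groups with the Kruskal-Wallis test plus Dunn's post hoc pairwise test
(alpha = 0.05; Bonferroni-adjusted p reported alongside raw p, and Cliff's
delta alongside every p-value because with thousands of frames per group
even trivial shifts reach significance).  Classification is unsupervised:
PCA on autoscaled descriptors and a self-organizing map (see
:mod:`nrtraj.som`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA as _SkPCA
from statsmodels.distributions.empirical_distribution import ECDF

from .errors import AssemblyError, NrtrajError

ACTIVITY_CLASSES = ("agonist", "partial_agonist", "antagonist", "EDC", "inactive")

LABEL_COLUMNS = ["receptor", "ligand", "start_conformation", "activity_class"]


@dataclass
class FeatureTable:
    """System x descriptor matrix with per-row identity labels.

    ``data`` holds finite numeric descriptors (one row per system/start
    conformation); ``labels`` is index-aligned with columns receptor,
    ligand, start_conformation, activity_class.
    """

    data: pd.DataFrame
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.labels.index):
            raise NrtrajError("feature data and labels must share an index")
        if self.data.isna().any().any() or not np.isfinite(self.data.to_numpy()).all():
            raise NrtrajError("feature table contains missing/non-finite values")

    @property
    def n_systems(self) -> int:
        return len(self.data)


def assemble_features(descriptors: dict, labels: dict | None = None,
                      registry: list[str] | None = None) -> FeatureTable:
    """Build a :class:`FeatureTable` from per-system descriptor mappings.

    ``descriptors`` maps a system key to a {descriptor name: value} dict;
    ``labels`` maps the same keys to label dicts (receptor, ligand,
    start_conformation, activity_class).  The column registry defaults to
    the sorted union of descriptor names; any system missing a registry
    entry raises :class:`AssemblyError` listing every gap.
    """
    if not descriptors:
        raise AssemblyError("no systems to assemble")
    keys = list(descriptors)
    if registry is None:
        registry = sorted(set().union(*(d.keys() for d in descriptors.values())))
    gaps = [f"{key}: missing {sorted(set(registry) - set(d))}"
            for key, d in descriptors.items() if set(registry) - set(d)]
    if gaps:
        raise AssemblyError("incomplete descriptor sets -- " + "; ".join(gaps))
    data = pd.DataFrame([[float(descriptors[k][c]) for c in registry] for k in keys],
                        index=pd.RangeIndex(len(keys)), columns=registry)
    lab_rows = []
    for k in keys:
        lab = dict(labels.get(k, {})) if labels else {}
        lab_rows.append({c: lab.get(c, "") for c in LABEL_COLUMNS})
    return FeatureTable(data=data, labels=pd.DataFrame(lab_rows, index=data.index))


def autoscale(table: FeatureTable) -> FeatureTable:
    """Zero-mean, unit-SD columns (n-1 denominator); constant columns dropped.

    Idempotent: autoscaling an already autoscaled table is the identity.
    """
    data = table.data
    sd = data.std(ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index.tolist()
    if constant:
        warnings.warn(f"dropping constant column(s): {constant}", stacklevel=2)
        data = data.drop(columns=constant)
        sd = sd.drop(index=constant)
    scaled = (data - data.mean()) / sd
    return FeatureTable(data=scaled, labels=table.labels.copy())


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class StatTestResult:
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_i, group_j, z, p_raw, p_adjusted, cliffs_delta
    alpha: float = 0.05


def cliffs_delta(a, b) -> float:
    """Cliff's delta effect size: P(a > b) - P(a < b), in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    greater = (a[:, None] > b[None, :]).sum()
    less = (a[:, None] < b[None, :]).sum()
    return float((greater - less) / (len(a) * len(b)))


def kruskal_dunn(groups: list, alpha: float = 0.05) -> StatTestResult:
    """Kruskal-Wallis H (tie-corrected) plus Dunn's pairwise post hoc test.

    Dunn z uses mean ranks over the pooled sample with tie correction;
    adjusted p is Bonferroni.  Identical data across all groups gives
    H = 0, p = 1 and no flagged pairs.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_dunn needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    # Dunn: mean ranks on the pooled sample
    ranks = sps.rankdata(pooled)
    sizes = [len(a) for a in arrays]
    bounds = np.cumsum([0, *sizes])
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(arrays))]
    n = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    m = len(arrays) * (len(arrays) - 1) // 2
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        denom = np.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        p_raw = float(2 * sps.norm.sf(abs(z)))
        rows.append({"group_i": i, "group_j": j, "z": float(z), "p_raw": p_raw,
                     "p_adjusted": min(1.0, p_raw * m),
                     "cliffs_delta": cliffs_delta(arrays[i], arrays[j])})
    return StatTestResult(h_statistic=float(h), p_value=float(p),
                          pairwise=pd.DataFrame(rows), alpha=alpha)


@dataclass
class EcdfSummary:
    quantiles: pd.Series  # deciles 0.1..0.9
    median: float
    mad: float
    ecdf: ECDF


def ecdf_summary(values) -> EcdfSummary:
    """Deciles, median, MAD and a right-continuous empirical CDF."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("ecdf_summary needs at least one finite value")
    q = np.arange(1, 10) / 10
    quantiles = pd.Series(np.quantile(v, q), index=q, name="quantile")
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    return EcdfSummary(quantiles=quantiles, median=med, mad=mad, ecdf=ECDF(v, side="right"))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame            # rows x components
    loadings: pd.DataFrame          # columns x components (orthonormal)
    explained_fraction: np.ndarray  # non-increasing, sums to <= 1


def pca(table: FeatureTable, n_components: int) -> PCAResult:
    """PCA of an autoscaled feature table with a fixed sign convention.

    The sign of each component is chosen so its largest-magnitude loading is
    positive, making scores reproducible across BLAS backends.  If the data
    rank cannot support the requested components the result is truncated
    with a warning.
    """
    X = table.data.to_numpy()
    n_rows, n_cols = X.shape
    limit = min(n_rows - 1, n_cols)
    if n_components > limit:
        raise ValueError(f"n_components {n_components} > min(rows-1, cols) = {limit}")
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # (columns, components)
    sv = model.singular_values_
    rank = int(np.sum(sv > 1e-10 * (sv[0] if sv[0] > 0 else 1.0)))
    if rank < n_components:
        warnings.warn(f"data rank {rank} < requested components {n_components}; truncating",
                      stacklevel=2)
        scores, loadings = scores[:, :rank], loadings[:, :rank]
        n_components = rank
    for k in range(n_components):
        if loadings[np.argmax(np.abs(loadings[:, k])), k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.data.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=table.data.columns, columns=comp_names),
        explained_fraction=model.explained_variance_ratio_[:n_components].copy(),
    )
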