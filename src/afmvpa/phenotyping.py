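"""Comorbidity phenotyping: dichotomize, impute, and cluster.

Clinical variables are mapped to 31 binary indicators, missing entries are
filled by column mode, and individuals are agglomerated by Ward's minimum
variance method on squared Euclidean distances. The two-cluster cut defines
the 'low risk' / 'high risk' phenotype used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DichotomizationRules",
    "PhenotypeMatrix",
    "LinkageTree",
    "PHENOTYPE_COLUMNS",
    "dichotomize",
    "impute_missing",
    "ward_linkage",
    "cut_clusters",
    "cluster_diagnostics",
]

# canonical column order of the 31 binary indicators
PHENOTYPE_COLUMNS = (
    "age_ge60",
    "sex_male",
    "bmi_ge25",
    "ethnicity_white",
    "alcohol_daily",
    "smoking_current",
    "egfr_lt90",
    "liver_abnormal",
    "cardioversion",
    "catheter_ablation",
    "lbbb",
    "lvh",
    "copd",
    "ckd",
    "heart_failure",
    "sleep_apnoea",
    "malignancy",
    "pad",
    "dementia",
    "stroke",
    "heart_disease",
    "t2d",
    "hypertension",
    "pci",
    "cabg",
    "pacemaker",
    "gi_bleeding",
    "rrt_transplant",
    "hypothyroidism",
    "hyperthyroidism",
    "anaemia",
)

# columns derived from continuous inputs; everything else is passed through
_DERIVED = {"age_ge60", "bmi_ge25", "egfr_lt90", "liver_abnormal", "anaemia"}


@dataclass(frozen=True)
class DichotomizationRules:
    """Clinical cut-points. Boundary conventions: age 60 and BMI 25 fall on
    the abnormal side; eGFR 90, GGT 40 and haematocrit exactly at the cut are
    normal."""

    age_cut: float = 60.0
    bmi_cut: float = 25.0
    egfr_cut: float = 90.0
    haematocrit_cut_female: float = 37.0
    haematocrit_cut_male: float = 40.0
    ggt_cut: float = 40.0

    def __post_init__(self) -> None:
        if min(
            self.age_cut,
            self.bmi_cut,
            self.egfr_cut,
            self.haematocrit_cut_female,
            self.haematocrit_cut_male,
            self.ggt_cut,
        ) <= 0:
            raise ValueError("all cut-points must be positive")


class PhenotypeMatrix:
    """Individuals x 31 binary indicators; entries may be NaN before imputation."""

    def __init__(self, ids, values: pd.DataFrame):
        if list(values.columns) != list(PHENOTYPE_COLUMNS):
            raise ValueError("phenotype matrix must carry exactly the 31 canonical columns")
        finite = values.to_numpy(dtype=float)
        ok = np.isnan(finite) | (finite == 0.0) | (finite == 1.0)
        if not ok.all():
            raise ValueError("phenotype entries must be 0, 1 or missing")
        self.ids = np.asarray(ids)
        self.values = values.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def to_array(self) -> np.ndarray:
        if self.n_missing:
            raise ValueError("matrix still contains missing entries; impute first")
        return self.values.to_numpy(dtype=float)


def dichotomize(clinical: pd.DataFrame, rules: DichotomizationRules | None = None) -> PhenotypeMatrix:
    """Map a clinical table to the 31-column binary phenotype matrix.

    Continuous inputs ``age``, ``bmi``, ``egfr``, ``ggt`` and ``haematocrit``
    (sex-specific cut) are dichotomized; the remaining indicators are taken
    as-is. Missingness is preserved as NaN. A haematocrit value with unknown
    sex yields a missing anaemia entry.
    """
    rules = rules or DichotomizationRules()
    n = len(clinical)
    out = pd.DataFrame(index=range(n), columns=list(PHENOTYPE_COLUMNS), dtype=float)

    def col(name):
        return pd.to_numeric(clinical[name], errors="coerce").to_numpy(dtype=float) if name in clinical else np.full(n, np.nan)

    age = col("age")
    out["age_ge60"] = np.where(np.isnan(age), np.nan, (age >= rules.age_cut).astype(float))
    bmi = col("bmi")
    out["bmi_ge25"] = np.where(np.isnan(bmi), np.nan, (bmi >= rules.bmi_cut).astype(float))
    egfr = col("egfr")
    out["egfr_lt90"] = np.where(np.isnan(egfr), np.nan, (egfr < rules.egfr_cut).astype(float))
    ggt = col("ggt")
    out["liver_abnormal"] = np.where(np.isnan(ggt), np.nan, (ggt > rules.ggt_cut).astype(float))

    sex = col("sex_male")
    hct = col("haematocrit")
    cut = np.where(sex == 1.0, rules.haematocrit_cut_male, rules.haematocrit_cut_female)
    anaemia = (hct < cut).astype(float)
    anaemia[np.isnan(hct) | np.isnan(sex)] = np.nan
    out["anaemia"] = anaemia
    out["sex_male"] = sex

    for name in PHENOTYPE_COLUMNS:
        if name in _DERIVED or name == "sex_male":
            continue
        out[name] = col(name)

    ids = clinical["id"].to_numpy() if "id" in clinical else np.arange(n)
    return PhenotypeMatrix(ids, out)


def impute_missing(matrix: PhenotypeMatrix) -> tuple[PhenotypeMatrix, int]:
    """Replace missing entries by the column mode (ties resolve to 0)."""
    values = matrix.values.copy()
    n_imputed = 0
    for name in PHENOTYPE_COLUMNS:
        colvals = values[name]
        miss = colvals.isna()
        if not miss.any():
            continue
        if miss.all():
            raise ValueError(f"column '{name}' is entirely missing; cannot impute")
        if miss.mean() > 0.5:
            raise ValueError(f"column '{name}' has >50% missingness")
        ones = (colvals == 1.0).sum()
        zeros = (colvals == 0.0).sum()
        fill = 1.0 if ones > zeros else 0.0
        values.loc[miss, name] = fill
        n_imputed += int(miss.sum())
    return PhenotypeMatrix(matrix.ids, values), n_imputed


@dataclass
class LinkageTree:
    """Agglomeration history: merges[i] = (cluster_a, cluster_b, height, size).

    Original observations are clusters 0..n-1; merge i creates cluster n+i.
    Heights are the within-cluster sum-of-squares increase of each merge.
    """

    merges: np.ndarray
    n_leaves: int

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        if self.merges.shape != (self.n_leaves - 1, 4):
            raise ValueError("linkage must have n-1 rows of 4")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def _merge_cost(size_a, cent_a, size_b, cent_b) -> float:
    """Ward objective: SSE increase when merging two clusters."""
    diff = cent_a - cent_b
    return size_a * size_b / (size_a + size_b) * float(diff @ diff)


def ward_linkage(matrix, *, rtol: float = 1e-9) -> LinkageTree:
    """Ward minimum-variance agglomeration on squared Euclidean distances.

    Uses the Lance-Williams update; at each step the pair of clusters with
    the smallest SSE increase merges, ties (within a relative tolerance)
    broken toward the lexicographically smallest index pair.
    """
    X = matrix.to_array() if isinstance(matrix, PhenotypeMatrix) else np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    vals = X[np.isfinite(X)]
    if not np.all((vals == 0.0) | (vals == 1.0)):
        raise ValueError("ward_linkage expects binary entries")
    if not np.all(np.isfinite(X)):
        raise ValueError("ward_linkage expects a complete matrix")

    # D holds twice the SSE increase (= squared Euclidean distance for singletons)
    sq = np.sum(X**2, axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    D = np.maximum(D, 0.0)  # clamp fp round-off
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    labels = np.arange(n)  # scipy-style cluster ids of the active rows
    merges = np.empty((n - 1, 4))

    for step in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], D, np.inf)
        dmin = masked.min()
        # tolerance-based tie set, then lowest (cluster-id) pair wins
        ties = np.argwhere(masked <= dmin * (1.0 + rtol) + 1e-12)
        best = None
        for i, j in ties:
            if i >= j:
                continue
            a, b = sorted((labels[i], labels[j]))
            if best is None or (a, b) < best[:2]:
                best = (a, b, i, j)
        a_id, b_id, i, j = best
        height = masked[i, j] / 2.0  # SSE increase
        new_size = sizes[i] + sizes[j]
        merges[step] = (a_id, b_id, height, new_size)

        # Lance-Williams Ward update into row i
        others = active.copy()
        others[i] = others[j] = False
        idx = np.where(others)[0]
        if idx.size:
            D[i, idx] = (
                (sizes[i] + sizes[idx]) * D[i, idx]
                + (sizes[j] + sizes[idx]) * D[j, idx]
                - sizes[idx] * D[i, j]
            ) / (new_size + sizes[idx])
            D[idx, i] = D[i, idx]
        active[j] = False
        sizes[i] = new_size
        labels[i] = n + step

    return LinkageTree(merges=merges, n_leaves=n)


def cut_clusters(tree: LinkageTree, k: int, matrix=None) -> np.ndarray:
    """Labels from removing the k-1 highest merges.

    Returns integer labels 0..k-1. When the phenotype matrix is supplied,
    label 1 marks the higher-comorbidity ('high risk') cluster for k = 2;
    clusters are otherwise numbered by first appearance.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = np.arange(n + max(n - 1, 0))

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for step in range(n - k):
        a, b, _, _ = tree.merges[step]
        new = n + step
        parent[find(int(a))] = new
        parent[find(int(b))] = new

    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)

    if k == 2 and matrix is not None:
        X = matrix.to_array() if isinstance(matrix, PhenotypeMatrix) else np.asarray(matrix, dtype=float)
        burden = X.sum(axis=1)
        mean0 = burden[labels == 0].mean()
        mean1 = burden[labels == 1].mean()
        if mean0 > mean1:
            labels = 1 - labels
    return labels


def cluster_diagnostics(tree: LinkageTree, matrix, k_range=range(2, 7)) -> dict:
    """Merge-height profile plus mean silhouette (squared Euclidean) per k."""
    from scipy.spatial.distance import pdist, squareform

    X = matrix.to_array() if isinstance(matrix, PhenotypeMatrix) else np.asarray(matrix, dtype=float)
    n = len(X)
    dist = squareform(pdist(X, metric="sqeuclidean"))
    out = {"heights": tree.heights.tolist(), "silhouette": {}}
    for k in k_range:
        if k > n:
            continue
        labels = cut_clusters(tree, k)
        out["silhouette"][k] = _mean_silhouette(dist, labels)
    return out


def _mean_silhouette(dist: np.ndarray, labels: np.ndarray) -> float | None:
    n = len(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        return None
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        a_n = counts[uniq.tolist().index(own)]
        if a_n == 1:
            s[i] = 0.0
            continue
        a = dist[i][labels == own].sum() / (a_n - 1)
        b = min(dist[i][labels == c].mean() for c in uniq if c != own)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    total = float(np.mean(s))
    if np.allclose(dist, 0.0):
        return None  # all points identical: silhouette undefined
    return total
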