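"""Site dissimilarity: Jaccard/Ruzicka distances, NMDS, PERMANOVA, PERMDISP.

The annotation view uses the binary Jaccard distance on accumulated
site x sonotype presence; the index view uses the Ruzicka distance
(quantitative Jaccard, 1 - sum(min)/sum(max)) on range-scaled site-mean
index profiles with ACT inverted to align directionality. Group
structure (the two study areas) is tested for location with PERMANOVA
(pseudo-F from the distance decomposition, label permutation) and for
dispersion with PERMDISP (ANOVA F on distances to group centroids in
principal-coordinate space, with Anderson's imaginary-axis correction
for negative eigenvalues). NMDS ordination summarises the matrices in
two dimensions with Kruskal stress-1 as the badness-of-fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

__all__ = [
    "DistanceMatrix",
    "NMDSResult",
    "PermTestResult",
    "jaccard_binary",
    "ruzicka",
    "prepare_index_profile",
    "nmds",
    "permanova",
    "permdisp",
    "mean_pairwise_dissimilarity",
]

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative site dissimilarity matrix, zero diagonal."""

    labels: list[str]
    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("distance matrix diagonal must be exactly 0")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class NMDSResult:
    """2-D (by default) ordination with Kruskal stress-1."""

    coordinates: pd.DataFrame  # sites x k
    stress: float
    converged: bool
    restarts_used: int
    seed: int


@dataclass
class PermTestResult:
    """Permutation-test outcome with the (b+1)/(m+1) p-value rule."""

    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    r_squared: float | None = None


# ---------------------------------------------------------------------------
# Distances


def _pairwise(matrix: np.ndarray, labels, kind: str) -> DistanceMatrix:
    n = matrix.shape[0]
    d = np.zeros((n, n))
    warned = False
    for i in range(n):
        for j in range(i + 1, n):
            a, b = matrix[i], matrix[j]
            denom = np.maximum(a, b).sum()
            if denom == 0.0:
                if not warned:
                    logger.warning("%s: two all-zero rows (%s, %s); distance "
                                   "defined as 0", kind, labels[i], labels[j])
                    warned = True
                dij = 0.0
            else:
                dij = 1.0 - np.minimum(a, b).sum() / denom
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=list(labels), values=d, method=kind)


def jaccard_binary(presence: pd.DataFrame) -> DistanceMatrix:
    """Binary Jaccard distance 1 - |A&B|/|A|B| on site presence rows."""
    if presence.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    vals = presence.to_numpy(dtype=np.float64)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("binary Jaccard requires a 0/1 matrix")
    return _pairwise(vals, presence.index, "jaccard_binary")


def ruzicka(features: pd.DataFrame) -> DistanceMatrix:
    """Ruzicka (quantitative Jaccard) distance 1 - sum(min)/sum(max)."""
    if features.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    vals = features.to_numpy(dtype=np.float64)
    if np.any(vals < 0):
        raise ValueError("Ruzicka distance requires non-negative features")
    return _pairwise(vals, features.index, "ruzicka")


def prepare_index_profile(site_means: pd.DataFrame,
                          invert: tuple[str, ...] = ("act",)) -> pd.DataFrame:
    """Range-scale site-mean indices to [0, 1], inverting ACT.

    ``site_means`` is indexed by site with columns act, aei, hf, sm
    (one dataset variant). Each column maps to (x - min)/(max - min);
    inverted columns are then replaced by 1 - scaled value so all
    features point the same way before the Ruzicka distance.
    """
    if site_means.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    out = {}
    for col in site_means.columns:
        x = site_means[col].to_numpy(dtype=np.float64)
        span = x.max() - x.min()
        if span == 0.0:
            raise ValueError(f"index {col!r} is constant across sites; "
                             "range-scaling undefined")
        scaled = (x - x.min()) / span
        out[col] = 1.0 - scaled if col in invert else scaled
    return pd.DataFrame(out, index=site_means.index)


# ---------------------------------------------------------------------------
# NMDS


def _stress1(d_obs: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding against observed dissimilarities."""
    n = len(coords)
    iu = np.triu_indices(n, 1)
    ed = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))[iu]
    obs = d_obs[iu]
    order = np.argsort(obs, kind="stable")
    iso = IsotonicRegression()
    disparities = np.empty_like(ed)
    disparities[order] = iso.fit_transform(np.arange(len(order)), ed[order])
    denom = float((ed ** 2).sum())
    if denom == 0.0:
        return np.inf
    return float(np.sqrt(((ed - disparities) ** 2).sum() / denom))


def nmds(d: DistanceMatrix, k: int = 2, restarts: int = 20,
         seed: int = 0) -> NMDSResult:
    """Non-metric MDS (best of ``restarts``) with Kruskal stress-1.

    Runs SMACOF with monotone regression on the precomputed
    dissimilarities; coordinates are deterministic for a fixed seed.
    ``converged`` is False for degenerate inputs (all-equal distances).
    """
    if d.n < k + 2:
        raise ValueError(f"NMDS in {k}-d needs at least {k + 2} sites")
    iu = np.triu_indices(d.n, 1)
    degenerate = np.allclose(d.values[iu], d.values[iu][0])
    mds = MDS(n_components=k, metric=False, dissimilarity="precomputed",
              n_init=restarts, max_iter=500, eps=1e-9, random_state=seed,
              normalized_stress=True)
    coords = mds.fit_transform(d.values)
    stress = _stress1(d.values, coords)
    frame = pd.DataFrame(coords, index=d.labels,
                         columns=[f"nmds{i + 1}" for i in range(k)])
    return NMDSResult(coordinates=frame, stress=stress,
                      converged=not degenerate and np.isfinite(stress),
                      restarts_used=restarts, seed=seed)


# ---------------------------------------------------------------------------
# Permutation tests


def _group_codes(d: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, dict):
        labels = [groups[lab] for lab in d.labels]
    else:
        labels = list(groups)
        if len(labels) != d.n:
            raise ValueError("groups length must match the distance matrix")
    codes = pd.Categorical(labels).codes.astype(np.int64)
    counts = np.bincount(codes)
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 members")
    return codes


def _permanova_ss(d2: np.ndarray, codes: np.ndarray
                  ) -> tuple[float, float, float]:
    """(SS_total, SS_within, SS_between) from squared distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(codes):
        mask = codes == g
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * mask.sum())
    return ss_total, ss_within, ss_total - ss_within


def _perm_f_batch(d2: np.ndarray, perm_codes: np.ndarray, n_groups: int,
                  n: int) -> np.ndarray:
    """Pseudo-F for a batch of permuted group-code rows (m, n)."""
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = np.zeros(perm_codes.shape[0])
    for g in range(n_groups):
        mask = (perm_codes == g).astype(np.float64)  # (m, n)
        quad = np.einsum("mi,ij,mj->m", mask, d2, mask)
        ss_within += quad / (2.0 * mask.sum(axis=1))
    ss_between = ss_total - ss_within
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(d: DistanceMatrix, groups, n_perm: int = 9999,
              seed: int = 0) -> PermTestResult:
    """PERMANOVA: pseudo-F location test by raw-label permutation.

    F = (SS_between/(a-1)) / (SS_within/(n-a)) with SS terms from the
    squared-distance decomposition; R² = SS_between/SS_total;
    p = (exceedances + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    codes = _group_codes(d, groups)
    n, a = d.n, len(np.unique(codes))
    d2 = d.values ** 2
    ss_total, ss_within, ss_between = _permanova_ss(d2, codes)
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    perm_codes = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    f_perm = _perm_f_batch(d2, perm_codes, a, n)
    p = (np.sum(f_perm >= f_obs - 1e-12) + 1.0) / (n_perm + 1.0)
    return PermTestResult(statistic=float(f_obs), p_value=float(p),
                          n_permutations=n_perm, seed=seed,
                          r_squared=float(r2))


def _centroid_distances(d: DistanceMatrix, codes: np.ndarray) -> np.ndarray:
    """Distance of each site to its group centroid in PCoA space.

    Negative eigenvalues contribute imaginary axes whose squared
    distances subtract (Anderson's correction); negative squared
    distances are clamped at zero.
    """
    n = d.n
    d2 = d.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((gower + gower.T) / 2.0)
    keep = np.abs(eigval) > 1e-10 * np.abs(eigval).max()
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(np.abs(eigval))
    sign = np.sign(eigval)  # +1 real axes, -1 imaginary axes

    z = np.empty(n)
    for g in np.unique(codes):
        mask = codes == g
        centroid = coords[mask].mean(axis=0)
        diff2 = (coords[mask] - centroid) ** 2
        z2 = (diff2 * sign).sum(axis=1)
        z[mask] = np.sqrt(np.maximum(z2, 0.0))
    return z


def permdisp(d: DistanceMatrix, groups, n_perm: int = 9999,
             seed: int = 0) -> PermTestResult:
    """PERMDISP: homogeneity of multivariate dispersion between groups.

    Distances to group centroids (principal-coordinate embedding,
    imaginary-axis correction) are compared with a one-way ANOVA F;
    the p-value permutes the group labels of those distances.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    codes = _group_codes(d, groups)
    a = len(np.unique(codes))
    z = _centroid_distances(d, codes)
    n = len(z)

    def anova_f(vals: np.ndarray, code_rows: np.ndarray) -> np.ndarray:
        grand = vals.mean()
        ss_b = np.zeros(code_rows.shape[0])
        ss_w = np.zeros(code_rows.shape[0])
        for g in range(a):
            mask = (code_rows == g)
            ng = mask.sum(axis=1)
            gsum = np.where(mask, vals[None, :], 0.0).sum(axis=1)
            gmean = gsum / ng
            ss_b += ng * (gmean - grand) ** 2
            ss_w += (np.where(mask, (vals[None, :] - gmean[:, None]) ** 2,
                              0.0)).sum(axis=1)
        ss_w = np.maximum(ss_w, 1e-300)
        return (ss_b / (a - 1)) / (ss_w / (n - a))

    f_obs = float(anova_f(z, codes[None, :])[0])
    rng = np.random.default_rng(seed)
    perm_codes = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    f_perm = anova_f(z, perm_codes)
    p = (np.sum(f_perm >= f_obs - 1e-12) + 1.0) / (n_perm + 1.0)
    return PermTestResult(statistic=f_obs, p_value=float(p),
                          n_permutations=n_perm, seed=seed)


def mean_pairwise_dissimilarity(d: DistanceMatrix, groups
                                ) -> tuple[float, dict[str, float]]:
    """Between-group mean distance and per-group within means.

    Groups of size 1 get a within mean of NaN (reported missing).
    """
    if isinstance(groups, dict):
        labels = np.array([groups[lab] for lab in d.labels])
    else:
        labels = np.asarray(list(groups))
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    iu = np.triu_indices(d.n, 1)
    same = labels[iu[0]] == labels[iu[1]]
    between = float(d.values[iu][~same].mean())
    within: dict[str, float] = {}
    for g in uniq:
        mask = same & (labels[iu[0]] == g)
        within[str(g)] = float(d.values[iu][mask].mean()) if mask.any() else np.nan
    return between, within
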