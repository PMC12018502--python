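"""Demographic comparisons and the voxelwise covariate-adjusted group contrast.

The voxelwise model is ordinary least squares on [intercept, group, covariates]
per masked voxel; the group t map (patient − control) is thresholded two-tailed
at the cluster-forming p, connected components are labelled, and cluster-level
family-wise error is controlled either by max-cluster-size permutation of the
group labels (default; exactly valid at small n under exchangeability) or by a
Gaussian-random-field approximation with residual-smoothness (FWHM) estimation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .dfcd import DFCDMap
from .imaging_io import AtlasParcellation, SubjectTable

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclasses.dataclass(frozen=True)
class CorrectionParams:
    voxel_p: float = 0.001          # cluster-forming p, two-tailed
    cluster_p: float = 0.05         # corrected cluster-level threshold
    method: str = "permutation"     # or "rft"
    n_permutations: int = 1000
    connectivity: int = 26
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.voxel_p < 1 and 0 < self.cluster_p < 1):
            raise ValueError("voxel_p and cluster_p must lie in (0, 1)")
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.method not in ("permutation", "rft"):
            raise ValueError("method must be 'permutation' or 'rft'")


@dataclasses.dataclass
class TStatMap:
    """Group-contrast t map plus everything needed to permute it."""

    t: np.ndarray               # (n_masked_voxels,)
    df: int
    mask: np.ndarray            # 3D boolean
    affine: np.ndarray
    betas: pd.DataFrame         # columns × voxels coefficient maps
    design: np.ndarray          # (n_subjects, n_columns)
    design_columns: list[str]
    response: np.ndarray        # (n_subjects, n_masked_voxels)

    def to_volume(self) -> np.ndarray:
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.t
        return vol


def compare_demographics(subjects: SubjectTable,
                         spec: list[dict]) -> pd.DataFrame:
    """Group comparisons of demographic/clinical columns.

    spec entries are {"column": name, "test": "t" | "chi2"}. chi2 is the
    Pearson chi-square without continuity correction on the group × category
    table; t is the pooled-variance two-sample t (patient − control).
    """
    table = subjects.table
    is_patient = table["group"] == "patient"
    rows = []
    for item in spec:
        col, test = item["column"], item["test"]
        if col not in table:
            raise ValueError(f"no such column: {col}")
        if test == "chi2":
            counts = pd.crosstab(table["group"], table[col])
            if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
                raise ValueError(f"{col}: zero marginal in contingency table")
            stat, p, _, _ = stats.chi2_contingency(counts.to_numpy(),
                                                   correction=False)
        elif test == "t":
            a = table.loc[is_patient, col].to_numpy(dtype=float)
            b = table.loc[~is_patient, col].to_numpy(dtype=float)
            stat, p = stats.ttest_ind(a, b, equal_var=True)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"column": col, "test": test,
                     "statistic": float(stat), "p": float(p)})
    return pd.DataFrame(rows)


def _stack_maps(maps: list[DFCDMap]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mask = maps[0].mask
    for m in maps[1:]:
        if m.mask.shape != mask.shape or not np.array_equal(m.mask, mask):
            raise ValueError("all subject maps must share an identical mask")
    response = np.stack([m.values for m in maps])
    return response, mask, maps[0].affine


def _build_design(subjects: SubjectTable,
                  covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(subjects)), subjects.group_indicator]
    names = ["intercept", "group"]
    cov = subjects.covariate_matrix(tuple(covariates))
    for j, name in enumerate(covariates):
        cols.append(cov[:, j])
        names.append(name)
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        _, r = np.linalg.qr(design)
        bad = [names[j] for j in range(design.shape[1])
               if abs(r[j, j]) < 1e-10]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return design, names


def _glm_t(design: np.ndarray, response: np.ndarray,
           col: int = 1) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS t for one design column, vectorised over voxels."""
    n, p = design.shape
    df = n - p
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ design.T @ response            # (p, V)
    resid = response - design @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(sigma2 * xtx_inv[col, col])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[col] / se, 0.0)
    return t, beta, df


def fit_group_glm(maps: list[DFCDMap], subjects: SubjectTable,
                  covariates: tuple[str, ...] = ("age", "sex")) -> TStatMap:
    """Voxelwise group contrast (patient − control) adjusting for covariates.

    With no covariates the t statistic equals the textbook pooled two-sample t.
    """
    if len(maps) != len(subjects):
        raise ValueError("one map per subject required")
    response, mask, affine = _stack_maps(maps)
    design, names = _build_design(subjects, covariates)
    df = len(subjects) - design.shape[1]
    if df < 1:
        raise ValueError("non-positive residual degrees of freedom")
    t, beta, df = _glm_t(design, response)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite t values on the mask")
    return TStatMap(t=t, df=df, mask=mask, affine=affine,
                    betas=pd.DataFrame(beta, index=names),
                    design=design, design_columns=names, response=response)


def _labelled_clusters(t_vol: np.ndarray, mask: np.ndarray, tcrit: float,
                       structure: np.ndarray) -> list[np.ndarray]:
    """Connected suprathreshold components, positive and negative separately
    (so opposite-sign clusters never merge)."""
    clusters = []
    for sign in (1.0, -1.0):
        supra = (sign * t_vol > tcrit) & mask
        lab, n = ndimage.label(supra, structure=structure)
        for k in range(1, n + 1):
            clusters.append(lab == k)
    return clusters


def _max_cluster_size(t: np.ndarray, mask: np.ndarray, tcrit: float,
                      structure: np.ndarray) -> int:
    vol = np.zeros(mask.shape)
    vol[mask] = t
    sizes = [int(c.sum()) for c in _labelled_clusters(vol, mask, tcrit, structure)]
    return max(sizes) if sizes else 0


def _estimate_fwhm(resid: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-axis smoothness (FWHM, voxels) from normalised residual gradients."""
    norm = resid / np.sqrt(np.einsum("ij,ij->j", resid, resid))
    vols = np.zeros((resid.shape[0],) + mask.shape)
    vols[:, mask] = norm
    fwhm = np.empty(3)
    for ax in range(3):
        d = np.diff(vols, axis=ax + 1)
        valid = np.logical_and(np.take(mask, range(mask.shape[ax] - 1), axis=ax),
                               np.take(mask, range(1, mask.shape[ax]), axis=ax))
        grad_var = np.mean(d[:, valid] ** 2) if valid.any() else np.inf
        lam = max(grad_var, 1e-12)
        fwhm[ax] = np.sqrt(4.0 * np.log(2.0) / lam)
    return fwhm


def _rft_cluster_p(k: int, u: float, n_voxels: int,
                   fwhm: np.ndarray) -> float:
    """Corrected cluster-level p for a cluster of k voxels in a 3D Gaussian
    random field thresholded at z = u (Friston et al. expected-cluster form)."""
    from scipy.special import gamma

    resels = n_voxels / np.prod(fwhm)
    em = (resels * (4 * np.log(2.0)) ** 1.5 * (u ** 2 - 1)
          * np.exp(-u ** 2 / 2) / (2 * np.pi) ** 2)
    em = max(em, 1e-12)
    p_voxel = stats.norm.sf(u)
    en = n_voxels * p_voxel / em            # expected cluster size, voxels
    beta = (gamma(2.5) / max(en, 1e-12)) ** (2.0 / 3.0)
    p_k = np.exp(-beta * k ** (2.0 / 3.0))
    return float(1.0 - np.exp(-em * p_k))


def cluster_correct(tmap: TStatMap, params: CorrectionParams = CorrectionParams(),
                    atlas: AtlasParcellation | None = None) -> pd.DataFrame:
    """Cluster-level corrected group differences.

    Forms clusters at the two-tailed voxel_p threshold of t(df); corrected_p
    is either the max-cluster-size permutation p (group labels permuted,
    covariates staying attached to their subjects) or the random-field-theory
    cluster p. Returns rows {region_label, peak_t, peak_x/y/z (mm),
    cluster_size, corrected_p} for clusters with corrected_p < cluster_p;
    no suprathreshold voxels gives an empty table.
    """
    if tmap.df < 3:
        raise ValueError("need residual df >= 3")
    if params.method == "permutation" and params.n_permutations < 100:
        warnings.warn("fewer than 100 permutations; corrected p is coarse",
                      stacklevel=2)
    structure = _STRUCTURES[params.connectivity]
    tcrit = stats.t.ppf(1 - params.voxel_p / 2, tmap.df)
    t_vol = tmap.to_volume()
    clusters = _labelled_clusters(t_vol, tmap.mask, tcrit, structure)
    columns = ["region_label", "peak_t", "peak_x", "peak_y", "peak_z",
               "cluster_size", "corrected_p"]
    if not clusters:
        return pd.DataFrame(columns=columns)

    if params.method == "permutation":
        rng = np.random.default_rng(params.seed)
        group_col = tmap.design_columns.index("group")
        null_max = np.empty(params.n_permutations, dtype=np.int64)
        for b in range(params.n_permutations):
            perm_design = tmap.design.copy()
            # a relabelling can be exactly collinear with a binary covariate
            # (rank-deficient design): such draws carry no information, redraw
            for _ in range(100):
                perm_design[:, group_col] = rng.permutation(
                    tmap.design[:, group_col])
                if np.linalg.matrix_rank(perm_design) == perm_design.shape[1]:
                    break
            else:
                raise RuntimeError("could not draw a full-rank relabelling")
            t_perm, _, _ = _glm_t(perm_design, tmap.response, col=group_col)
            null_max[b] = _max_cluster_size(t_perm, tmap.mask, tcrit, structure)

        def corrected(size: int, _peak: float) -> float:
            return float((1 + np.sum(null_max >= size))
                         / (1 + params.n_permutations))
    else:
        resid = tmap.response - tmap.design @ np.linalg.pinv(tmap.design) \
            @ tmap.response
        fwhm = _estimate_fwhm(resid, tmap.mask)
        # equivalent Gaussian threshold for the t cluster-forming level
        u = stats.norm.isf(stats.t.sf(tcrit, tmap.df))
        n_voxels = int(tmap.mask.sum())

        def corrected(size: int, _peak: float) -> float:
            return _rft_cluster_p(size, u, n_voxels, fwhm)

    rows = []
    for comp in clusters:
        idx = np.argwhere(comp)
        tvals = t_vol[comp]
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
        idx, tvals = idx[order], tvals[order]
        peak_pos = int(np.argmax(np.abs(tvals)))  # first in (x,y,z) order on ties
        peak_vox = idx[peak_pos]
        peak_mm = tmap.affine @ np.append(peak_vox, 1.0)
        size = int(comp.sum())
        p_corr = corrected(size, float(tvals[peak_pos]))
        if atlas is not None:
            labels_here = atlas.labels[comp]
            labels_here = labels_here[labels_here != 0]
            region = atlas.name_of(int(np.bincount(labels_here).argmax())) \
                if labels_here.size else "unlabelled"
        else:
            region = f"cluster_{len(rows) + 1}"
        rows.append({"region_label": region,
                     "peak_t": float(tvals[peak_pos]),
                     "peak_x": float(peak_mm[0]), "peak_y": float(peak_mm[1]),
                     "peak_z": float(peak_mm[2]),
                     "cluster_size": size, "corrected_p": p_corr})
    out = pd.DataFrame(rows, columns=columns)
    out = out[out["corrected_p"] < params.cluster_p]
    return out.sort_values(["corrected_p", "cluster_size"],
                           ascending=[True, False]).reset_index(drop=True)
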