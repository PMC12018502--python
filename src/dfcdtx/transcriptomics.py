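"""PLS association between a regional imaging contrast and gene expression.

The regional group-difference map (mean t per parcel) is the response; the
region × gene expression matrix (genes z-scored across regions) is the
predictor block. Component-1 gene weights are taken from a one-component PLS
regression, sign-aligned so the region scores correlate positively with the
response: genes with the most positive weights ("PLS+") are those whose
expression rises where the contrast rises, the most negative are "PLS−".
Optionally a bootstrap over regions turns weights into Z = weight / SE.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .group_stats import TStatMap
from .imaging_io import AtlasParcellation

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PLSResult:
    weights: pd.Series                  # gene -> component-1 weight
    region_scores: pd.Series            # region -> component-1 score
    y_variance_explained: np.ndarray    # per component
    bootstrap_z: pd.Series | None = None


@dataclasses.dataclass
class GeneRanking:
    positive: list[str]     # top n_top, descending
    negative: list[str]     # bottom n_top, ascending (most negative first)
    n_top: int


def parcel_mean(tmap: TStatMap, atlas: AtlasParcellation) -> pd.Series:
    """Mean t over each region's masked voxels, indexed by region id.

    Regions with no masked voxels are excluded (logged); fewer than 3
    surviving regions is an error.
    """
    if tmap.mask.shape != atlas.labels.shape:
        raise ValueError("t map and atlas grids differ")
    t_vol = tmap.to_volume()
    values, index = [], []
    for rid in atlas.region_ids:
        sel = (atlas.labels == rid) & tmap.mask
        if not sel.any():
            log.info("region %d has no masked voxels; excluded", rid)
            continue
        values.append(float(t_vol[sel].mean()))
        index.append(int(rid))
    if len(values) < 3:
        raise ValueError("fewer than 3 regions survive masking")
    return pd.Series(values, index=pd.Index(index, name="region_id"), name="t")


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(ddof=1)
    dropped = sd.index[sd == 0]
    if len(dropped):
        log.info("dropping %d zero-variance genes", len(dropped))
        X = X.drop(columns=dropped)
        sd = sd.drop(dropped)
    return (X - X.mean()) / sd


def pls_association(y: pd.Series, X: pd.DataFrame, n_components: int = 1,
                    standardize: bool = True) -> PLSResult:
    """Component-1 PLS gene weights for a regional response.

    y and X must share their region index. Genes are z-scored across regions
    first (configurable); the component is flipped if needed so that
    corr(region scores, y) >= 0.
    """
    common = y.index.intersection(X.index)
    if len(common) != len(y) or len(common) != len(X):
        missing = set(y.index).symmetric_difference(X.index)
        raise ValueError(f"region mismatch between y and X: {sorted(missing)}")
    X = X.loc[y.index]
    if float(np.std(y)) == 0:
        raise ValueError("response has zero variance")
    if standardize:
        X = _standardize(X)
    y_c = (y - y.mean()).to_numpy(dtype=float)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X.to_numpy(dtype=float), y_c)
    weights = pls.x_weights_[:, 0].copy()
    scores = pls.x_scores_[:, 0].copy()
    if np.corrcoef(scores, y_c)[0, 1] < 0:
        weights, scores = -weights, -scores
    total = float(y_c @ y_c)
    fitted = pls.predict(X.to_numpy(dtype=float)).ravel()
    resid = y_c - fitted
    var_expl = np.array([1.0 - float(resid @ resid) / total])
    return PLSResult(
        weights=pd.Series(weights, index=X.columns, name="weight"),
        region_scores=pd.Series(scores, index=y.index, name="score"),
        y_variance_explained=var_expl,
    )


def bootstrap_weights(y: pd.Series, X: pd.DataFrame, n_boot: int = 1000,
                      seed: int = 0, standardize: bool = True) -> pd.Series:
    """Z = weight / bootstrap SE, resampling regions with replacement.

    Each bootstrap component is sign-aligned to the original weights before
    aggregation; a degenerate resample (constant y) is redrawn up to 10 times.
    """
    if n_boot < 100:
        raise ValueError("need n_boot >= 100")
    base = pls_association(y, X, standardize=standardize)
    genes = base.weights.index
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(genes)))
    n = len(y)
    for b in range(n_boot):
        for attempt in range(10):
            idx = rng.integers(n, size=n)
            y_b = y.iloc[idx]
            if float(np.std(y_b)) > 0:
                break
        else:
            raise RuntimeError("could not draw a non-degenerate resample")
        X_b = X.iloc[idx]
        X_b = X_b.set_index(pd.RangeIndex(n))
        y_b = y_b.reset_index(drop=True)
        res = pls_association(y_b, X_b, standardize=standardize)
        w = res.weights.reindex(genes).to_numpy()
        w = np.nan_to_num(w, nan=0.0)
        if w @ base.weights.to_numpy() < 0:
            w = -w
        boots[b] = w
    se = boots.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, base.weights.to_numpy() / se, 0.0)
    return pd.Series(z, index=genes, name="z")


def rank_genes(result: PLSResult, n_top: int = 1318,
               by: str = "weight") -> GeneRanking:
    """Signed top-N gene lists from component-1 weights or bootstrap Z.

    Ties are broken by gene symbol so the selection is deterministic.
    """
    if by == "weight":
        scores = result.weights
    elif by == "z":
        if result.bootstrap_z is None:
            raise ValueError("no bootstrap Z available; run bootstrap_weights")
        scores = result.bootstrap_z
    else:
        raise ValueError("by must be 'weight' or 'z'")
    if 2 * n_top > len(scores):
        raise ValueError(
            f"2*n_top = {2 * n_top} exceeds {len(scores)} genes")
    frame = scores.rename("score").rename_axis("gene").reset_index()
    pos = frame.sort_values(["score", "gene"], ascending=[False, True])
    neg = frame.sort_values(["score", "gene"], ascending=[True, True])
    return GeneRanking(positive=pos["gene"].head(n_top).tolist(),
                       negative=neg["gene"].head(n_top).tolist(),
                       n_top=n_top)


def recovery_auc(scores: pd.Series, planted: set[str]) -> float:
    """AUC for separating planted from null genes by |score| (Mann-Whitney)."""
    is_planted = scores.index.isin(planted)
    if is_planted.all() or not is_planted.any():
        raise ValueError("need both planted and null genes")
    u = stats.mannwhitneyu(np.abs(scores[is_planted]),
                           np.abs(scores[~is_planted]),
                           alternative="greater").statistic
    return float(u / (is_planted.sum() * (~is_planted).sum()))
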