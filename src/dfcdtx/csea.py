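"""Cell-type / brain-region specificity: pSI and threshold enrichment.

The specificity index (SI) of a gene for a type is rank-based: for every
other type, genes are ranked by the ratio of mean expression in the target
type to mean expression in the other type (rank 1 = most enriched), and SI
is the average of those ranks — small SI means consistently type-specific.
pSI converts SI into a probability by permuting the sample type labels:
pSI = Pr[SI_perm <= SI_observed]. When the number of distinct label
assignments is at most n_perm the permutation distribution is enumerated
exhaustively (the p is then exact); otherwise n_perm seeded shuffles are
drawn and the add-one estimator (1 + hits) / (1 + n_perm) is used.

Candidate sets at nested thresholds (0.05 ⊇ 0.01 ⊇ 0.001 ⊇ 0.0001) are then
tested for over-representation of a gene list by one-sided Fisher exact tests.
"""

from __future__ import annotations

import logging
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.05, 0.01, 0.001, 0.0001)
_EPS = 1e-9


def _si_matrix(profiles: np.ndarray, labels: np.ndarray,
               types: np.ndarray) -> np.ndarray:
    """SI per (type, gene): mean rank of the expression ratio vs other types.

    Ranks of the t-vs-o mean-expression ratio equal ranks of the log-mean
    difference, which vectorises across comparison types.
    """
    n_types = len(types)
    onehot = (labels[:, None] == np.arange(n_types)).astype(float)
    means = (onehot.T @ profiles) / onehot.sum(axis=0)[:, None]
    log_means = np.log(means + _EPS)
    n_genes = profiles.shape[1]
    si = np.zeros((n_types, n_genes))
    for t in range(n_types):
        others = np.delete(np.arange(n_types), t)
        diff = log_means[t][None, :] - log_means[others]
        ranks = stats.rankdata(-diff, method="average", axis=1)
        si[t] = ranks.mean(axis=0)
    return si


def _multiset_permutations(items: list[int]):
    """All distinct orderings of a multiset (lexicographic)."""
    counts = {}
    for x in items:
        counts[x] = counts.get(x, 0) + 1
    keys = sorted(counts)
    out: list[int] = []

    def rec():
        if len(out) == len(items):
            yield tuple(out)
            return
        for k in keys:
            if counts[k]:
                counts[k] -= 1
                out.append(k)
                yield from rec()
                out.pop()
                counts[k] += 1

    yield from rec()


def n_distinct_assignments(labels: list) -> int:
    counts = pd.Series(labels).value_counts()
    n = factorial(len(labels))
    for c in counts:
        n //= factorial(int(c))
    return n


def compute_psi(profiles: pd.DataFrame, types: pd.Series,
                n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """pSI per gene per type from samples × genes profiles.

    types gives the type label of every profile row. Returns a genes × types
    DataFrame of pSI values in (0, 1]; smaller = more specific.
    """
    if not profiles.index.equals(types.index):
        types = types.reindex(profiles.index)
        if types.isna().any():
            raise ValueError("every profile row needs a type label")
    type_names = sorted(types.unique())
    if len(type_names) < 2:
        raise ValueError("need at least 2 types")
    counts = types.value_counts()
    if (counts < 1).any():
        raise ValueError("a type has zero samples")
    labels = np.array([type_names.index(t) for t in types])
    values = profiles.to_numpy(dtype=float)
    obs = _si_matrix(values, labels, np.arange(len(type_names)))

    exhaustive = n_distinct_assignments(list(labels)) <= n_perm
    hits = np.zeros_like(obs)
    if exhaustive:
        total = 0
        for perm in _multiset_permutations(list(labels)):
            si = _si_matrix(values, np.array(perm), np.arange(len(type_names)))
            hits += si <= obs + 1e-12
            total += 1
        psi = hits / total
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            si = _si_matrix(values, perm, np.arange(len(type_names)))
            hits += si <= obs + 1e-12
        psi = (1.0 + hits) / (1.0 + n_perm)
    out = pd.DataFrame(psi.T, index=profiles.columns, columns=type_names)
    out.index.name = "gene"
    return out


def candidate_genes(psi: pd.DataFrame, type_name: str,
                    threshold: float) -> set[str]:
    return set(psi.index[psi[type_name] < threshold])


def specificity_enrichment(gene_list: list[str], psi: pd.DataFrame,
                           thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                           background: list[str] | None = None) -> pd.DataFrame:
    """One-sided Fisher enrichment of gene_list in each type's candidate set.

    thresholds must be descending; candidate sets are asserted to nest.
    An empty candidate set records p = 1 rather than erroring.
    """
    if list(thresholds) != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be descending")
    universe = set(background) if background is not None else set(psi.index)
    listed = set(gene_list) & universe
    rows = []
    for type_name in psi.columns:
        previous = None
        for thr in thresholds:
            cand = candidate_genes(psi, type_name, thr) & universe
            if previous is not None and not cand <= previous:
                raise AssertionError("candidate sets failed to nest")
            previous = cand
            a = len(listed & cand)
            b = len(listed - cand)
            c = len(cand - listed)
            d = len(universe) - a - b - c
            if not cand:
                p = 1.0
            else:
                _, p = stats.fisher_exact([[a, b], [c, d]],
                                          alternative="greater")
            rows.append({"type": type_name, "threshold": thr,
                         "candidates": len(cand), "overlap": a,
                         "p": float(p)})
    return pd.DataFrame(rows)
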