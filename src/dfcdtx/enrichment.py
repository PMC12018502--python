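"""Over-representation analysis of gene lists against GMT collections.

One-sided hypergeometric upper-tail p per set, Benjamini-Hochberg q across
the sets of a collection. The background defaults to the tested universe
(all genes in the expression matrix), since the selection operated on it.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets in one namespace (e.g. BP / CC / MF / pathway)."""

    sets: dict[str, set[str]]
    namespace: str = ""
    descriptions: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for name, members in self.sets.items():
            members = {str(g).upper() for g in members}
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            cleaned[name] = members
        self.sets = cleaned


def read_gmt(path: str | Path, namespace: str = "") -> GeneSetCollection:
    sets, desc = {}, {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = set(fields[2:])
        desc[fields[0]] = fields[1]
    return GeneSetCollection(sets=sets, namespace=namespace, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name in sorted(collection.sets):
        desc = collection.descriptions.get(name, "na")
        genes = "\t".join(sorted(collection.sets[name]))
        lines.append(f"{name}\t{desc}\t{genes}")
    Path(path).write_text("\n".join(lines) + "\n")


def enrich(gene_list: list[str], collection: GeneSetCollection,
           background: list[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of gene_list in each set.

    p(set) = P[X >= overlap], X ~ Hypergeom(M=|background|, K=|set∩background|,
    N=|list|); q is the BH step-up value across the collection's sets.
    Genes outside the background are logged and dropped from the list.
    """
    background_set = {g.upper() for g in background}
    if not background_set:
        raise ValueError("empty background")
    listed = {g.upper() for g in gene_list}
    stray = listed - background_set
    if stray:
        log.info("dropping %d list genes outside the background", len(stray))
        listed &= background_set
    if not listed:
        raise ValueError("empty gene list after background filtering")
    M, N = len(background_set), len(listed)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & background_set
        K = len(members)
        k = len(members & listed)
        p = float(hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        expected = K * N / M
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "list_size": N,
                     "fold_enrichment": (k / expected) if expected else np.nan,
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["p", "set"]).reset_index(drop=True)
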