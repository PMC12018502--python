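"""Synthetic inputs with planted, recoverable ground truth.

Every pipeline input — two-group 4D BOLD with state-switching connectivity,
an integer parcellation, a subject table, a region × gene expression matrix,
GMT gene-set collections, cell-type expression profiles and a PPI edge list —
is generated from a single integer seed via named substreams, so each stage
can be regenerated independently and bit-identically.

The BOLD model is a parcel-level hidden-Markov switching process: each parcel
carries a latent state sequence; in state k the parcels of a community share a
common latent signal, which induces suprathreshold correlation between their
voxels. Patients' designated "affected" parcels switch state less often than
controls', so their windowed connectivity degree fluctuates less across
windows — lower dFCD variability, the planted group effect. Equal switch
rates give an exact null: the two groups are then draws from the same process.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .imaging_io import AtlasParcellation, BoldSeries, SubjectTable

_SUBSTREAMS = ("bold", "demographics", "expression", "sets", "ppi", "profiles")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG of the global seed; stable across calls."""
    if name not in _SUBSTREAMS:
        raise ValueError(f"unknown substream {name!r}; known: {_SUBSTREAMS}")
    key = _SUBSTREAMS.index(name)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Cohort simulation parameters.

    grid_shape must tile into n_regions equal rectangular parcels.
    switch_rate_* are per-step probabilities of leaving the current state,
    where a step is state_step TRs (the sliding step of the windowed
    analysis, so reconfiguration happens on the timescale the windows
    resolve); switch_rate_patient < switch_rate_control plants lower dFCD
    variability in patients' affected parcels. coupling/noise_sd set the
    within-community correlation at coupling² / (coupling² + noise_sd²)
    (0.5 by default, comfortably above the r = 0.2 connectivity threshold).
    """

    grid_shape: tuple[int, int, int] = (12, 12, 6)
    n_regions: int = 24
    T: int = 230
    TR: float = 2.0
    n_per_group: int = 20
    n_states: int = 2
    switch_rate_control: float = 0.08
    switch_rate_patient: float = 0.01
    affected_region_ids: tuple[int, ...] | None = None
    noise_sd: float = 1.0
    coupling: float = 0.9
    state_step: int = 10
    n_communities: int = 2
    confounded: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.switch_rate_control <= 1
                and 0 <= self.switch_rate_patient <= 1):
            raise ValueError("switch rates must lie in [0, 1]")
        if int(np.prod(self.grid_shape)) < self.n_regions:
            raise ValueError("grid volume smaller than n_regions")
        if self.n_states < 2:
            raise ValueError("need at least 2 connectivity states")

    @property
    def affected(self) -> tuple[int, ...]:
        """Default: the parcels of the first latent community."""
        if self.affected_region_ids is not None:
            return tuple(self.affected_region_ids)
        n_comm = min(self.n_communities, self.n_regions)
        community = np.arange(self.n_regions) * n_comm // self.n_regions
        return tuple(int(p) + 1 for p in np.flatnonzero(community == 0))


@dataclasses.dataclass(frozen=True)
class ExpressionSimConfig:
    """Region × gene matrix with genes planted to track a regional map."""

    n_genes: int = 2000
    n_linked_pos: int = 20
    n_linked_neg: int = 20
    link_strength: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_linked_pos + self.n_linked_neg > self.n_genes:
            raise ValueError("more planted genes than genes")
        if not (0 < self.link_strength < 1):
            raise ValueError("link_strength must be strictly inside (0, 1)")


def _tile_factors(grid_shape: tuple[int, int, int], n_regions: int
                  ) -> tuple[int, int, int]:
    """Parcels per axis (nx, ny, nz) with nx·ny·nz = n_regions and each axis
    length divisible by its parcel count."""
    gx, gy, gz = grid_shape
    best = None
    for nx in range(1, n_regions + 1):
        if n_regions % nx or gx % nx:
            continue
        rem = n_regions // nx
        for ny in range(1, rem + 1):
            if rem % ny or gy % ny:
                continue
            nz = rem // ny
            if gz % nz:
                continue
            cand = (nx, ny, nz)
            # prefer near-cubic parcels
            score = np.ptp([gx / nx, gy / ny, gz / nz])
            if best is None or score < best[0]:
                best = (score, cand)
    if best is None:
        raise ValueError(
            f"cannot tile grid {grid_shape} into {n_regions} equal parcels"
        )
    return best[1]


def make_atlas(config: SimConfig) -> AtlasParcellation:
    """Rectangular tiling of the grid into n_regions parcels, labels 1..R."""
    nx, ny, nz = _tile_factors(config.grid_shape, config.n_regions)
    gx, gy, gz = config.grid_shape
    labels = np.zeros(config.grid_shape, dtype=np.int32)
    region = 1
    for ix, iy, iz in itertools.product(range(nx), range(ny), range(nz)):
        labels[ix * gx // nx:(ix + 1) * gx // nx,
               iy * gy // ny:(iy + 1) * gy // ny,
               iz * gz // nz:(iz + 1) * gz // nz] = region
        region += 1
    affine = np.diag([3.0, 3.0, 3.0, 1.0])  # 3 mm isotropic, MNI-style
    return AtlasParcellation(labels=labels, affine=affine)


def _markov_states(rng: np.random.Generator, T: int, n_states: int,
                   switch_rate: float, state_step: int) -> np.ndarray:
    """Per-TR state sequence; switch decisions happen every state_step TRs."""
    n_blocks = -(-T // state_step)
    blocks = np.empty(n_blocks, dtype=np.int64)
    blocks[0] = rng.integers(n_states)
    flips = rng.random(n_blocks - 1) < switch_rate
    jumps = rng.integers(1, n_states, size=max(n_blocks - 1, 1))
    for b in range(1, n_blocks):
        blocks[b] = (blocks[b - 1] + jumps[b - 1]) % n_states if flips[b - 1] \
            else blocks[b - 1]
    return np.repeat(blocks, state_step)[:T]


def generate_cohort(config: SimConfig
                    ) -> tuple[list[BoldSeries], AtlasParcellation, SubjectTable]:
    """Simulate the full two-group cohort.

    Returns one BoldSeries per subject (patients first), the parcellation and
    the subject table. Subject order matches the table rows.
    """
    atlas = make_atlas(config)
    rng = substream(config.seed, "bold")
    n_comm = min(config.n_communities, config.n_regions)
    # fixed block community per parcel (same in every state): two parcels of a
    # community correlate exactly when their latent states coincide, so the
    # switch rate directly controls how much windowed degree fluctuates. With
    # the default layout the affected parcels form exactly one community, so
    # a patient's whole affected community is stable together.
    community = np.arange(config.n_regions) * n_comm // config.n_regions
    parcel_of_voxel = atlas.labels[atlas.labels != 0] - 1
    mask = atlas.labels != 0
    affected = np.array(config.affected, dtype=np.int64) - 1

    subjects, rows = [], []
    demo = substream(config.seed, "demographics")
    for group, n in (("patient", config.n_per_group),
                     ("control", config.n_per_group)):
        for i in range(n):
            sid = f"sub-{group}-{i + 1:02d}"
            rates = np.full(config.n_regions, config.switch_rate_control)
            if group == "patient":
                rates[affected] = config.switch_rate_patient
            states = np.stack([
                _markov_states(rng, config.T, config.n_states, rates[p],
                               config.state_step)
                for p in range(config.n_regions)
            ])  # (R, T)
            latent = rng.standard_normal(
                (config.n_states, n_comm, config.T))
            shared = latent[states, community[:, None],
                            np.arange(config.T)]  # (R, T)
            noise = rng.standard_normal((mask.sum(), config.T))
            voxels = (config.coupling * shared[parcel_of_voxel]
                      + config.noise_sd * noise)
            data = np.zeros(config.grid_shape + (config.T,))
            data[mask] = voxels
            subjects.append(BoldSeries(data=data, affine=atlas.affine,
                                       tr=config.TR, subject_id=sid))
            age = demo.normal(55.0, 4.0)
            if config.confounded and group == "patient":
                age += 6.0
            rows.append({
                "subject_id": sid,
                "group": group,
                "age": round(float(age), 1),
                "sex": "M" if i % 2 == 0 else "F",
                "education": round(float(demo.normal(12.0, 2.3)), 1),
                "bcva": round(float(demo.normal(
                    0.65 if group == "patient" else 1.08, 0.14)), 2),
            })
    return subjects, atlas, SubjectTable(pd.DataFrame(rows))


@dataclasses.dataclass
class ExpressionSim:
    matrix: pd.DataFrame            # regions × genes
    planted_pos: list[str]
    planted_neg: list[str]


def generate_expression(atlas: AtlasParcellation, diff_map: np.ndarray,
                        config: ExpressionSimConfig) -> ExpressionSim:
    """Region × gene matrix with planted spatially-linked genes.

    Planted positive genes are built as ρ·z(d) + √(1−ρ²)·e with e residualised
    against d and standardised, so their empirical Pearson correlation with
    the difference map equals +link_strength exactly (up to float error);
    negative genes get −link_strength. The rest are spatially random.
    """
    region_ids = atlas.region_ids
    diff_map = np.asarray(diff_map, dtype=np.float64)
    if diff_map.shape[0] != len(region_ids):
        raise ValueError("diff_map must have one value per region")
    n_regions = len(region_ids)
    if n_regions < 3:
        raise ValueError("need at least 3 regions for a spatial correlation")
    rng = substream(config.seed, "expression")
    d = (diff_map - diff_map.mean()) / diff_map.std(ddof=1)
    rho = config.link_strength

    def linked(sign: float) -> np.ndarray:
        e = rng.standard_normal(n_regions)
        e = e - d * (e @ d) / (d @ d)            # orthogonal to d
        e = (e - e.mean()) / e.std(ddof=1)
        return sign * rho * d + np.sqrt(1 - rho ** 2) * e

    width = len(str(config.n_genes))
    names = [f"GENE{i + 1:0{width}d}" for i in range(config.n_genes)]
    cols = np.empty((n_regions, config.n_genes))
    n_pos, n_neg = config.n_linked_pos, config.n_linked_neg
    for j in range(n_pos):
        cols[:, j] = linked(+1.0)
    for j in range(n_pos, n_pos + n_neg):
        cols[:, j] = linked(-1.0)
    cols[:, n_pos + n_neg:] = rng.standard_normal(
        (n_regions, config.n_genes - n_pos - n_neg))
    matrix = pd.DataFrame(cols, index=pd.Index(region_ids, name="region_id"),
                          columns=names)
    return ExpressionSim(matrix=matrix,
                         planted_pos=names[:n_pos],
                         planted_neg=names[n_pos:n_pos + n_neg])


def generate_gene_sets(genes: list[str], n_sets: int,
                       planted_set_from: list[str], seed: int,
                       set_size: int = 20, planted_fraction: float = 0.8
                       ) -> dict[str, list[str]]:
    """Random gene sets plus one set drawn mostly from the planted genes.

    The planted set ('SET_PLANTED') takes ceil(planted_fraction·set_size)
    members from planted_set_from and fills up at random; the remaining
    n_sets−1 sets are uniform draws from the universe.
    """
    if set_size > len(genes):
        raise ValueError("set size exceeds gene universe")
    rng = substream(seed, "sets")
    n_from_planted = min(int(np.ceil(planted_fraction * set_size)),
                         len(planted_set_from))
    planted = list(rng.choice(planted_set_from, n_from_planted, replace=False))
    others = [g for g in genes if g not in set(planted)]
    planted += list(rng.choice(others, set_size - n_from_planted, replace=False))
    sets = {"SET_PLANTED": sorted(planted)}
    for k in range(n_sets - 1):
        sets[f"SET_RAND{k + 1:03d}"] = sorted(
            rng.choice(genes, set_size, replace=False))
    return sets


def generate_ppi_edges(genes: list[str], hub_genes: list[str],
                       base_degree: int = 2, hub_degree: int = 12,
                       confidence_range: tuple[float, float] = (0.4, 1.0),
                       seed: int = 0) -> pd.DataFrame:
    """STRING-style edge list with designated high-confidence hubs.

    Hubs get hub_degree partners at confidence in (0.9, 1.0); background
    edges have confidences spanning confidence_range (many of which fall
    below the 0.9 cutoff and are filtered out downstream). No self-loops.
    """
    rng = substream(seed, "ppi")
    hubs = set(hub_genes)
    if not hubs <= set(genes):
        raise ValueError("hub genes must be members of the gene universe")
    rows: dict[tuple[str, str], float] = {}

    def add(a: str, b: str, conf: float) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        rows[key] = max(rows.get(key, 0.0), conf)

    non_hubs = [g for g in genes if g not in hubs]
    for h in hub_genes:
        partners = rng.choice(non_hubs, size=min(hub_degree, len(non_hubs)),
                              replace=False)
        for p in partners:
            add(h, p, float(rng.uniform(0.905, 0.995)))
    lo, hi = confidence_range
    for g in non_hubs:
        partners = rng.choice(genes, size=base_degree, replace=False)
        for p in partners:
            add(g, p, float(rng.uniform(lo, hi)))
    table = pd.DataFrame(
        [(a, b, c) for (a, b), c in sorted(rows.items())],
        columns=["gene_a", "gene_b", "confidence"])
    return table


def generate_cell_profiles(genes: list[str], types: list[str],
                           n_samples_per_type: int,
                           specific_genes: dict[str, list[str]],
                           seed: int = 0, fold: float = 8.0
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Samples × genes expression profiles with type-specific gene modules.

    Genes in specific_genes[t] are expressed `fold` times higher in type t
    samples; all other expression is lognormal background noise.
    """
    rng = substream(seed, "profiles")
    index, labels = [], []
    for t in types:
        for i in range(n_samples_per_type):
            index.append(f"{t}_rep{i + 1}")
            labels.append(t)
    base = rng.lognormal(mean=1.0, sigma=0.25, size=(len(index), len(genes)))
    profiles = pd.DataFrame(base, index=index, columns=genes)
    for t, gene_list in specific_genes.items():
        rows = [i for i, lab in enumerate(labels) if lab == t]
        profiles.iloc[rows, [genes.index(g) for g in gene_list]] *= fold
    return profiles, pd.Series(labels, index=index, name="type")
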