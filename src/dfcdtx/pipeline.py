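"""End-to-end orchestration: synthetic demo bundle, staged run, manifest.

run_all executes dfcd → group contrast → PLS → {enrichment, specificity,
PPI} from a single YAML config, hashing every output into a manifest so a
rerun with the same config and seed is bit-reproducible. Volumes are written
as uncompressed .nii so file hashes are deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import csea as csea_mod
from . import enrichment as enr_mod
from . import ppi as ppi_mod
from . import synthetic_data as sim
from . import transcriptomics as tx
from .dfcd import FCDParams, dfcd_variability
from .group_stats import CorrectionParams, cluster_correct, fit_group_glm
from .imaging_io import (load_atlas, load_bold, load_subjects, save_atlas,
                         save_bold, save_subjects, write_map)


@dataclasses.dataclass
class PipelineConfig:
    bold_dir: str
    atlas: str
    subjects: str
    expression: str
    gene_sets: list[str]
    cell_profiles: str
    ppi_edges: str
    out_dir: str
    tr: float = 2.0
    fcd: FCDParams = dataclasses.field(default_factory=FCDParams)
    correction: CorrectionParams = dataclasses.field(
        default_factory=CorrectionParams)
    covariates: tuple[str, ...] = ("age", "sex")
    n_top: int = 20
    rank_by: str = "weight"
    n_boot: int = 0
    psi_n_perm: int = 1000
    psi_thresholds: tuple[float, ...] = csea_mod.DEFAULT_THRESHOLDS
    min_confidence: float = 0.9
    hub_fraction: float = 0.15
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        fcd = FCDParams(**raw.pop("fcd", {}))
        corr = CorrectionParams(**raw.pop("correction", {}))
        raw["covariates"] = tuple(raw.get("covariates", ("age", "sex")))
        raw["psi_thresholds"] = tuple(
            raw.get("psi_thresholds", csea_mod.DEFAULT_THRESHOLDS))
        return cls(fcd=fcd, correction=corr, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))

    def validate_inputs(self) -> None:
        missing = [p for p in
                   [self.bold_dir, self.atlas, self.subjects, self.expression,
                    self.cell_profiles, self.ppi_edges, *self.gene_sets]
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing pipeline inputs: {missing}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_demo(out_dir: str | Path, seed: int = 0,
              sim_config: sim.SimConfig | None = None,
              expr_config: sim.ExpressionSimConfig | None = None) -> Path:
    """Write a complete synthetic input bundle plus a ready-to-run config.

    Ground truth (affected parcels, planted genes, planted hubs, planted
    gene set) is recorded in ground_truth.json next to the data.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = sim_config or sim.SimConfig(seed=seed, n_per_group=8, T=150)
    cfg = dataclasses.replace(cfg, seed=seed)
    subjects, atlas, table = sim.generate_cohort(cfg)
    bold_dir = out / "bold"
    bold_dir.mkdir(exist_ok=True)
    for s in subjects:
        save_bold(s, bold_dir / f"{s.subject_id}.nii")
    save_atlas(atlas, out / "atlas.nii")
    save_subjects(table, out / "subjects.tsv")

    # expression planted against the affected-parcel indicator (the expected
    # spatial direction of the group contrast: affected parcels go negative)
    diff = np.zeros(len(atlas.region_ids))
    affected_idx = [i for i, rid in enumerate(atlas.region_ids)
                    if rid in cfg.affected]
    diff[affected_idx] = -1.0
    diff += 0.05 * np.random.default_rng(seed).standard_normal(diff.shape)
    ecfg = expr_config or sim.ExpressionSimConfig(
        n_genes=400, n_linked_pos=12, n_linked_neg=12, link_strength=0.7)
    ecfg = dataclasses.replace(ecfg, seed=seed)
    expr = sim.generate_expression(atlas, diff, ecfg)
    expr.matrix.to_csv(out / "expression.tsv", sep="\t")

    genes = list(expr.matrix.columns)
    sets = sim.generate_gene_sets(genes, n_sets=25,
                                  planted_set_from=expr.planted_pos
                                  + expr.planted_neg,
                                  seed=seed, set_size=15)
    coll = enr_mod.GeneSetCollection(
        sets={k: set(v) for k, v in sets.items()}, namespace="demo")
    enr_mod.write_gmt(coll, out / "gene_sets.gmt")

    types = ["neuron", "astrocyte", "microglia", "oligodendrocyte"]
    specific = {"neuron": expr.planted_pos[:8]}
    profiles, labels = sim.generate_cell_profiles(
        genes, types, n_samples_per_type=3, specific_genes=specific,
        seed=seed)
    prof = profiles.copy()
    prof.insert(0, "type", labels)
    prof.to_csv(out / "cell_profiles.tsv", sep="\t")

    hubs = expr.planted_pos[:3]
    edges = sim.generate_ppi_edges(genes, hubs, base_degree=2, hub_degree=10,
                                   seed=seed)
    edges.to_csv(out / "ppi_edges.tsv", sep="\t", index=False)

    (out / "ground_truth.json").write_text(json.dumps({
        "affected_region_ids": list(cfg.affected),
        "planted_pos": expr.planted_pos,
        "planted_neg": expr.planted_neg,
        "planted_set": "SET_PLANTED",
        "planted_hubs": hubs,
    }, indent=2))

    config = PipelineConfig(
        bold_dir=str(bold_dir), atlas=str(out / "atlas.nii"),
        subjects=str(out / "subjects.tsv"),
        expression=str(out / "expression.tsv"),
        gene_sets=[str(out / "gene_sets.gmt")],
        cell_profiles=str(out / "cell_profiles.tsv"),
        ppi_edges=str(out / "ppi_edges.tsv"),
        out_dir=str(out / "results"),
        tr=cfg.TR,
        # group inference runs on raw SD maps; z-normalisation is a display
        # convention (see docs/methods.md)
        fcd=FCDParams(normalize=False),
        correction=CorrectionParams(n_permutations=500, seed=seed),
        n_top=30, psi_n_perm=500, seed=seed,
    )
    config.to_yaml(out / "config.yaml")
    return out / "config.yaml"


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to out_dir)."""
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": config.seed,
                      "config": dataclasses.asdict(config)}

    def record(stage: str, paths: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in sorted(paths)},
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }

    # stage 1: per-subject dFCD maps
    t0 = time.perf_counter()
    atlas = load_atlas(config.atlas)
    subjects = load_subjects(config.subjects)
    maps = []
    map_dir = out / "dfcd_maps"
    map_dir.mkdir(exist_ok=True)
    written = []
    for sid in subjects.table["subject_id"]:
        bold = load_bold(Path(config.bold_dir) / f"{sid}.nii", tr=config.tr,
                         subject_id=sid)
        m = dfcd_variability(bold, atlas, config.fcd)
        maps.append(m)
        p = map_dir / f"{sid}_dfcd.nii"
        write_map(m.to_volume(), m.affine, p)
        written.append(p)
    record("dfcd", written, t0)

    # stage 2: group contrast + cluster correction
    t0 = time.perf_counter()
    tmap = fit_group_glm(maps, subjects, covariates=config.covariates)
    clusters = cluster_correct(tmap, config.correction, atlas=atlas)
    tmap_path = out / "group_t.nii"
    write_map(tmap.to_volume(), tmap.affine, tmap_path)
    cl_path = out / "clusters.tsv"
    clusters.to_csv(cl_path, sep="\t", index=False)
    record("group_stats", [tmap_path, cl_path], t0)

    # stage 3: PLS association + gene lists
    t0 = time.perf_counter()
    expr = pd.read_csv(config.expression, sep="\t", index_col=0)
    y = tx.parcel_mean(tmap, atlas)
    expr = expr.loc[y.index]
    result = tx.pls_association(y, expr)
    if config.n_boot >= 100:
        result.bootstrap_z = tx.bootstrap_weights(
            y, expr, n_boot=config.n_boot, seed=config.seed)
    ranking = tx.rank_genes(result, n_top=config.n_top, by=config.rank_by)
    w_path = out / "pls_weights.tsv"
    result.weights.to_csv(w_path, sep="\t")
    pos_path, neg_path = out / "pls_pos_genes.txt", out / "pls_neg_genes.txt"
    pos_path.write_text("\n".join(ranking.positive) + "\n")
    neg_path.write_text("\n".join(ranking.negative) + "\n")
    record("transcriptomics", [w_path, pos_path, neg_path], t0)

    background = list(expr.columns)

    # stage 4a: enrichment
    t0 = time.perf_counter()
    paths = []
    for gmt in config.gene_sets:
        coll = enr_mod.read_gmt(gmt, namespace=Path(gmt).stem)
        for label, gene_list in (("pos", ranking.positive),
                                 ("neg", ranking.negative)):
            table = enr_mod.enrich(gene_list, coll, background)
            p = out / f"enrichment_{Path(gmt).stem}_{label}.tsv"
            table.to_csv(p, sep="\t", index=False)
            paths.append(p)
    record("enrichment", paths, t0)

    # stage 4b: specificity
    t0 = time.perf_counter()
    prof = pd.read_csv(config.cell_profiles, sep="\t", index_col=0)
    labels = prof.pop("type")
    psi = csea_mod.compute_psi(prof, labels, n_perm=config.psi_n_perm,
                               seed=config.seed)
    paths = []
    for label, gene_list in (("pos", ranking.positive),
                             ("neg", ranking.negative)):
        table = csea_mod.specificity_enrichment(
            gene_list, psi, thresholds=config.psi_thresholds,
            background=background)
        p = out / f"specificity_{label}.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths.append(p)
    record("csea", paths, t0)

    # stage 4c: PPI
    t0 = time.perf_counter()
    edges = ppi_mod.read_edges(config.ppi_edges)
    paths = []
    for label, gene_list in (("pos", ranking.positive),
                             ("neg", ranking.negative)):
        net = ppi_mod.build_network(edges, gene_list,
                                    min_confidence=config.min_confidence)
        net_path = out / f"ppi_network_{label}.tsv"
        ppi_mod.write_network(net, net_path)
        hub_path = out / f"ppi_hubs_{label}.tsv"
        hubs = ppi_mod.hub_genes(net, top_fraction=config.hub_fraction)
        deg = ppi_mod.degree_table(net)
        deg[deg["gene"].isin(hubs)].to_csv(hub_path, sep="\t", index=False)
        paths += [net_path, hub_path]
    record("ppi", paths, t0)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
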