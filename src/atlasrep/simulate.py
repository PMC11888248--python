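"""Synthetic paired atlases with planted ground truth.

Two atlases share latent cell types but differ the way a whole-cell and a
single-nucleus protocol differ: atlas B sees a random subset of genes at
reduced (nuclear-retention) efficiency and at lower sequencing depth. Some
shared types may be represented by two perturbed subclusters in B (planted
fine splits), and each atlas may carry types the other lacks. Counts are
negative binomial (gamma-Poisson) around log-normal per-type expression
programs; each type owns a dissection region and a 3-D spatial field, and a
reduced-gene-panel spatial dataset can be derived from either atlas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._util import substream
from .data import ExpressionDataset

REGION_VOCAB = [f"R{i:02d}" for i in range(26)]


@dataclass
class GeneratorConfig:
    """Study conditions for the paired-atlas generator.

    Defaults: 40 shared types at 60 cells per type and 1,500 genes; atlas A
    sequenced at 5,000 counts/cell, atlas B at 2,500 with 30% of genes
    attenuated by a nuclear-retention factor drawn from ``retention_range``.
    """

    n_types: int = 40
    n_genes: int = 1500
    cells_per_type_a: tuple[int, int] = (60, 60)
    cells_per_type_b: tuple[int, int] = (60, 60)
    depth_a: float = 5000.0
    depth_b: float = 2500.0
    libsize_sigma: float = 0.3
    nb_dispersion: float = 0.5
    program_effect_sd: float = 1.2
    retention_range: tuple[float, float] = (0.2, 0.8)
    retention_frac: float = 0.3
    n_split_types: int = 0
    split_shift_sd: float = 0.25
    n_unique_a: int = 0
    n_unique_b: int = 0
    n_regions: int = 8
    n_slices: int = 5
    region_fidelity: float = 0.8
    spatial_sd: float = 0.25
    field_mm: float = 8.0
    markers_per_cluster: int = 4
    seed: int = 1

    def validate(self) -> None:
        if self.n_split_types > self.n_types:
            raise ValueError("more split types than shared types")
        if not (0 < self.retention_range[0] <= self.retention_range[1] <= 1):
            raise ValueError("retention_range must lie in (0, 1]")
        if self.n_regions > len(REGION_VOCAB):
            raise ValueError("n_regions exceeds region vocabulary")
        for lo, hi in (self.cells_per_type_a, self.cells_per_type_b):
            if not (1 <= lo <= hi):
                raise ValueError("cells-per-type range must satisfy 1 <= lo <= hi")


@dataclass
class TruthTable:
    """Planted correspondence between the two synthetic atlases."""

    shared_pairs: list[tuple[str, str]]
    split_map: dict[str, tuple[str, str]]
    unique_a: set[str] = field(default_factory=set)
    unique_b: set[str] = field(default_factory=set)
    type_region: dict[str, str] = field(default_factory=dict)
    type_center: dict[str, tuple[int, float, float]] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        rows = [("shared", a, b) for a, b in self.shared_pairs]
        rows += [("split", a, b) for a, (b1, b2) in self.split_map.items() for b in (b1, b2)]
        rows += [("unique_a", a, "") for a in sorted(self.unique_a)]
        rows += [("unique_b", "", b) for b in sorted(self.unique_b)]
        pd.DataFrame(rows, columns=["pair_type", "cluster_a", "cluster_b"]).to_csv(
            path, sep="\t", index=False
        )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _sample_atlas(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    programs: dict[str, np.ndarray],
    cluster_region: dict[str, str],
    cells_range: tuple[int, int],
    depth: float,
    retention: np.ndarray | None,
    dataset_id: str,
) -> ExpressionDataset:
    lo, hi = cells_range
    blocks, clusters, regions = [], [], []
    region_pool = REGION_VOCAB[: cfg.n_regions]
    for k in sorted(programs):
        mu_rel = programs[k]
        if retention is not None:
            mu_rel = mu_rel * retention
        n_cells = int(rng.integers(lo, hi + 1))
        libs = depth * rng.lognormal(-cfg.libsize_sigma**2 / 2, cfg.libsize_sigma, n_cells)
        mean = mu_rel[:, None] * libs[None, :]
        blocks.append(_nb_counts(rng, mean, cfg.nb_dispersion))
        clusters += [k] * n_cells
        keep = rng.random(n_cells) < cfg.region_fidelity
        reg = np.where(keep, cluster_region[k], rng.choice(region_pool, n_cells))
        regions += list(reg)
    counts = sp.csr_matrix(np.concatenate(blocks, axis=1))
    gene_ids = np.array([f"g{i:04d}" for i in range(cfg.n_genes)], dtype=object)
    cells = pd.DataFrame(
        {"cluster": clusters, "region": regions},
        index=pd.Index([f"{dataset_id}_c{i:05d}" for i in range(len(clusters))], name="cell_id"),
    )
    return ExpressionDataset(dataset_id, counts, gene_ids, cells)


def _markers(
    programs: dict[str, np.ndarray], siblings: dict[str, str], m: int, gene_ids: np.ndarray
) -> dict[str, list[str]]:
    """Top-m genes per cluster by fold change against all non-sibling clusters.

    Excluding the sibling makes planted split clusters share their markers —
    the regime in which a handful of markers cannot separate similar clusters.
    """
    keys = sorted(programs)
    mat = np.stack([programs[k] for k in keys])  # clusters x genes
    out = {}
    eps = 1e-12
    for i, k in enumerate(keys):
        rivals = [j for j, k2 in enumerate(keys) if k2 != k and siblings.get(k) != k2]
        rival_max = mat[rivals].max(axis=0)
        fc = mat[i] / (rival_max + eps)
        top = np.argsort(-fc, kind="stable")[:m]
        out[k] = [str(gene_ids[g]) for g in top]
    return out


def simulate_pair(cfg: GeneratorConfig):
    """Generate (atlas A, atlas B, TruthTable, markers A, markers B).

    Fully reproducible from ``cfg.seed``; independent named substreams drive
    expression programs, count sampling, and spatial placement.
    """
    cfg.validate()
    rng_prog = substream(cfg.seed, "programs")
    rng_a = substream(cfg.seed, "sampling_a")
    rng_b = substream(cfg.seed, "sampling_b")
    rng_sp = substream(cfg.seed, "spatial")

    g = cfg.n_genes
    baseline = rng_prog.lognormal(0.0, 1.0, g)

    def make_program(effect: np.ndarray) -> np.ndarray:
        mu = baseline * effect
        return mu / mu.sum()

    shared_names = [f"T{i:02d}" for i in range(cfg.n_types)]
    split_names = shared_names[: cfg.n_split_types]
    effects = {t: rng_prog.lognormal(0.0, cfg.program_effect_sd, g) for t in shared_names}
    uniq_a = [f"UA{i:02d}" for i in range(cfg.n_unique_a)]
    uniq_b = [f"UB{i:02d}" for i in range(cfg.n_unique_b)]
    for t in uniq_a + uniq_b:
        effects[t] = rng_prog.lognormal(0.0, cfg.program_effect_sd, g)

    # cluster naming: A keeps type names with an A prefix; B with a B prefix;
    # split types appear in B as two perturbed children.
    programs_a = {f"A_{t}": make_program(effects[t]) for t in shared_names + uniq_a}
    programs_b: dict[str, np.ndarray] = {}
    siblings_b: dict[str, str] = {}
    shared_pairs: list[tuple[str, str]] = []
    split_map: dict[str, tuple[str, str]] = {}
    for t in shared_names:
        if t in split_names:
            kids = (f"B_{t}x", f"B_{t}y")
            for kid in kids:
                shift = rng_prog.lognormal(0.0, cfg.split_shift_sd, g)
                programs_b[kid] = make_program(effects[t] * shift)
            siblings_b[kids[0]], siblings_b[kids[1]] = kids[1], kids[0]
            split_map[f"A_{t}"] = kids
        else:
            programs_b[f"B_{t}"] = make_program(effects[t])
            shared_pairs.append((f"A_{t}", f"B_{t}"))
    for t in uniq_b:
        programs_b[f"B_{t}"] = make_program(effects[t])

    # region and spatial assignment: one region + one 3-D center per latent
    # type, inherited by both sides (and by both split children).
    region_pool = REGION_VOCAB[: cfg.n_regions]
    type_region: dict[str, str] = {}
    type_center: dict[str, tuple[int, float, float]] = {}
    for t in shared_names + uniq_a + uniq_b:
        region = str(rng_sp.choice(region_pool))
        center = (int(rng_sp.integers(cfg.n_slices)),
                  float(rng_sp.uniform(0, cfg.field_mm)),
                  float(rng_sp.uniform(0, cfg.field_mm)))
        for name in (f"A_{t}", f"B_{t}", f"B_{t}x", f"B_{t}y"):
            type_region[name] = region
            type_center[name] = center
    cluster_region_a = {k: type_region[k] for k in programs_a}
    cluster_region_b = {k: type_region[k] for k in programs_b}

    retention = np.ones(g)
    attenuated = rng_prog.random(g) < cfg.retention_frac
    retention[attenuated] = rng_prog.uniform(*cfg.retention_range, int(attenuated.sum()))

    ds_a = _sample_atlas(cfg, rng_a, programs_a, cluster_region_a,
                         cfg.cells_per_type_a, cfg.depth_a, None, "atlasA")
    ds_b = _sample_atlas(cfg, rng_b, programs_b, cluster_region_b,
                         cfg.cells_per_type_b, cfg.depth_b, retention, "atlasB")

    truth = TruthTable(
        shared_pairs=shared_pairs,
        split_map=split_map,
        unique_a={f"A_{t}" for t in uniq_a},
        unique_b={f"B_{t}" for t in uniq_b},
        type_region={k: type_region[k] for k in list(programs_a) + list(programs_b)},
        type_center={k: type_center[k] for k in list(programs_a) + list(programs_b)},
    )
    gene_ids = ds_a.gene_ids
    cat_a = _markers(programs_a, {}, cfg.markers_per_cluster, gene_ids)
    eff_programs_b = {k: v * retention for k, v in programs_b.items()}
    cat_b = _markers(eff_programs_b, siblings_b, cfg.markers_per_cluster, gene_ids)
    return ds_a, ds_b, truth, cat_a, cat_b


def simulate_spatial_panel(
    ds: ExpressionDataset,
    truth: TruthTable,
    panel_size: int,
    noise_sd: float = 0.1,
    seed: int = 0,
    depth: float = 2000.0,
    spatial_sd: float = 0.25,
    slice_jitter: bool = True,
    cells_per_cluster: int | None = None,
) -> ExpressionDataset:
    """Reduced-gene-panel spatial dataset derived from one atlas.

    Each source cluster contributes cells scattered (Gaussian, ``spatial_sd``
    mm) around its planted center; expression is the cluster's empirical
    program restricted to a random gene panel, perturbed by multiplicative
    log-normal noise of scale ``noise_sd``, then NB-sampled at ``depth``.
    """
    if panel_size > ds.n_genes:
        raise ValueError("panel larger than the gene universe")
    rng = substream(seed, "spatial_panel")
    panel_idx = np.sort(rng.choice(ds.n_genes, size=panel_size, replace=False))
    gene_ids = ds.gene_ids[panel_idx]
    counts_dense = np.asarray(ds.counts.todense(), dtype=np.float64)
    labels = ds.cluster_of.to_numpy()
    blocks, clusters, slices, xs, ys, regions = [], [], [], [], [], []
    for k in sorted(pd.unique(labels)):
        mask = labels == k
        prog = counts_dense[:, mask].sum(axis=1)
        prog = prog / prog.sum()
        prog = prog[panel_idx]
        if prog.sum() == 0:
            continue
        prog = prog / prog.sum()
        n = int(mask.sum()) if cells_per_cluster is None else cells_per_cluster
        noisy = prog[:, None] * rng.lognormal(0.0, noise_sd, (panel_size, n)) if noise_sd > 0 else np.tile(prog[:, None], (1, n))
        noisy = noisy / noisy.sum(axis=0, keepdims=True)
        counts = _nb_counts(rng, noisy * depth, 0.0)
        blocks.append(counts)
        clusters += [k] * n
        sl, cx, cy = truth.type_center[k]
        slices += list(np.full(n, sl))
        xs += list(rng.normal(cx, spatial_sd, n))
        ys += list(rng.normal(cy, spatial_sd, n))
        regions += [truth.type_region[k]] * n
    cells = pd.DataFrame(
        {"cluster": clusters, "region": regions, "slice": slices, "x": xs, "y": ys},
        index=pd.Index([f"sp_c{i:05d}" for i in range(len(clusters))], name="cell_id"),
    )
    return ExpressionDataset(
        f"{ds.dataset_id}_panel{panel_size}", sp.csr_matrix(np.concatenate(blocks, axis=1)),
        gene_ids, cells,
    )


def simulate_noise_cells(
    template: ExpressionDataset, n_cells: int, seed: int = 0, depth: float = 2000.0
) -> ExpressionDataset:
    """Structureless control cells: a flat program over the template's genes."""
    rng = substream(seed, "noise_cells")
    g = template.n_genes
    prog = np.full(g, 1.0 / g)
    counts = _nb_counts(rng, np.tile(prog[:, None] * depth, (1, n_cells)), 0.0)
    cells = pd.DataFrame(
        {"cluster": ["noise"] * n_cells},
        index=pd.Index([f"nz_c{i:05d}" for i in range(n_cells)], name="cell_id"),
    )
    return ExpressionDataset("noise", sp.csr_matrix(counts), template.gene_ids, cells)


def degrade_to_null(ds: ExpressionDataset, seed: int = 0) -> ExpressionDataset:
    """Permute cluster labels uniformly across cells; expression untouched."""
    rng = substream(seed, "null_labels")
    cells = ds.cells.copy()
    cells["cluster"] = rng.permutation(cells["cluster"].to_numpy())
    return ExpressionDataset(f"{ds.dataset_id}_null", ds.counts, ds.gene_ids, cells)


def split_config(**overrides) -> GeneratorConfig:
    """The split-and-unique fixture: planted fine splits plus atlas-private types.

    Every shared type is represented by two sibling subclusters in atlas B,
    recreating the regime in which small marker panels separate clusters
    globally but not from their nearest sibling; each atlas also carries
    three private types with no counterpart.
    """
    base = GeneratorConfig(n_split_types=40, n_unique_a=3, n_unique_b=3)
    return replace(base, **overrides)
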