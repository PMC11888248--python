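"""End-to-end orchestration with a TOML config, manifest and resume support.

Stage order mirrors the analysis: simulate -> prepare -> match -> markers ->
map_cells -> coexpr -> enrich. Every stage writes TSV/JSON outputs plus a
manifest entry (parameter hash and output checksums); rerunning with the
same config reproduces all outputs byte-identically, and ``--resume`` skips
stages whose outputs are intact, recomputing everything downstream of the
first invalidated stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpr as cx
from . import markers as mk
from . import matching as mt
from . import spatial as spt
from ._util import substream
from .data import (
    HvgSet,
    normalize_log_cpm,
    read_dataset,
    select_hvgs,
    write_dataset,
)
from .simulate import GeneratorConfig, simulate_pair, simulate_spatial_panel
from .stats import adjust_p, hypergeom_overlap_test
from .voting import AurocTable

STAGES = ["simulate", "prepare", "match", "markers", "map_cells", "coexpr", "enrich"]
FLOAT_FMT = "%.10g"


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration (TOML on disk)."""

    out_dir: Path
    seed: int = 1
    simulate: dict = dataclasses.field(default_factory=dict)
    hvg: dict = dataclasses.field(default_factory=lambda: {"n_bins": 10, "quantile": 0.75})
    matching: dict = dataclasses.field(default_factory=lambda: {"alpha": 0.05})
    calling: dict = dataclasses.field(
        default_factory=lambda: {"n_rounds": 100, "subsample_frac": 0.8, "threshold": 0.5,
                                 "panel_size": 500, "noise_sd": 0.1}
    )
    coexpr: dict = dataclasses.field(
        default_factory=lambda: {"fractions": [0.1, 0.25, 0.5, 1.0], "n_rep": 20}
    )
    enrich: dict = dataclasses.field(default_factory=lambda: {"min_clusters": 2})

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        out_dir = Path(raw.pop("out_dir", "pipeline_out"))
        cfg = cls(out_dir=out_dir)
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict):
                getattr(cfg, key).update(val)
            else:
                setattr(cfg, key, val)
        return cfg

    def stage_params(self, stage: str) -> dict:
        base = {"seed": self.seed}
        base.update(getattr(self, stage, {}) if isinstance(getattr(self, stage, None), dict) else {})
        if stage in ("match",):
            base.update(self.matching)
            base.update(self.hvg)
        if stage == "prepare":
            base.update(self.hvg)
        if stage == "map_cells":
            base.update(self.calling)
        if stage == "simulate":
            base["panel_size"] = self.calling.get("panel_size", 500)
            base["noise_sd"] = self.calling.get("noise_sd", 0.1)
        return base


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()


class Manifest:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "manifest.json"
        self.out_dir = out_dir
        self.entries: dict = {}
        if self.path.exists():
            self.entries = json.loads(self.path.read_text())

    def record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.entries[stage] = {
            "params_hash": _params_hash(params),
            "outputs": {str(p.relative_to(self.out_dir)): _sha256(p) for p in outputs},
        }
        self.path.write_text(json.dumps(self.entries, indent=1, sort_keys=True))

    def is_valid(self, stage: str, params: dict) -> bool:
        entry = self.entries.get(stage)
        if entry is None or entry["params_hash"] != _params_hash(params):
            return False
        for rel, digest in entry["outputs"].items():
            p = self.out_dir / rel
            if not p.exists() or _sha256(p) != digest:
                return False
        return True


def class_enrichment(
    pairs: mt.ReciprocalPairTable, annotation: dict[str, str], min_clusters: int = 10
) -> pd.DataFrame:
    """Hypergeometric enrichment of reciprocal hits per cluster class.

    Classes smaller than ``min_clusters`` are dropped; p-values are
    BH-adjusted across the classes tested.
    """
    recip = set(pairs.reciprocal()["cluster_a"])
    all_clusters = list(pairs.table["cluster_a"])
    n_total = len(all_clusters)
    n_recip = len(recip & set(all_clusters))
    classes: dict[str, list[str]] = {}
    for c in all_clusters:
        classes.setdefault(annotation[c], []).append(c)
    rows = []
    for cls_name in sorted(classes):
        members = classes[cls_name]
        if len(members) < min_clusters:
            continue
        k = sum(1 for c in members if c in recip)
        res = hypergeom_overlap_test(k, len(members), n_recip, n_total)
        rows.append({"class": cls_name, "n_clusters": len(members),
                     "n_reciprocal": k, "p": res.p_value})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = adjust_p(df["p"].to_numpy(), "bh")
    return df


# -- stage implementations ----------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    gen_kwargs = dict(cfg.simulate)
    gen_kwargs.setdefault("seed", cfg.seed)
    for key in ("cells_per_type_a", "cells_per_type_b", "retention_range"):
        if key in gen_kwargs:
            gen_kwargs[key] = tuple(gen_kwargs[key])
    gcfg = GeneratorConfig(**gen_kwargs)
    ds_a, ds_b, truth, cat_a, cat_b = simulate_pair(gcfg)
    outputs = []
    for ds, name in ((ds_a, "data_a"), (ds_b, "data_b")):
        outputs += list(write_dataset(ds, out / name).values())
    truth.to_tsv(out / "truth.tsv")
    mk.MarkerCatalog(cat_a, "atlasA").to_tsv(out / "markers_a.tsv")
    mk.MarkerCatalog(cat_b, "atlasB").to_tsv(out / "markers_b.tsv")
    spatial = simulate_spatial_panel(
        ds_a, truth, panel_size=int(cfg.calling.get("panel_size", 500)),
        noise_sd=float(cfg.calling.get("noise_sd", 0.1)), seed=cfg.seed,
        spatial_sd=gcfg.spatial_sd,
    )
    outputs += list(write_dataset(spatial, out / "spatial").values())
    outputs += [out / "truth.tsv", out / "markers_a.tsv", out / "markers_b.tsv"]
    return outputs


def _load_datasets(out: Path):
    ds = {}
    for name in ("data_a", "data_b", "spatial"):
        d = out / "simulate" / name
        ds[name] = read_dataset(d / "matrix.mtx", d / "genes.tsv", d / "cells.tsv",
                                dataset_id=name)
    return ds


def _stage_prepare(cfg: RunConfig, out: Path) -> list[Path]:
    ds = _load_datasets(out.parent)
    nv_a = normalize_log_cpm(ds["data_a"])
    nv_b = normalize_log_cpm(ds["data_b"])
    hvg = select_hvgs([nv_a, nv_b], int(cfg.hvg["n_bins"]), float(cfg.hvg["quantile"]))
    hvg.to_tsv(out / "hvg.tsv")
    return [out / "hvg.tsv"]


def _stage_match(cfg: RunConfig, out: Path) -> list[Path]:
    ds = _load_datasets(out.parent)
    nv_a = normalize_log_cpm(ds["data_a"])
    nv_b = normalize_log_cpm(ds["data_b"])
    hvg = HvgSet.from_tsv(out.parent / "prepare" / "hvg.tsv")
    res = mt.match_datasets(nv_a, nv_b, hvg, alpha=float(cfg.matching["alpha"]))
    res.sym.values.to_csv(out / "sym_auroc.tsv", sep="\t", float_format=FLOAT_FMT)
    res.pairs.table.to_csv(out / "pairs.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    model_a = mt.build_pretrained(res.rnc_a)
    model_b = mt.build_pretrained(res.rnc_b)
    model_a.to_files(out / "model_a.tsv", out / "model_a.json")
    model_b.to_files(out / "model_b.tsv", out / "model_b.json")
    return [out / "sym_auroc.tsv", out / "pairs.tsv", out / "model_a.tsv",
            out / "model_a.json", out / "model_b.tsv", out / "model_b.json"]


def _stage_markers(cfg: RunConfig, out: Path) -> list[Path]:
    ds = _load_datasets(out.parent)
    cat_a = mk.MarkerCatalog.from_tsv(out.parent / "simulate" / "markers_a.tsv", "atlasA")
    cat_b = mk.MarkerCatalog.from_tsv(out.parent / "simulate" / "markers_b.tsv", "atlasB")
    nv_a = normalize_log_cpm(ds["data_a"])
    nv_b = normalize_log_cpm(ds["data_b"])
    out_paths = []
    summary = {}
    for nv, cat, tag in ((nv_a, cat_a, "a"), (nv_b, cat_b, "b")):
        matrix = mk.marker_auroc_matrix(nv, cat)
        matrix.values.to_csv(out / f"marker_auroc_{tag}.tsv", sep="\t", float_format=FLOAT_FMT)
        out_paths.append(out / f"marker_auroc_{tag}.tsv")
        on_target = matrix.on_target()
        local = {k: mk.marker_local_auroc(nv, cat, k, matrix) for k in on_target.index}
        summary[f"mean_global_auroc_{tag}"] = float(on_target.mean())
        summary[f"mean_local_auroc_{tag}"] = float(np.mean(list(local.values())))
    pairing = mk.marker_based_pairing(cat_a, nv_b)
    pairing.to_csv(out / "marker_pairs.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    (out / "marker_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return out_paths + [out / "marker_pairs.tsv", out / "marker_summary.json"]


def _stage_map_cells(cfg: RunConfig, out: Path) -> list[Path]:
    ds = _load_datasets(out.parent)
    from .data import compute_centroids

    nv_sp = normalize_log_cpm(ds["spatial"])
    pairs_df = pd.read_csv(out.parent / "match" / "pairs.tsv", sep="\t")
    pairs = mt.ReciprocalPairTable(pairs_df)
    calls = {}
    out_paths = []
    for name, tag in (("data_a", "a"), ("data_b", "b")):
        cent = compute_centroids(normalize_log_cpm(ds[name]))
        calls[tag] = spt.call_cells(
            nv_sp, cent, n_rounds=int(cfg.calling["n_rounds"]),
            subsample_frac=float(cfg.calling["subsample_frac"]),
            threshold=float(cfg.calling["threshold"]),
            seed=cfg.seed,
        )
        calls[tag].calls.to_csv(out / f"calls_{tag}.tsv", sep="\t", float_format=FLOAT_FMT)
        out_paths.append(out / f"calls_{tag}.tsv")
    flag, per_slice = spt.pair_concordance(calls["a"], calls["b"], pairs)
    per_slice.to_csv(out / "per_slice.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    dist = spt.paired_centroid_distance(
        calls["a"], calls["b"], list(zip(pairs.reciprocal()["cluster_a"],
                                         pairs.reciprocal()["cluster_b"])))
    dist.to_csv(out / "pair_distances.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    summary = {
        "n_cells": int(len(flag)),
        "prop_concordant": float(flag.mean()),
        "mean_pair_distance_mm": float(dist["distance_mm"].dropna().mean()),
    }
    (out / "spatial_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return out_paths + [out / "per_slice.tsv", out / "pair_distances.tsv",
                        out / "spatial_summary.json"]


def _stage_coexpr(cfg: RunConfig, out: Path) -> list[Path]:
    ds = _load_datasets(out.parent)
    nv_a = normalize_log_cpm(ds["data_a"])
    nv_b = normalize_log_cpm(ds["data_b"])
    hvg = HvgSet.from_tsv(out.parent / "prepare" / "hvg.tsv")
    pairs_df = pd.read_csv(out.parent / "match" / "pairs.tsv", sep="\t")
    recip = pairs_df[pairs_df["is_reciprocal"]]
    pair_list = list(zip(recip["cluster_a"], recip["cluster_b"]))
    mat_a, mat_b = cx.paired_centroid_matrices(nv_a, nv_b, pair_list, exclude=hvg)
    table = cx.coordinated_table(mat_a, mat_b, hvg)
    table.to_tsv(out / "coexpr.tsv")
    curves = cx.subsample_curves(
        mat_a, mat_b, tuple(cfg.coexpr["fractions"]), int(cfg.coexpr["n_rep"]), cfg.seed
    )
    curves.to_csv(out / "curves.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    # seeded synthetic gene-set collection over the scored genes
    rng = substream(cfg.seed, "gene_sets")
    scored = list(table.table.dropna(subset=["percentile"]).index)
    sets = {}
    for i in range(10):
        size = int(rng.integers(15, 60))
        sets[f"random_set_{i:02d}"] = set(rng.choice(scored, size=size, replace=False))
    ranked = table.table.loc[scored].sort_values("percentile", ascending=False)
    sets["top_coordinated"] = set(ranked.index[:30])
    with open(out / "synthetic_sets.gmt", "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, "synthetic"] + sorted(sets[name])) + "\n")
    summary = cx.gene_set_summary(table, sets)
    summary.to_csv(out / "gene_set_summary.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    return [out / "coexpr.tsv", out / "curves.tsv", out / "synthetic_sets.gmt",
            out / "gene_set_summary.tsv"]


def _stage_enrich(cfg: RunConfig, out: Path) -> list[Path]:
    pairs_df = pd.read_csv(out.parent / "match" / "pairs.tsv", sep="\t")
    pairs = mt.ReciprocalPairTable(pairs_df)
    truth = pd.read_csv(out.parent / "simulate" / "truth.tsv", sep="\t")
    ds = _load_datasets(out.parent)
    annotation = {
        k: str(ds["data_a"].cells[ds["data_a"].cells["cluster"] == k]["region"].mode().iloc[0])
        for k in pairs.table["cluster_a"]
    }
    df = class_enrichment(pairs, annotation, int(cfg.enrich["min_clusters"]))
    df.to_csv(out / "class_enrichment.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    return [out / "class_enrichment.tsv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "prepare": _stage_prepare,
    "match": _stage_match,
    "markers": _stage_markers,
    "map_cells": _stage_map_cells,
    "coexpr": _stage_coexpr,
    "enrich": _stage_enrich,
}


def run_pipeline(cfg: RunConfig, resume: bool = False, stages=None) -> dict:
    """Run the pipeline stages in order; returns the manifest entries.

    With ``resume=True`` a stage is skipped while its manifest entry is
    intact (same parameters, outputs present with matching checksums); the
    first invalidated stage forces every later stage to rerun.
    """
    out_root = Path(cfg.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out_root)
    invalidated = False
    todo = stages or STAGES
    for stage in todo:
        params = cfg.stage_params(stage)
        if resume and not invalidated and manifest.is_valid(stage, params):
            continue
        invalidated = True
        stage_dir = out_root / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        try:
            outputs = _STAGE_FUNCS[stage](cfg, stage_dir)
        except Exception as err:  # noqa: BLE001 - annotate and re-raise with stage name
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        manifest.record(stage, params, outputs)
    return manifest.entries
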