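"""End-to-end pipeline: simulate -> filter -> alignments -> trees -> metrics -> fit.

A single YAML config drives a reproducible run. Each stage writes into its
own subdirectory of the run directory and records a content hash in the run
manifest; a rerun with the same config skips stages whose outputs already
exist with matching hashes, and a completed run directory plus its manifest
reproduce the outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agemodel import GRID_ALPHA, GRID_LAMBDA, CellTreeAge
from .alignment import encode_alignment, read_fasta, subsample_pseudoreplicates, write_fasta
from .features import FEATURE_NAMES, features_table
from .simulate import SimConfig, simulate_cohort
from .trees import infer_sample_trees, read_newick, write_newick
from .variants import filter_variants, load_call_matrix, load_germline_vcf

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "alignments", "trees", "metrics", "fit")


class PipelineConfigError(ValueError):
    """Raised for unknown or inconsistent pipeline configuration keys."""


@dataclass
class PipelineConfig:
    """Every stage parameter of a pipeline run, round-trippable to YAML."""

    seed: int = 0
    out_dir: str = "ctr_run"
    #: pre-existing cohort directory (sample subdirs + metadata.csv); when
    #: None the simulate stage generates one.
    input_dir: str | None = None
    germline_vcf: str | None = None
    min_umis: int = 8
    min_barcodes: int = 4
    n_reps: int = 5
    cells_per_rep: int = 700
    lambda_grid: list = field(default_factory=lambda: list(GRID_LAMBDA))
    alpha_grid: list = field(default_factory=lambda: list(GRID_ALPHA))
    standardize: bool = True
    preselect_k: list | None = None
    dummy: bool = True
    simulate: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if isinstance(self.simulate, dict):
            known = {f.name for f in dataclasses.fields(SimConfig)}
            unknown = set(self.simulate) - known
            if unknown:
                raise PipelineConfigError(f"unknown simulate keys: {sorted(unknown)}")
            self.simulate = SimConfig(**self.simulate)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"]["age_range"] = list(d["simulate"]["age_range"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _hash_tree_of_files(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()[:16]


def discover_samples(cohort_dir) -> list:
    """Sample subdirectories holding alt.mtx/ref.mtx/barcodes.tsv/variants.csv."""
    root = Path(cohort_dir)
    out = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        if (sub / "alt.mtx").exists():
            out.append((sub.name, sub))
    return out


class PipelineRun:
    """Executes the staged pipeline inside a run directory."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"version": __version__, "stages": {}}
        self.manifest["config"] = cfg.to_dict()
        self.manifest["config_hash"] = _hash_obj(cfg.to_dict())
        self.manifest["seed"] = cfg.seed

    def _save_manifest(self):
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, default=str))

    def _stage(self, name: str, input_hash: str, outputs: list, fn) -> str:
        """Run ``fn`` unless recorded hash matches and outputs exist."""
        rec = self.manifest["stages"].get(name)
        if rec and rec.get("hash") == input_hash and all(Path(o).exists() for o in outputs):
            logger.info("stage %s: up to date, skipped", name)
            return input_hash
        t0 = time.time()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name} failed: {exc}") from exc
        self.manifest["stages"][name] = {
            "hash": input_hash,
            "runtime_s": round(time.time() - t0, 3),
            "outputs": [str(o) for o in outputs],
        }
        self._save_manifest()
        return input_hash

    def run(self) -> Path:
        cfg = self.cfg

        # ---- stage 1: cohort (simulate or external input) --------------
        cohort_dir = self.out / "cohort"
        if cfg.input_dir is None:
            sim_hash = _hash_obj({"sim": dataclasses.asdict(cfg.simulate)})
            self._stage("simulate", sim_hash, [cohort_dir / "metadata.csv"],
                        lambda: simulate_cohort(cfg.simulate, out_dir=cohort_dir))
            upstream = sim_hash
        else:
            cohort_dir = Path(cfg.input_dir)
            upstream = _hash_tree_of_files(cohort_dir)
            self.manifest["stages"]["simulate"] = {"hash": upstream, "external": str(cohort_dir)}
        samples = discover_samples(cohort_dir)
        metadata = pd.read_csv(cohort_dir / "metadata.csv")

        # ---- stage 2: filter -------------------------------------------
        filt_dir = self.out / "filtered"
        filt_hash = _hash_obj({"up": upstream, "germ": cfg.germline_vcf,
                               "min_umis": cfg.min_umis, "min_barcodes": cfg.min_barcodes})

        def do_filter():
            germ = (load_germline_vcf(cfg.germline_vcf)
                    if cfg.germline_vcf else None)
            for sid, sdir in samples:
                try:
                    m = load_call_matrix(sdir / "alt.mtx", sdir / "ref.mtx",
                                         sdir / "barcodes.tsv", sdir / "variants.csv")
                    f = filter_variants(m, germ, cfg.min_umis, cfg.min_barcodes)
                    f.write(filt_dir / sid)
                except Exception as exc:
                    raise RuntimeError(f"sample {sid}: {exc}") from exc

        self._stage("filter", filt_hash,
                    [filt_dir / sid / "alt.mtx" for sid, _ in samples], do_filter)

        # ---- stage 3: alignments ---------------------------------------
        aln_dir = self.out / "alignments"
        aln_hash = _hash_obj({"up": filt_hash, "n_reps": cfg.n_reps,
                              "cells_per_rep": cfg.cells_per_rep, "seed": cfg.seed,
                              "min_umis": cfg.min_umis})

        def do_alignments():
            for k, (sid, _) in enumerate(samples):
                try:
                    m = load_call_matrix(filt_dir / sid / "alt.mtx", filt_dir / sid / "ref.mtx",
                                         filt_dir / sid / "barcodes.tsv",
                                         filt_dir / sid / "variants.csv")
                    a = encode_alignment(m, min_umis=cfg.min_umis, sample_id=sid)
                    seed = np.random.SeedSequence(cfg.seed, spawn_key=(3, k))
                    reps = subsample_pseudoreplicates(a, cfg.n_reps, cfg.cells_per_rep, seed)
                    (aln_dir / sid).mkdir(parents=True, exist_ok=True)
                    for r, rep in enumerate(reps):
                        write_fasta(rep, aln_dir / sid / f"rep{r}.fasta")
                except Exception as exc:
                    raise RuntimeError(f"sample {sid}: {exc}") from exc

        self._stage("alignments", aln_hash,
                    [aln_dir / sid / f"rep{r}.fasta" for sid, _ in samples
                     for r in range(cfg.n_reps)], do_alignments)

        # ---- stage 4: trees --------------------------------------------
        tree_dir = self.out / "trees"
        tree_hash = _hash_obj({"up": aln_hash})

        def do_trees():
            for sid, _ in samples:
                try:
                    alns = [read_fasta(aln_dir / sid / f"rep{r}.fasta")
                            for r in range(cfg.n_reps)]
                    trees = infer_sample_trees(alns)
                    (tree_dir / sid).mkdir(parents=True, exist_ok=True)
                    for r, t in enumerate(trees):
                        write_newick(t, tree_dir / sid / f"rep{r}.nwk")
                except Exception as exc:
                    raise RuntimeError(f"sample {sid}: {exc}") from exc

        self._stage("trees", tree_hash,
                    [tree_dir / sid / f"rep{r}.nwk" for sid, _ in samples
                     for r in range(cfg.n_reps)], do_trees)

        # ---- stage 5: metrics ------------------------------------------
        features_path = self.out / "features.csv"
        feat_hash = _hash_obj({"up": tree_hash, "metrics": FEATURE_NAMES})

        def do_metrics():
            trees, sids, rids = [], [], []
            for sid, _ in samples:
                for r in range(cfg.n_reps):
                    trees.append(read_newick(tree_dir / sid / f"rep{r}.nwk"))
                    sids.append(sid)
                    rids.append(r)
            features_table(trees, sids, rids).to_csv(features_path, index=False)

        self._stage("metrics", feat_hash, [features_path], do_metrics)

        # ---- stage 6: fit ----------------------------------------------
        fit_hash = _hash_obj({"up": feat_hash, "lambda": cfg.lambda_grid,
                              "alpha": cfg.alpha_grid, "standardize": cfg.standardize,
                              "preselect": cfg.preselect_k, "dummy": cfg.dummy})
        pred_path = self.out / "predictions.csv"
        perf_path = self.out / "performance.json"
        coef_path = self.out / "coefficients.csv"
        model_path = self.out / "model.json"

        def do_fit():
            feats = pd.read_csv(features_path)
            model = CellTreeAge.from_features(feats, metadata, standardize=cfg.standardize)
            res = model.fit(tuple(cfg.lambda_grid), tuple(cfg.alpha_grid))
            res.predictions.to_csv(pred_path, index=False)
            res.coefficients.to_csv(coef_path, index=False)
            perf = {"nested_cv": res.performance.as_dict()}
            if cfg.dummy:
                perf["dummy"] = model.fit_dummy().performance.as_dict()
            if cfg.preselect_k:
                pre = model.fit_preselected(list(cfg.preselect_k),
                                            tuple(cfg.lambda_grid), tuple(cfg.alpha_grid))
                perf["preselect"] = {str(k): r.performance.as_dict()
                                     for k, r in pre.per_k.items()}
                perf["preselect_best_k"] = pre.best_k
                perf["preselect_ranking"] = pre.ranking
            model.fit_final(tuple(cfg.lambda_grid), tuple(cfg.alpha_grid)).to_json(model_path)
            perf_path.write_text(json.dumps(perf, indent=1))

        self._stage("fit", fit_hash, [pred_path, perf_path, coef_path, model_path], do_fit)
        self._save_manifest()
        return self.out


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage of the pipeline; returns the run directory."""
    return PipelineRun(cfg).run()
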