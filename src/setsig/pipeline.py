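"""Configuration-driven end-to-end experiment runs.

A run executes preprocess → set features → internal/external validation →
stability → concordance → category enrichment (→ subtyping when modules are
given) on a directory of cohorts or on synthetic data, writing every stage's
output as TSV/JSON plus a manifest.  Stages communicate only through
serialized files, so a run can be inspected or restarted stage by stage.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io, enrichment, set_statistics, stability, subtyping, validation
from .centroid import fit_centroid
from .synthetic import SyntheticSpec, generate_datasets


@dataclass
class RunConfig:
    out_dir: str = "setsig_run"
    # inputs: either a directory of cohorts or a synthetic spec
    expr_dir: str | None = None  # expects <name>.tsv + <name>.labels.tsv pairs
    gmt: str | None = None
    gmt_category: str = "other"
    annotation: str | None = None
    modules: str | None = None  # optional (module, symbol, sign) TSV for subtyping
    simulate: dict | None = None  # SyntheticSpec fields; used when expr_dir is None
    # preprocessing
    qc_prefix: str = "AFFX"
    var_eps: float = 1e-8
    max_missing_frac: float = 0.15
    normalization: str = "none"
    min_set_size: int = 1
    # analysis
    statistics: list[str] = field(default_factory=lambda: ["centroid", "raw"])
    B: int = 25
    train_frac: float = 2.0 / 3.0
    feature_grid: list[int] | None = None
    bootstrap_reps: int = 500
    overlap_cutoffs: list[int] = field(default_factory=lambda: list(range(1, 201)))
    overlap_k: int | None = None  # default: all datasets
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for stat in self.statistics:
            if stat not in set_statistics.STATISTICS:
                raise ValueError(f"unknown statistic {stat!r}")
        if self.expr_dir is None and self.simulate is None:
            raise ValueError("either expr_dir or simulate must be given")
        for key in ("expr_dir", "gmt", "annotation", "modules"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise ValueError(f"{key} path does not exist: {val}")


def _load_inputs(config: RunConfig):
    if config.expr_dir is not None:
        datasets = []
        for expr in sorted(Path(config.expr_dir).glob("*.tsv")):
            if expr.name.endswith(".labels.tsv"):
                continue
            labels = expr.with_suffix("").with_suffix(".labels.tsv")
            datasets.append(data_io.read_expression_table(
                expr, labels if labels.exists() else None))
        if not datasets:
            raise ValueError(f"no expression tables in {config.expr_dir}")
        if config.gmt is None:
            raise ValueError("gmt is required with expr_dir input")
        coll = data_io.read_gmt(config.gmt, category=config.gmt_category)
        truth = None
    else:
        spec = SyntheticSpec(**{**(config.simulate or {}), "seed": config.seed})
        from .synthetic import generate_collection
        rng = np.random.default_rng(spec.seed)
        coll, informative = generate_collection(spec, rng)
        datasets, truth = generate_datasets(spec, coll, informative)
    return datasets, coll, truth


def run_experiment(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    On a stage failure, partial outputs are kept, a FAILED marker naming the
    stage is written, and the exception is re-raised.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "config": asdict(config)}
    stage = "load"
    try:
        datasets, coll, truth = _load_inputs(config)
        manifest["datasets"] = [ds.name for ds in datasets]

        stage = "preprocess"
        clean = []
        for ds in datasets:
            c, log = data_io.preprocess(
                ds, qc_prefix=config.qc_prefix, var_eps=config.var_eps,
                max_missing_frac=config.max_missing_frac,
                normalization=config.normalization)
            clean.append(c)
            if log:
                pd.Series(log).to_csv(out / f"{ds.name}.removed.tsv", sep="\t",
                                      header=False)
        clean = validation.align_datasets(clean)
        manifest["stages"].append("preprocess")

        stage = "features"
        annotation = (data_io.read_annotation(config.annotation)
                      if config.annotation else None)
        feats: dict[str, list] = {}
        for stat in config.statistics:
            feats[stat] = []
            for ds in clean:
                if stat == "raw":
                    fm = set_statistics.compute_set_features(ds, None, "raw")
                else:
                    mapped, _ = data_io.map_collection(
                        coll, ds, annotation=annotation,
                        min_set_size=max(config.min_set_size, 2))
                    fm = set_statistics.compute_set_features(ds, mapped, stat)
                feats[stat].append(fm)
                pd.DataFrame(fm.values, index=fm.set_names,
                             columns=fm.sample_ids).to_csv(
                    out / f"{ds.name}.{stat}.features.tsv", sep="\t")
        manifest["stages"].append("features")

        plan = validation.SplitPlan(B=config.B, train_frac=config.train_frac,
                                    seed=config.seed)

        stage = "internal_validation"
        for stat in config.statistics:
            for ds, fm in zip(clean, feats[stat]):
                rep = validation.internal_validation(
                    fm.values, ds.labels, plan,
                    feature_grid=config.feature_grid, name=ds.name)
                rep.table.to_csv(out / f"{ds.name}.{stat}.internal.tsv",
                                 sep="\t", index=False)
        manifest["stages"].append("internal_validation")

        stage = "external_validation"
        ext_tables = {}
        if len(clean) >= 2:
            for stat in config.statistics:
                triples = [(ds.name, fm.values, ds.labels)
                           for ds, fm in zip(clean, feats[stat])]
                rep = validation.external_validation(
                    triples, plan, feature_grid=config.feature_grid)
                rep.table.to_csv(out / f"external.{stat}.tsv", sep="\t", index=False)
                ext_tables[stat] = rep.table
            manifest["stages"].append("external_validation")

        stage = "stability"
        conc = {}
        for stat in config.statistics:
            fm0 = feats[stat][0]
            rs = stability.bootstrap_feature_ranks(
                fm0.values, clean[0].labels, n_reps=config.bootstrap_reps,
                seed=config.seed, feature_names=fm0.set_names)
            rs.as_frame().to_csv(out / f"{clean[0].name}.{stat}.bootstrap.tsv",
                                 sep="\t", index=False)
            if len(clean) >= 2:
                models = [fit_centroid(fm.values, ds.labels,
                                       feature_names=fm.set_names, statistic=stat)
                          for ds, fm in zip(clean, feats[stat])]
                names = [ds.name for ds in clean]
                rho = stability.spearman_weight_concordance(models, names=names)
                rho.to_csv(out / f"concordance.{stat}.tsv", sep="\t", index=False)
                lists = [stability.ranked_feature_list(fm.values, ds.labels,
                                                       fm.set_names)
                         for ds, fm in zip(clean, feats[stat])]
                k = config.overlap_k or len(clean)
                ov = stability.list_overlap_counts(lists, config.overlap_cutoffs, k)
                ov.to_csv(out / f"overlap.{stat}.tsv", sep="\t", index=False)
                conc[stat] = {"mean_rho": float(rho["rho"].mean())}
        manifest["stages"].append("stability")
        manifest["concordance"] = conc

        stage = "enrichment"
        if any(s != "raw" for s in config.statistics):
            stat = next(s for s in config.statistics if s != "raw")
            fm0 = feats[stat][0]
            mapped, _ = data_io.map_collection(coll, clean[0], annotation=annotation,
                                               min_set_size=2)
            cat_of = {s.name: s.category for s in mapped.sets}
            lists = [stability.ranked_feature_list(fm.values, ds.labels, fm.set_names)
                     for ds, fm in zip(clean, feats[stat])]
            consensus = stability.consensus_rank(lists)
            cats = [cat_of.get(name, "other") for name in consensus]
            results = {}
            for cat in sorted(set(cats)):
                if 0 < cats.count(cat) < len(cats):
                    ks = enrichment.ks_category_enrichment(cats, cat)
                    results[cat] = {"D": ks.d, "p": ks.p_value}
            (out / "enrichment.json").write_text(json.dumps(results, indent=2))
            manifest["stages"].append("enrichment")

        stage = "subtyping"
        if config.modules is not None:
            mods = {m.name: m for m in subtyping.read_modules(config.modules)}
            if "ER" in mods and "HER2" in mods:
                assign = subtyping.subtype_samples(
                    clean[0], mods["ER"], mods["HER2"],
                    annotation=annotation, seed=config.seed)
                assign.as_frame().to_csv(out / f"{clean[0].name}.subtypes.tsv",
                                         sep="\t", index=False)
                manifest["stages"].append("subtyping")

        manifest["status"] = "completed"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n\n{traceback.format_exc()}")
        manifest["status"] = f"failed at {stage}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
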