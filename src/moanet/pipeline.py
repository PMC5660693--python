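"""End-to-end workflow: preprocess -> MOA-ANOVA gate -> class split ->
reference-class network -> preservation in the test class -> enrichment.

Each stage writes its outputs under the configured directory with stable
names, so any stage can be re-run standalone from the intermediates; a run
manifest records the config, seeds, output hashes and timings. The whole run
is a pure function of (inputs, config, seed).
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

from . import __version__, io, moa_stats, preprocess, simulate
from .enrichment import ora, read_gmt
from .network import build_network
from .preservation import (
    PermutationScheme,
    classify_preserved,
    reports_to_frame,
    reports_to_json,
    zsummary,
)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "split_by_class",
    "PipelineError",
    "demo_config",
]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Either ``expression_path``/``annotation_path`` point at TSV inputs, or a
    synthetic study is generated from the ``synthetic`` block (passed through
    to :func:`moanet.simulate.generate_study`; ``modules`` entries are
    ModuleSpec fields).
    """

    out_dir: str = "moanet_out"
    seed: int = 0
    expression_path: str | None = None
    annotation_path: str | None = None
    probe_map_path: str | None = None
    gene_sets_path: str | None = None
    synthetic: dict = field(default_factory=dict)
    beta: float = 10.0
    anova_fdr: float = 0.01
    pvac_threshold: float = 0.5
    min_module_size: int = 30
    cut_height_fraction: float = 0.99
    n_permutations: int = 200
    z_threshold: float = 10.0
    moa_class_map: dict = field(default_factory=lambda: dict(simulate.DEFAULT_MOA_CLASS_MAP))
    reference_class: str = "RM"
    network_columns: str = "replicates"  # or "chemicals"
    enrichment_fdr: float = 0.10

    def __post_init__(self):
        if not 0 < self.anova_fdr < 1:
            raise ValueError("anova_fdr must lie in (0, 1)")
        if not 0 < self.pvac_threshold <= 1:
            raise ValueError("pvac_threshold must lie in (0, 1]")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.network_columns not in ("replicates", "chemicals"):
            raise ValueError("network_columns must be 'replicates' or 'chemicals'")
        for moa, cls in self.moa_class_map.items():
            if cls not in ("RM", "NRM"):
                raise ValueError(f"MOA {moa!r} mapped to unknown class {cls!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    outputs: dict = field(default_factory=dict)   # name -> sha256
    timings: dict = field(default_factory=dict)   # stage -> seconds

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True, default=str)


def demo_config(out_dir: str = "moanet_demo", seed: int = 3, n_permutations: int = 200) -> PipelineConfig:
    """Demonstration study: 2,000 genes, four planted modules of which three
    are preserved between the classes and one decoheres in the NRM samples,
    on a gated background of moderately MOA-responsive genes (a quarter of
    the genome at 0.8x-noise effects, so the significant-gene universe mixes
    modular and non-modular genes roughly as real studies do).
    """
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        cut_height_fraction=0.98,
        n_permutations=n_permutations,
        synthetic=dict(
            n_genes=2000,
            noise_sd=1.0,
            moa_affected_fraction=0.25,
            moa_effect_sd=0.8,
            moa_factor_sd=1.0,
            chem_factor_sd=1.0,
            sample_factor_sd=0.5,
            modules=[
                dict(module_id="M1", size=150, eigengene_loading_range=(0.75, 0.95)),
                dict(module_id="M2", size=120, eigengene_loading_range=(0.75, 0.95)),
                dict(module_id="M3", size=90, eigengene_loading_range=(0.75, 0.95)),
                dict(
                    module_id="M4",
                    size=60,
                    eigengene_loading_range=(0.75, 0.95),
                    preserved_in_test=False,
                ),
            ],
        ),
    )


def split_by_class(data: pd.DataFrame, class_of) -> tuple:
    """Split columns into (RM, NRM) by each column's class, preserving order.

    ``class_of`` maps column id -> "RM"/"NRM"; an unclassed column or an
    empty class is an error.
    """
    class_of = pd.Series(class_of)
    missing = [c for c in data.columns if c not in class_of.index]
    if missing:
        raise ValueError(f"columns without class assignment: {missing[:5]}")
    cls = class_of.loc[[c for c in data.columns]]
    bad = set(cls) - {"RM", "NRM"}
    if bad:
        raise ValueError(f"unknown classes: {sorted(bad)}")
    rm = data.loc[:, (cls == "RM").to_numpy()]
    nrm = data.loc[:, (cls == "NRM").to_numpy()]
    if rm.shape[1] == 0 or nrm.shape[1] == 0:
        raise ValueError("one of the classes has no columns")
    return rm, nrm


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_module_specs(entries) -> list:
    return [simulate.ModuleSpec(**e) for e in entries]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed, version=__version__)
    t_all = time.time()

    def _checkpoint(stage, t0):
        manifest.timings[stage] = round(time.time() - t0, 3)

    # ------------------------------------------------------------------ input
    t0 = time.time()
    stage = "input"
    try:
        if config.expression_path:
            expr = io.read_expression(config.expression_path)
            annot = io.read_annotation(config.annotation_path)
            truth = None
        else:
            syn = dict(config.synthetic)
            design_kwargs = syn.pop("design", {})
            modules = _build_module_specs(syn.pop("modules", []))
            syn.setdefault("seed", config.seed)
            design = simulate.StudyDesign(**design_kwargs)
            expr, annot, truth = simulate.generate_study(design, modules, **syn)
            io.write_expression(expr, out / "expression.tsv")
            io.write_annotation(annot, out / "annotation.tsv")
            truth.to_json(out / "truth.json")
    except (OSError, ValueError, KeyError) as exc:
        raise PipelineError(stage, "input_error", str(exc)) from exc
    _checkpoint(stage, t0)

    # ------------------------------------------------------------- preprocess
    t0 = time.time()
    stage = "preprocess"
    try:
        if config.probe_map_path:
            probe_map = pd.read_csv(config.probe_map_path, sep="\t", index_col=0).iloc[:, 0]
            scores, expr = preprocess.pvac_filter(expr, probe_map, config.pvac_threshold)
            scores.to_csv(out / "pvac_scores.tsv", sep="\t", index=False)
        centered = preprocess.mean_center_by_batch(expr, annot["route"])
        ratios = preprocess.to_log_ratios(centered, annot)
        chem_avg = preprocess.average_by_chemical(ratios, annot)
        io.write_expression(ratios.data, out / "log_ratios.tsv")
        io.write_expression(chem_avg, out / "chemical_averages.tsv")
    except (preprocess.AnnotationError, ValueError) as exc:
        raise PipelineError(stage, "preprocess_error", str(exc)) from exc
    _checkpoint(stage, t0)

    # ----------------------------------------------------------- gene gating
    t0 = time.time()
    stage = "select-genes"
    try:
        anova = moa_stats.fit_moa_anova(ratios, annot, fdr_threshold=config.anova_fdr)
        anova.table.to_csv(out / "anova_results.tsv", sep="\t", index=False)
        sig = anova.significant_genes()
        (out / "significant_genes.txt").write_text("\n".join(sig) + ("\n" if sig else ""))
        log.info("MOA-ANOVA gate: %d / %d genes at FDR < %g", len(sig), len(anova.table), config.anova_fdr)
        if len(sig) < 3 * config.min_module_size:
            log.warning("few significant genes (%d); networks may be degenerate", len(sig))
    except ValueError as exc:
        raise PipelineError(stage, "anova_error", str(exc)) from exc
    _checkpoint(stage, t0)

    # ------------------------------------------------- diagnostics / class DE
    t0 = time.time()
    stage = "diagnostics"
    try:
        sig_ratios = ratios.data.loc[sig]
        chem_class = {
            chem: config.moa_class_map[moa]
            for chem, moa in annot.loc[annot["role"] == "treated", ["chemical", "moa"]]
            .drop_duplicates()
            .itertuples(index=False)
        }
        diff = moa_stats.class_differential(chem_avg.loc[sig], chem_class)
        diff.to_csv(out / "class_differential.tsv", sep="\t", index=False)
        scores, frac = moa_stats.sample_pca(sig_ratios)
        scores.iloc[:, :2].assign(
            pc1_frac=frac[0], pc2_frac=frac[1] if len(frac) > 1 else 0.0
        ).to_csv(out / "pca_scores.tsv", sep="\t")
        Zlink, labels = moa_stats.sample_cluster(sig_ratios)
        (out / "sample_dendrogram.nwk").write_text(io.linkage_to_newick(Zlink, labels) + "\n")
    except (KeyError, ValueError) as exc:
        raise PipelineError(stage, "diagnostics_error", str(exc)) from exc
    _checkpoint(stage, t0)

    # -------------------------------------------------------------- networks
    t0 = time.time()
    stage = "network"
    try:
        if config.network_columns == "chemicals":
            net_data = chem_avg.loc[sig]
            col_class = chem_class
        else:
            net_data = sig_ratios
            col_class = {
                s: config.moa_class_map[annot.at[s, "moa"]] for s in sig_ratios.columns
            }
        rm_data, nrm_data = split_by_class(net_data, col_class)
        ref_data, test_data = (
            (rm_data, nrm_data) if config.reference_class == "RM" else (nrm_data, rm_data)
        )
        keep = ref_data.index[(ref_data.std(axis=1) > 0) & (test_data.std(axis=1) > 0)]
        ref_data, test_data = ref_data.loc[keep], test_data.loc[keep]
        model = build_network(
            ref_data,
            beta=config.beta,
            min_module_size=config.min_module_size,
            cut_height_fraction=config.cut_height_fraction,
        )
        model.assignment.to_frame().to_csv(out / "modules.tsv", sep="\t")
        (out / "gene_dendrogram.nwk").write_text(
            io.linkage_to_newick(model.assignment.linkage, list(ref_data.index)) + "\n"
        )
    except ValueError as exc:
        raise PipelineError(stage, "network_error", str(exc)) from exc
    _checkpoint(stage, t0)

    # ---------------------------------------------------------- preservation
    t0 = time.time()
    stage = "preserve"
    try:
        scheme = PermutationScheme(n_permutations=config.n_permutations, seed=config.seed)
        reports = zsummary(ref_data, test_data, model.assignment.labels, scheme, beta=config.beta)
        reports_to_json(reports, out / "preservation.json")
        frame = reports_to_frame(reports)
        if len(frame):
            frame.insert(1, "module_color", frame["module"].map(
                lambda m: model.assignment.colors[model.assignment.labels == m].iloc[0]
            ))
        frame.to_csv(out / "preservation.tsv", sep="\t", index=False)
        preserved = classify_preserved(reports, threshold=config.z_threshold)
        log.info(
            "preserved modules (Z_summary > %g): %s",
            config.z_threshold,
            [(r.module, round(r.z_summary, 2)) for r in preserved],
        )
    except ValueError as exc:
        raise PipelineError(stage, "preservation_error", str(exc)) from exc
    _checkpoint(stage, t0)

    # ------------------------------------------------------------ enrichment
    if config.gene_sets_path:
        t0 = time.time()
        stage = "enrich"
        try:
            sets = read_gmt(config.gene_sets_path)
            universe = list(ref_data.index)
            tables = []
            for m in model.assignment.modules:
                genes = model.assignment.genes_in(m)
                tab = ora(genes, universe, sets)
                tab.insert(0, "module", m)
                tables.append(tab)
            enr = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        except (OSError, ValueError) as exc:
            raise PipelineError(stage, "enrichment_error", str(exc)) from exc
        _checkpoint(stage, t0)

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest.outputs[p.name] = _sha256(p)
    manifest.timings["total"] = round(time.time() - t_all, 3)
    manifest.to_json(out / "manifest.json")
    return manifest
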