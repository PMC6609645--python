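"""End-to-end orchestration: simulate -> ingest -> preprocess -> screen ->
enrich -> modules -> rules -> report.

A run is driven by a validated PipelineConfig (YAML/JSON or in code), writes
every stage's tables under the output directory, and records a RunManifest
(config snapshot, per-file sha256 checksums, wall-clock per stage, derived
seeds) sufficient to reproduce the run byte-identically.  Per-stage seeds are
derived from the global seed by stable hashing of the stage name, so adding
or disabling a stage does not perturb the randomness of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, StageError
from . import diffstats, enrich, netmod, preprocess, ruleclass, synthdata
from .ingest_annotate import (
    PLATFORMS, TISSUES, load_annotations, load_intensity_table, load_samples,
)

logger = logging.getLogger(__name__)

STAGES = ("synthdata", "ingest", "preprocess", "diffstats", "enrich",
          "netmod", "ruleclass", "report")

_FLOAT_FMT = "%.10g"


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed (< 2**31)."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31 - 1)


@dataclass
class PipelineConfig:
    """Validated configuration; unknown keys are rejected."""

    outdir: str = "metmap_out"
    seed: int = 0
    input_dir: str | None = None      # real mode: directory of fixture-dialect files
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    # synthetic-mode generation parameters
    n_gc: int = 142
    n_lc: int = 144
    effects: list[tuple[str, str, str, float]] = field(default_factory=lambda: [
        # class x tissue effect pattern emulating the study's headline
        # directions: carnitines up in liver, LPCs down in muscle and serum.
        ("carnitine", "liver", "T2D_vs_nonDM", 1.2),
        ("LPC", "muscle", "T2D_vs_nonDM", -1.2),
        ("LPC", "serum", "T2D_vs_nonDM", -1.0),
    ])
    missing_rate: float = 0.15
    left_censor_weight: float = 0.8
    # analysis parameters (defaults follow the published methods)
    missing_threshold: float = 0.25
    impute_constant: float = 1.00001
    n_perms: int = 100_000
    alpha: float = 0.1
    ci_level: float = 0.90
    ci_method: str = "t"
    n_boot: int = 10_000
    enet_l1_ratio: float = 0.5
    cv_folds: int = 10
    scale_ddof: int = 1
    edge_alpha: float = 0.1
    module_max_size: int = 15
    selection_max_iter: int = 30
    selection_n_estimators: int = 150
    n_bins: int = 3
    ratio_top_n: int = 20

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in d.items()})
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def validate(self) -> None:
        if not 0 < self.missing_threshold < 1:
            raise ConfigurationError("missing_threshold must be in (0,1)")
        if self.impute_constant <= 0:
            raise ConfigurationError("impute_constant must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.ci_level < 1:
            raise ConfigurationError("alpha and ci_level must be in (0,1)")
        if self.n_perms < 1 or self.n_boot < 1 or self.cv_folds < 2:
            raise ConfigurationError("n_perms, n_boot >= 1 and cv_folds >= 2")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        effects = []
        for e in self.effects:
            effects.append(tuple(e))
        self.effects = effects

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["effects"] = [list(e) for e in self.effects]
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict[str, int] = field(default_factory=dict)
    stage_status: dict[str, str] = field(default_factory=dict)
    wall_clock_s: dict[str, float] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        with path.open("w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    schema = {c: str(df[c].dtype) for c in df.columns}
    with path.with_suffix(path.suffix + ".schema.json").open("w") as fh:
        json.dump(schema, fh, indent=1, sort_keys=True)


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute every enabled stage in order.

    A stage failure records the error in the manifest and skips everything
    downstream; partial outputs are retained.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.snapshot(), version=__version__)
    manifest.seeds = {s: stage_seed(config.seed, s) for s in STAGES}
    state: dict[str, Any] = {}
    failed = False
    for stage in STAGES:
        if failed:
            manifest.stage_status[stage] = "skipped_downstream_failure"
            continue
        if not config.stages.get(stage, True):
            manifest.stage_status[stage] = "disabled"
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, state, outdir, manifest.seeds[stage])
            manifest.stage_status[stage] = "ok"
        except Exception as exc:  # noqa: BLE001 - reported via manifest
            logger.exception("stage %s failed", stage)
            manifest.stage_status[stage] = f"failed: {exc}"
            failed = True
        manifest.wall_clock_s[stage] = round(time.perf_counter() - t0, 3)
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest.checksums[str(p.relative_to(outdir))] = _sha256(p)
    manifest.write(outdir / "manifest.json")
    if failed:
        raise StageError(
            "pipeline failed; see manifest stage_status in " + str(outdir))
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_synthdata(config: PipelineConfig, state: dict, outdir: Path,
                     seed: int) -> None:
    if config.input_dir is not None:
        return  # real mode: nothing to simulate
    cohort = synthdata.generate_cohort(synthdata.CohortSpec(seed=seed))
    ann = synthdata.generate_annotation(config.n_gc, config.n_lc, seed=seed)
    effects = synthdata.EffectSpec.from_tuples(config.effects)
    missing = synthdata.MissingnessSpec(config.missing_rate,
                                        config.left_censor_weight)
    dataset = synthdata.generate_intensities(cohort, ann, effects, missing,
                                             seed=seed)
    fixture_dir = outdir / "fixture"
    synthdata.write_fixture(dataset, fixture_dir)
    state["fixture_dir"] = fixture_dir


def _stage_ingest(config: PipelineConfig, state: dict, outdir: Path,
                  seed: int) -> None:
    data_dir = Path(config.input_dir) if config.input_dir else state["fixture_dir"]
    samples = load_samples(data_dir / "samples.tsv")
    annotations = load_annotations(data_dir / "annotations.json")
    tables = {}
    for tissue in TISSUES:
        for platform in PLATFORMS:
            p = data_dir / f"intensity_{tissue}_{platform.replace('-', '')}.tsv"
            if p.exists():
                tables[(tissue, platform)] = load_intensity_table(p, tissue, platform)
    if not tables:
        raise StageError(f"no intensity tables found under {data_dir}")
    state.update(samples=samples, annotations=annotations, tables=tables)


def _stage_preprocess(config: PipelineConfig, state: dict, outdir: Path,
                      seed: int) -> None:
    scaled: dict[str, preprocess.ScaledTable] = {}
    for tissue in TISSUES:
        gc = state["tables"].get((tissue, "GC-MS"))
        lc = state["tables"].get((tissue, "LC-MS"))
        if gc is None or lc is None:
            continue
        st = preprocess.preprocess_tissue(
            gc, lc, threshold=config.missing_threshold,
            constant=config.impute_constant, ddof=config.scale_ddof)
        scaled[tissue] = st
        st.values.to_csv(outdir / f"scaled_{tissue}.tsv", sep="\t",
                         index_label="metabolite_id", float_format=_FLOAT_FMT)
    state["scaled"] = scaled
    prov = {t: s.provenance for t, s in scaled.items()}
    with (outdir / "preprocess_provenance.json").open("w") as fh:
        json.dump(prov, fh, indent=1, sort_keys=True, default=str)
    screen = preprocess.covariate_elastic_net(
        state["samples"], l1_ratio=config.enet_l1_ratio,
        n_folds=config.cv_folds, seed=seed)
    cov_rows = [{"covariate": k, "coefficient": v}
                for k, v in screen.elastic_net_coefficients.items()]
    _write_tsv(pd.DataFrame(cov_rows), outdir / "covariate_elastic_net.tsv")
    spearman_frames = []
    cov_frame = preprocess._covariate_frame(state["samples"])
    for tissue, st in scaled.items():
        spearman_frames.append(preprocess.covariate_spearman(st, cov_frame))
    if spearman_frames:
        _write_tsv(pd.concat(spearman_frames, ignore_index=True),
                   outdir / "covariate_spearman.tsv")


def _stage_diffstats(config: PipelineConfig, state: dict, outdir: Path,
                     seed: int) -> None:
    scaled, samples = state["scaled"], state["samples"]
    diff = diffstats.differential_screen(
        scaled, samples, alpha=config.alpha, n_perms=config.n_perms,
        n_boot=config.n_boot, ci_level=config.ci_level, seed=seed,
        ci_method=config.ci_method)
    pairwise = diffstats.pairwise_screen(
        scaled, samples, alpha=config.alpha, n_perms=config.n_perms,
        n_boot=config.n_boot, seed=seed)
    reg = diffstats.regression_hba1c(
        scaled, samples, n_perms=config.n_perms, alpha=config.alpha, seed=seed)
    ratio_frames = []
    for tissue, st in scaled.items():
        top = (diff[(diff["tissue"] == tissue) & diff["significant"]]
               .nsmallest(config.ratio_top_n, "p_perm")["metabolite_id"].tolist())
        if len(top) >= 2:
            import itertools as _it
            pairs = list(_it.combinations(top, 2))
            ratio_frames.append(diffstats.pair_ratios(
                st, samples, pairs=pairs, n_perms=min(config.n_perms, 10_000),
                seed=seed))
    state["diff"], state["pairwise"], state["reg"] = diff, pairwise, reg
    _write_tsv(diff, outdir / "differential_T2D_vs_nonDM.tsv")
    _write_tsv(pairwise, outdir / "differential_pairwise.tsv")
    _write_tsv(reg, outdir / "regression_hba1c.tsv")
    if ratio_frames:
        _write_tsv(pd.concat(ratio_frames, ignore_index=True),
                   outdir / "pair_ratios.tsv")


def _stage_enrich(config: PipelineConfig, state: dict, outdir: Path,
                  seed: int) -> None:
    res = enrich.enrich_all(state["diff"], state["annotations"])
    state["enrich"] = res
    _write_tsv(res, outdir / "enrichment.tsv")


def _stage_netmod(config: PipelineConfig, state: dict, outdir: Path,
                  seed: int) -> None:
    scaled, samples = state["scaled"], state["samples"]
    network = netmod.build_network(scaled, samples, edge_alpha=config.edge_alpha)
    modules = netmod.find_modules(network, scaled, samples,
                                  alpha=config.alpha,
                                  max_size=config.module_max_size)
    class_of = {r.local_id: r.curated_class for r in state["annotations"]}
    scopes = netmod.summarize_scopes(modules, network, class_of)
    netmod.write_network(network, outdir / "network.graphml",
                         outdir / "network_edges.tsv")
    _write_tsv(netmod.modules_table(modules), outdir / "modules.tsv")
    for name, df in scopes.items():
        _write_tsv(df, outdir / f"edge_scopes_{name}.tsv")
    state["modules"] = modules


def _stage_ruleclass(config: PipelineConfig, state: dict, outdir: Path,
                     seed: int) -> None:
    scaled, samples = state["scaled"], state["samples"]
    pheno = {s.sample_id: ("T2D" if s.phenotype == "T2D" else "non-diabetes")
             for s in samples}
    cv_report: dict[str, dict] = {}
    all_rules = []
    for tissue, st in scaled.items():
        X = st.values.T  # samples x metabolites
        y = [pheno[sid] for sid in X.index]
        sel = ruleclass.select_all_relevant(
            X, y, max_iter=config.selection_max_iter,
            n_estimators=config.selection_n_estimators, seed=seed)
        feats = sel.confirmed or sel.tentative[:10] or list(X.columns[:10])
        table = ruleclass.discretize(X[feats], y, n_bins=config.n_bins)
        reducts = ruleclass.compute_reducts(table)
        rules = ruleclass.induce_rules(table, reducts)
        rt = ruleclass.rules_table(rules)
        rt.insert(0, "tissue", tissue)
        all_rules.append(rt)
        cv = ruleclass.crossvalidate(X[feats], y, k=config.cv_folds,
                                     seed=seed, n_bins=config.n_bins)
        cv.pop("predictions")
        cv["confirmed_features"] = sel.confirmed
        cv_report[tissue] = cv
        nets = ruleclass.build_rule_network(rules) if rules else {}
        for cls, g in nets.items():
            safe = cls.replace(" ", "_").replace("-", "_")
            import networkx as nx
            nx.write_graphml(g, outdir / f"rule_network_{tissue}_{safe}.graphml")
    if all_rules:
        _write_tsv(pd.concat(all_rules, ignore_index=True), outdir / "rules.tsv")
    with (outdir / "cv_report.json").open("w") as fh:
        json.dump(cv_report, fh, indent=1, sort_keys=True)
    state["cv_report"] = cv_report


def _stage_report(config: PipelineConfig, state: dict, outdir: Path,
                  seed: int) -> None:
    write_report(state, outdir, alpha=config.alpha)


def write_report(state: Mapping[str, Any], outdir: Path, alpha: float = 0.1) -> None:
    """Emit the two overview matrices and the summary counts.

    (a) a differential matrix: significant metabolites x tissue with
    significance marker and direction; (b) an HbA1c-association matrix with
    adjusted R^2; (c) summary counts.
    """
    outdir = Path(outdir)
    notes = []
    class_of = {r.local_id: r.curated_class
                for r in state.get("annotations", [])}
    diff = state.get("diff")
    summary: dict[str, Any] = {}
    if diff is not None and len(diff):
        sig_any = diffstats.summarize_significant(diff)
        keep = sig_any.loc[sig_any["significant_any"], "metabolite_id"]
        mat = diff[diff["metabolite_id"].isin(keep)].copy()
        mat["cell"] = np.where(
            mat["significant"],
            np.where(mat["effect"] > 0, "up*", "down*"),
            "")
        wide = mat.pivot_table(index="metabolite_id", columns="tissue",
                               values="cell", aggfunc="first").fillna("")
        wide.insert(0, "class", [class_of.get(m.split("__")[0], "unclassified")
                                 for m in wide.index])
        wide.reset_index().to_csv(outdir / "report_differential_matrix.tsv",
                                  sep="\t", index=False)
        n_total = diff["metabolite_id"].nunique()
        n_sig = int(sig_any["significant_any"].sum())
        summary.update(
            n_metabolites_tested=n_total,
            n_significant_any_tissue=n_sig,
            pct_significant_any_tissue=round(100 * n_sig / n_total, 2),
        )
    else:
        notes.append("differential results missing; matrix omitted")
    reg = state.get("reg")
    if reg is not None and len(reg):
        sig_met = reg.groupby("metabolite_id")["significant"].any()
        keep = sig_met[sig_met].index
        sub = reg[reg["metabolite_id"].isin(keep)].copy()
        sub["cell"] = np.where(sub["significant"],
                               sub["adj_r2"].round(3).astype(str) + "*",
                               sub["adj_r2"].round(3).astype(str))
        wide = sub.pivot_table(index="metabolite_id", columns="tissue",
                               values="cell", aggfunc="first").fillna("")
        wide.insert(0, "class", [class_of.get(m.split("__")[0], "unclassified")
                                 for m in wide.index])
        wide.reset_index().to_csv(outdir / "report_hba1c_matrix.tsv",
                                  sep="\t", index=False)
        summary["n_hba1c_associated_any_tissue"] = int(len(keep))
    else:
        notes.append("regression results missing; HbA1c matrix omitted")
    summary["notes"] = notes
    with (outdir / "report_summary.json").open("w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)


_STAGE_FUNCS = {
    "synthdata": _stage_synthdata,
    "ingest": _stage_ingest,
    "preprocess": _stage_preprocess,
    "diffstats": _stage_diffstats,
    "enrich": _stage_enrich,
    "netmod": _stage_netmod,
    "ruleclass": _stage_ruleclass,
    "report": _stage_report,
}
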