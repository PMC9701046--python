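"""End-to-end pipeline: (simulate | load) -> DEG -> STC profiles ->
enrichment -> co-expression network, with a machine-readable manifest.

Every output is plain TSV/JSON re-readable by this package's own readers,
and the whole bundle is a deterministic function of the manifest (config +
seed): running twice with the same config gives byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._version import __version__
from .enrichment import run_enrichment
from .io import (ExpressionMatrix, read_design, read_expression_table,
                 write_design, write_expression_table, write_table)
from .network import build_network, node_metrics, rank_hubs, write_edge_list, \
    write_graphml
from .profiles import (assign_profiles, enumerate_profiles, profile_catalog,
                       profile_significance, transform_to_log_ratios)
from .rvm import fit_rvm_prior, rvm_f_test, select_degs
from .simulate import (GeneSetCollection, SimConfig, read_gmt,
                       simulate_dataset, simulate_gene_sets, write_gmt)

logger = logging.getLogger("stcpipe")


@dataclass
class PipelineConfig:
    """Everything one run needs; serialized verbatim into the manifest.

    Data mode: set ``matrix_path``/``design_path`` (+ optional
    ``gmt_path``).  Simulation mode: leave them None and the ``sim``
    config is used; gene sets are then simulated too (``sim_n_sets``
    random sets of ``sim_set_size`` genes plus one planted set per planted
    profile).  ``network_profiles`` defaults to (5, 2) — for the
    three-condition design these are the up-then-down trajectory and its
    mirror.
    """

    matrix_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    sim: SimConfig = field(default_factory=lambda: SimConfig(
        profile_fractions={5: 0.1, 6: 0.05},
        variance_prior_shape=8.0, variance_prior_scale=2.0))
    sim_n_sets: int = 20
    sim_set_size: int = 25
    alpha_p: float = 0.05
    alpha_fdr: float = 0.05
    alpha_profile: float = 0.05
    alpha_enrichment: float = 0.05
    stc_c: int = 1
    network_threshold: float = 0.8
    network_profiles: tuple[int, ...] = (5, 2)
    network_top_k: int = 21
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha_p", "alpha_fdr", "alpha_profile",
                     "alpha_enrichment", "network_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.data_mode:
            for p in (self.matrix_path, self.design_path):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
            if self.gmt_path and not Path(self.gmt_path).exists():
                raise FileNotFoundError(self.gmt_path)

    @property
    def data_mode(self) -> bool:
        return self.matrix_path is not None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["profile_fractions"] = {
            str(k): v for k, v in d["sim"]["profile_fractions"].items()}
        d["sim"]["groups"] = list(d["sim"]["groups"])
        d["network_profiles"] = list(self.network_profiles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if sim:
            sim = dict(sim)
            sim["profile_fractions"] = {
                int(k): float(v)
                for k, v in sim.get("profile_fractions", {}).items()}
            sim["groups"] = tuple(sim.get("groups", SimConfig.groups))
            d["sim"] = SimConfig(**sim)
        if "network_profiles" in d:
            d["network_profiles"] = tuple(d["network_profiles"])
        return cls(**d)


def _genes_in_profile(assignment: pd.DataFrame, pid: int) -> list[str]:
    mask = (assignment["profile"] == pid).fillna(False).to_numpy(dtype=bool)
    return list(assignment.index[mask])


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record: logging.LogRecord) -> None:
        self.count += 1


class StageError(RuntimeError):
    """An error in a named pipeline stage (aborts the run)."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(name, exc) from exc
        return wrapped
    return deco


@_stage("input")
def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.data_mode:
        design = read_design(config.design_path)
        matrix = read_expression_table(config.matrix_path, design)
        collection = read_gmt(config.gmt_path) if config.gmt_path else None
        truth = None
    else:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        matrix, truth = simulate_dataset(sim)
        planted = sorted(sim.profile_fractions)
        collection = simulate_gene_sets(
            truth, config.sim_n_sets, config.sim_set_size,
            planted=planted, seed=config.seed + 1)
        write_expression_table(matrix, outdir / "matrix.tsv")
        write_design(matrix.sample_groups, outdir / "design.tsv")
        write_gmt(collection, outdir / "gene_sets.gmt")
        write_table(truth.reset_index(), outdir / "truth.tsv")
    if collection is not None:
        collection = GeneSetCollection(collection.sets,
                                       list(matrix.values.index)).harmonized(
            list(matrix.values.index))
    return matrix, collection, truth


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage, write the result bundle, return the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_file_log(outdir / "run.log")
    warning_counter = _WarningCounter()
    logger.addHandler(warning_counter)

    matrix, collection, _truth = _load_inputs(config, outdir)
    logger.info("input: %d genes x %d samples, groups %s",
                matrix.n_genes, matrix.n_samples, matrix.groups)

    # ---- DEG ---------------------------------------------------------
    @_stage("deg")
    def _deg():
        prior = fit_rvm_prior(matrix)
        table = rvm_f_test(matrix, prior, config.alpha_p, config.alpha_fdr)
        return prior, table

    prior, deg_table = _deg()
    degs = select_degs(deg_table)
    write_table(deg_table.reset_index(), outdir / "deg_table.tsv")
    logger.info("deg: a=%.6g b=%.6g d=%d; %d/%d genes selected",
                prior.a, prior.b, prior.d, len(degs), matrix.n_genes)

    # ---- STC ---------------------------------------------------------
    @_stage("stc")
    def _stc():
        profiles = enumerate_profiles(matrix.n_groups, config.stc_c)
        write_table(profile_catalog(profiles), outdir / "profile_catalog.tsv")
        if not degs:
            logger.warning("no DEG selected; STC, enrichment and network "
                           "outputs will be empty")
            return profiles, None, None, None
        ratios = transform_to_log_ratios(matrix, degs)
        assignment = assign_profiles(ratios, profiles)
        significance = profile_significance(
            assignment, ratios, profiles, alpha=config.alpha_profile)
        return profiles, ratios, assignment, significance

    profiles, ratios, assignment, significance = _stc()
    if assignment is not None:
        write_table(assignment.reset_index().rename(columns={"index": "gene"}),
                    outdir / "profile_assignments.tsv")
        write_table(significance, outdir / "profile_significance.tsv")
        for p in profiles:
            members = _genes_in_profile(assignment, p.id)
            (outdir / f"profile_{p.id}.txt").write_text(
                "".join(f"{g}\n" for g in members))
    else:
        assignment = pd.DataFrame(
            {"profile": pd.array([], dtype="Int64"), "correlation": []})
        significance = pd.DataFrame(
            columns=["profile", "observed", "expected", "p_value",
                     "significant"])
        write_table(assignment.reset_index().rename(columns={"index": "gene"}),
                    outdir / "profile_assignments.tsv")
        write_table(significance, outdir / "profile_significance.tsv")

    # ---- enrichment --------------------------------------------------
    @_stage("enrichment")
    def _enrich():
        enriched_profiles = []
        if collection is None or significance.empty:
            return enriched_profiles
        sig_ids = list(significance.loc[significance["significant"],
                                        "profile"].astype(int))
        wanted = sorted(set(sig_ids) | set(config.network_profiles))
        for pid in wanted:
            members = _genes_in_profile(assignment, pid)
            result = run_enrichment(members, collection,
                                    alpha=config.alpha_enrichment)
            write_table(result, outdir / f"enrichment_profile_{pid}.tsv")
            enriched_profiles.append(pid)
        return enriched_profiles

    enriched_profiles = _enrich()

    # ---- network -----------------------------------------------------
    @_stage("network")
    def _network():
        selected = [g for pid in config.network_profiles
                    for g in _genes_in_profile(assignment, pid)]
        labels = {g: int(assignment.loc[g, "profile"]) for g in selected}
        if len(selected) < 2:
            logger.warning("fewer than 2 genes in network profiles %s; "
                           "empty network written", config.network_profiles)
            import networkx as nx
            graph = nx.Graph()
        else:
            graph = build_network(matrix, selected,
                                  threshold=config.network_threshold,
                                  profile_labels=labels)
        metrics = node_metrics(graph)
        write_edge_list(graph, outdir / "network_edges.tsv")
        write_table(metrics, outdir / "network_metrics.tsv")
        if not metrics.empty:
            hubs = rank_hubs(metrics, config.network_top_k)
        else:
            hubs = metrics
        write_table(hubs, outdir / "network_hubs.tsv")
        if graph.number_of_nodes():
            write_graphml(graph, outdir / "network.graphml")
        return graph, metrics

    graph, _metrics = _network()

    manifest = {
        "package": "stcpipe",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_genes": int(matrix.n_genes),
        "n_samples": int(matrix.n_samples),
        "groups": list(matrix.groups),
        "n_deg": len(degs),
        "significant_profiles": [
            int(p) for p in significance.loc[significance["significant"],
                                             "profile"]
        ] if not significance.empty else [],
        "enriched_profiles": enriched_profiles,
        "network_nodes": int(graph.number_of_nodes()),
        "network_edges": int(graph.number_of_edges()),
        "warnings": warning_counter.count,
        "outputs": sorted(p.name for p in outdir.iterdir()
                          if p.name not in ("manifest.json", "run.log")),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d DEG, %d network nodes",
                len(degs), graph.number_of_nodes())
    logger.removeHandler(warning_counter)
    _teardown_file_log()
    return manifest


_file_handler: logging.Handler | None = None


def _setup_file_log(path: Path) -> None:
    # no timestamps: reruns with the same manifest must be byte-identical
    global _file_handler
    _teardown_file_log()
    _file_handler = logging.FileHandler(path, mode="w")
    _file_handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(_file_handler)
    if logger.level == logging.NOTSET:
        logger.setLevel(logging.INFO)


def _teardown_file_log() -> None:
    global _file_handler
    if _file_handler is not None:
        logger.removeHandler(_file_handler)
        _file_handler.close()
        _file_handler = None
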