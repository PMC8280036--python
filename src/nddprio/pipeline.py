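"""End-to-end orchestration: filter -> counts -> association -> catalog ->
co-expression permutation -> functional network -> constraint comparison.

Every stage is a pure function of (inputs, config, seed); the run report
records the configuration hash and an SHA-256 digest of every output so a
rerun with identical inputs is verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import catalog as cat
from . import coexpr as cx
from . import constraint as cs
from . import io as nio
from . import network as nw
from . import tada
from . import variants as var

logger = logging.getLogger(__name__)


class PipelineValidationError(ValueError):
    """Bad configuration or missing input (CLI exit code 2)."""


class StageFailure(RuntimeError):
    """A stage failed during execution (CLI exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


INPUT_KEYS = (
    "variants",
    "mutation_rates",
    "control_counts",
    "expression",
    "sample_metadata",
    "ppi",
    "constraint",
    "evidence",
)


@dataclass
class PipelineConfig:
    inputs: dict[str, str]
    n_trios: int
    n_cases: int
    n_controls: int
    reve_threshold: float = 0.7
    max_af: float = 0.001
    fdr: float = 0.1
    fdr_strong: float = 0.05
    r_threshold: float = 0.7
    miscore_threshold: float = 0.45
    min_novel_connections: int = 2
    percentile_cutoff: float = 50.0
    n_iter: int = 10_000
    seed: int = 0
    hyperparams: tada.TadaHyperparams = field(default_factory=tada.TadaHyperparams)

    def validate(self) -> None:
        checks = [
            (0.0 <= self.reve_threshold <= 1.0, "reve_threshold outside [0,1]"),
            (0.0 <= self.max_af <= 1.0, "max_af outside [0,1]"),
            (0.0 < self.fdr <= 1.0, "fdr outside (0,1]"),
            (0.0 < self.fdr_strong <= self.fdr, "fdr_strong outside (0, fdr]"),
            (0.0 < self.r_threshold < 1.0, "r_threshold outside (0,1)"),
            (0.0 <= self.miscore_threshold <= 1.0, "miscore_threshold outside [0,1]"),
            (self.min_novel_connections >= 1, "min_novel_connections must be >= 1"),
            (self.n_iter >= 1, "n_iter must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise PipelineValidationError(msg)
        for key in INPUT_KEYS:
            if key not in self.inputs:
                raise PipelineValidationError(f"missing input path for '{key}'")
            if not Path(self.inputs[key]).exists():
                raise PipelineValidationError(f"input file not found: {key} = {self.inputs[key]}")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        hp = d.pop("hyperparams", None)
        cfg = cls(
            inputs=dict(d.pop("inputs")),
            n_trios=int(d.pop("n_trios")),
            n_cases=int(d.pop("n_cases")),
            n_controls=int(d.pop("n_controls")),
            **{k: v for k, v in d.items()},
        )
        if hp:
            cfg.hyperparams = tada.TadaHyperparams.from_dict(hp)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return {
            "inputs": dict(self.inputs),
            "n_trios": self.n_trios,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "reve_threshold": self.reve_threshold,
            "max_af": self.max_af,
            "fdr": self.fdr,
            "fdr_strong": self.fdr_strong,
            "r_threshold": self.r_threshold,
            "miscore_threshold": self.miscore_threshold,
            "min_novel_connections": self.min_novel_connections,
            "percentile_cutoff": self.percentile_cutoff,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "hyperparams": {
                "gamma_bar_dn": dict(self.hyperparams.gamma_bar_dn),
                "beta_dn": dict(self.hyperparams.beta_dn),
                "gamma_bar_cc": dict(self.hyperparams.gamma_bar_cc),
                "beta_cc": dict(self.hyperparams.beta_cc),
                "rho": dict(self.hyperparams.rho),
                "nu": dict(self.hyperparams.nu),
                "pi": self.hyperparams.pi,
            },
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def workspace_config(workspace: str | Path, **overrides: Any) -> PipelineConfig:
    """Configuration for a directory laid out by ``simulate_workspace``.

    Cohort sizes come from the workspace's ``workspace.yaml`` when present
    (written by the generator), falling back to the generator defaults.
    """
    ws = Path(workspace)
    from .simulate import SimulationConfig

    sim = SimulationConfig()
    sizes = {
        "n_trios": sim.n_trios,
        "n_cases": sim.n_trios + sim.n_singletons,
        "n_controls": sim.n_controls,
    }
    meta = ws / "workspace.yaml"
    if meta.exists():
        import yaml

        sizes.update(yaml.safe_load(meta.read_text()) or {})
    base: dict[str, Any] = {
        "inputs": {k: str(ws / f"{k}.tsv") for k in INPUT_KEYS},
        **sizes,
    }
    base.update(overrides)
    return PipelineConfig.from_dict(base)


def run_all(cfg: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute every stage in order; returns the machine-readable run report.

    A stage failure raises :class:`StageFailure` after writing a partial
    manifest of the outputs produced so far.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_dict = cfg.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True).encode()
    ).hexdigest()
    report: dict[str, Any] = {
        "config_hash": config_hash,
        "seed": cfg.seed,
        "stages": {},
        "outputs": {},
    }
    produced: dict[str, Path] = {}
    ss = np.random.SeedSequence(cfg.seed)
    perm_seed = int(ss.generate_state(1)[0] % (2**31))

    def emit(name: str, path: Path) -> None:
        produced[name] = path
        report["outputs"][name] = _sha256(path)

    def fail(stage: str, exc: Exception) -> StageFailure:
        manifest = {k: str(v) for k, v in produced.items()}
        (out / "partial_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return StageFailure(stage, exc)

    # --- filter ---------------------------------------------------------
    try:
        variants = nio.read_variants(cfg.inputs["variants"])
        selected = var.select_potential_functional(
            variants, reve_threshold=cfg.reve_threshold, max_af=cfg.max_af
        )
        control_counts = nio.read_table(cfg.inputs["control_counts"])
        counts = var.tabulate_gene_counts(
            selected,
            n_trios=cfg.n_trios,
            n_cases=cfg.n_cases,
            n_controls=cfg.n_controls,
            control_counts=control_counts,
        )
        multi = var.find_multi_dnv_genes(counts)
        xlinked = sorted({sv.variant.gene for sv in var.detect_xlinked_hemizygous(selected)})
        nio.write_gene_counts(counts, out / "gene_counts.tsv")
        nio.write_table(multi, out / "multi_dnv_genes.tsv")
        nio.write_gene_set(xlinked, out / "xlinked_genes.txt")
        emit("gene_counts", out / "gene_counts.tsv")
        emit("multi_dnv_genes", out / "multi_dnv_genes.tsv")
        emit("xlinked_genes", out / "xlinked_genes.txt")
        report["stages"]["filter"] = {
            "n_input_variants": len(variants),
            "n_selected": len(selected),
            "n_genes": len(counts.genes),
            "n_xlinked_genes": len(xlinked),
        }
    except Exception as exc:  # noqa: BLE001 - re-raised as stage failure
        raise fail("filter", exc)

    # --- tada -----------------------------------------------------------
    try:
        mu = nio.read_mutation_rates(cfg.inputs["mutation_rates"])
        results = tada.prioritize(
            counts, mu, params=cfg.hyperparams, fdr_threshold=cfg.fdr
        )
        nio.write_table(results, out / "tada_results.tsv")
        emit("tada_results", out / "tada_results.tsv")
        report["stages"]["tada"] = {
            "n_genes": len(results),
            "n_candidates": int(results["candidate"].sum()),
        }
    except Exception as exc:
        raise fail("tada", exc)

    # --- catalog --------------------------------------------------------
    try:
        evidence = nio.read_evidence(cfg.inputs["evidence"])
        entries = cat.merge_candidates(
            results, xlinked, evidence, fdr_threshold=cfg.fdr, fdr_strong=cfg.fdr_strong
        )
        catalog_df = cat.catalog_to_frame(entries)
        nio.write_table(catalog_df, out / "catalog.tsv")
        emit("catalog", out / "catalog.tsv")
        novel = {e.gene for e in entries if e.status == "novel"}
        known_candidates = {e.gene for e in entries if e.status == "known"}
        # the known reference set spans all established genes, not just this
        # cohort's candidates
        known = {
            g
            for g, ev in evidence.items()
            if cat.classify_gene(g, ev) or ev.pubmed_support
        }
        report["stages"]["catalog"] = {
            "n_candidates": len(entries),
            "n_novel": len(novel),
            "n_known_candidates": len(known_candidates),
            "n_known_reference": len(known),
        }
    except Exception as exc:
        raise fail("catalog", exc)

    # --- coexpression permutation ----------------------------------------
    coexpr_graph = None
    try:
        matrix = nio.read_expression(cfg.inputs["expression"], cfg.inputs["sample_metadata"])
        filtered = cx.select_samples(matrix)
        coexpr_graph = cx.coexpression_edges(filtered, threshold=cfg.r_threshold)
        nio.write_edge_list(coexpr_graph, out / "coexpression_edges.tsv", attr="r")
        emit("coexpression_edges", out / "coexpression_edges.tsv")
        stage: dict[str, Any] = {
            "n_samples_used": len(filtered.samples),
            "n_edges": coexpr_graph.number_of_edges(),
        }
        novel_in_graph = novel & set(coexpr_graph.nodes)
        if novel_in_graph:
            perm = cx.permutation_test(
                coexpr_graph,
                novel,
                known,
                n_iter=cfg.n_iter,
                seed=perm_seed,
            )
            perm_out = {
                "observed": perm.observed,
                "p_values": perm.p_values,
                "n_iterations": perm.n_iterations,
                "seed": perm.seed,
                "dropped_genes": list(perm.dropped_genes),
            }
            stage["permutation"] = perm_out
            (out / "permutation.json").write_text(
                json.dumps(perm_out, indent=2, sort_keys=True)
            )
            emit("permutation", out / "permutation.json")
        else:
            stage["permutation"] = "skipped: no novel candidate genes in the expression graph"
        report["stages"]["coexpr"] = stage
    except Exception as exc:
        raise fail("coexpr", exc)

    # --- network ----------------------------------------------------------
    try:
        ppi_graph = nw.ppi_edges(nio.read_ppi(cfg.inputs["ppi"]), threshold=cfg.miscore_threshold)
        net = nw.build_functional_network(
            novel,
            known,
            coexpr_graph,
            ppi_graph,
            min_novel_connections=cfg.min_novel_connections,
        )
        nio.write_graphml(net.graph, out / "network.graphml")
        nio.write_edge_list(net.graph, out / "network_edges.tsv", attr="provenance")
        nio.write_table(nw.novel_degree_table(net), out / "novel_degree.tsv", index=False)
        emit("network", out / "network.graphml")
        emit("network_edges", out / "network_edges.tsv")
        emit("novel_degree", out / "novel_degree.tsv")
        report["stages"]["network"] = {
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.graph.number_of_edges(),
            "isolated_novel": list(net.isolated_novel),
        }
    except Exception as exc:
        raise fail("network", exc)

    # --- constraint -------------------------------------------------------
    try:
        constraint = nio.read_constraint(cfg.inputs["constraint"])
        ranked = cs.percentile_ranks(constraint)
        nio.write_table(ranked.round(6), out / "constraint_percentiles.tsv")
        emit("constraint_percentiles", out / "constraint_percentiles.tsv")
        candidates = sorted({e.gene for e in entries} & set(ranked.index))
        stage = {"n_candidates_scored": len(candidates)}
        if candidates:
            rest = ranked.index.difference(candidates)
            tests = {}
            for metric in ("pli_percentile", "rvis_percentile"):
                a = ranked.loc[candidates, metric].dropna()
                b = ranked.loc[rest, metric].dropna()
                if len(a) and len(b):
                    u, p = cs.rank_sum_test(a, b)
                    tests[metric] = {"U": u, "p_two_sided": p}
            stage["rank_sum"] = tests
            multi_genes = [g for g in multi.index if g in ranked.index]
            stage["multi_dnv_top_fraction"] = cs.top_fraction_count(
                ranked.loc[multi_genes], cutoff_percentile=cfg.percentile_cutoff
            )
        (out / "constraint_report.json").write_text(
            json.dumps(stage, indent=2, sort_keys=True)
        )
        emit("constraint_report", out / "constraint_report.json")
        report["stages"]["constraint"] = stage
    except Exception as exc:
        raise fail("constraint", exc)

    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
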