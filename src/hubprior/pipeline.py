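"""End-to-end orchestration: DE → network → hubs → Step 1/Step 2 →
prioritized list → evaluation → classification, from a single config.

Every stage writes its intermediate TSV; the run produces a
machine-readable JSON report of stage counts, parameters and the seed.  One
global seed derives fixed per-stage seeds so each stage is independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io_formats as io
from .classification import coediff_features, loocv_evaluate
from .diffexpr import permutation_fdr, select_de
from .network_topology import build_disease_network, select_hubs
from .network_variation import network_variation
from .prioritization import (
    combine_hubs,
    go_enrichment,
    reference_overlap,
    tissue_filter,
)
from .semantic_similarity import prioritize_by_semsim

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "run_on_fixture"]

# fixed per-stage seed offsets derived from the global seed
_SEED_DE, _SEED_NETVAR, _SEED_CLASSIFY = 11, 22, 33


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run.

    Defaults mirror the study conditions: permissive positive-direction DE
    selection (q <= 0.98), evidence filter at 2, top-half bottlenecks,
    200 label permutations for the co-expression null, two-sided p-values
    at alpha 0.05 with Bonferroni, median semantic similarity > 0.5,
    brain-tissue fold 1.5, and a 100-tree forest for LOOCV.
    """

    expression: str = ""
    groups: str = ""
    interactions: str = ""
    obo: str = ""
    gaf: str = ""
    tissues: str = ""
    reference: str = ""
    housekeeping: str = ""

    min_evidence: int = 2
    fdr_threshold: float = 0.98
    de_direction: str = "positive"
    de_n_perm: int = 100
    s0: float | str = "auto"
    bottleneck_quantile: float = 0.5
    n_perm: int = 200
    alpha: float = 0.05
    sidedness: str = "two_sided"
    smooth: bool = False
    semsim_threshold: float = 0.5
    combine: str = "all_pairs_avg"
    namespace: str = "P"
    tissue_targets: tuple[str, ...] = ("whole brain", "prefrontal cortex")
    tissue_fold: float = 1.5
    enrichment_alpha: float = 0.05
    n_trees: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "tissue_targets" in data:
            data["tissue_targets"] = tuple(data["tissue_targets"])
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("expression", "groups", "interactions", "obo", "gaf",
                     "tissues", "reference", "housekeeping"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise PipelineError(f"config path {name!r} missing: {p!r}")

    def params_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tissue_targets"] = list(d["tissue_targets"])
        return d


class _Stage:
    """Context manager that re-raises with the stage name and logs timing."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self._t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self._t0
        if exc is not None:
            raise PipelineError(f"stage {self.name}: {exc}") from exc
        logger.info("stage %s: done in %.2fs", self.name, dt)
        return False


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage from the configured input files.

    Returns the run report (also written to ``report.json``); intermediate
    TSVs are written as each stage completes, so partial outputs survive a
    failure.
    """
    config.validate_paths()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _Stage("load"):
        expr, groups = io.read_expression(config.expression, config.groups)
        raw = io.read_interactions(config.interactions, config.min_evidence)
        dag = io.read_obo(config.obo)
        ann = io.read_annotations(config.gaf, namespace=config.namespace, dag=dag)
        tissues = io.read_tissue_table(config.tissues)
        reference = io.read_gene_set(config.reference, "reference")
        housekeeping = io.read_gene_set(config.housekeeping, "housekeeping")

    report = _run_stages(
        expr, groups, raw, dag, ann, tissues, reference, housekeeping,
        config, outdir,
    )
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _run_stages(
    expr, groups, raw, dag, ann, tissues, reference, housekeeping,
    config: PipelineConfig, outdir: Path,
) -> dict:
    counts: dict[str, object] = {}

    with _Stage("diffexpr"):
        de = permutation_fdr(
            expr, groups,
            n_perm=config.de_n_perm,
            seed=config.seed + _SEED_DE,
            s0=config.s0,
        )
        de_set = select_de(de, config.fdr_threshold, config.de_direction)
        de.table.rename_axis("gene_id").to_csv(outdir / "de.tsv", sep="\t")
        counts["de_genes"] = len(de_set)

    with _Stage("network"):
        net = build_disease_network(raw, de_set)
        edges = sorted(tuple(sorted(e)) for e in net.edges)
        with open(outdir / "disease_network.tsv", "w") as fh:
            fh.write("gene_a\tgene_b\n")
            for a, b in edges:
                fh.write(f"{a}\t{b}\n")
        counts["network_nodes"] = net.number_of_nodes()
        counts["network_edges"] = net.number_of_edges()

    with _Stage("hubs"):
        hub_table = select_hubs(net, config.bottleneck_quantile)
        hub_table.table.to_csv(outdir / "hubs.tsv", sep="\t")
        hubs = hub_table.hubs()
        counts["hubs"] = len(hubs)
        counts["degree_hubs"] = len(hub_table.degree_hubs())
        counts["bottlenecks"] = len(hub_table.bottlenecks())

    with _Stage("netvar"):
        nv = network_variation(
            expr, groups, net, hubs,
            n_perm=config.n_perm,
            seed=config.seed + _SEED_NETVAR,
            alpha=config.alpha,
            sidedness=config.sidedness,
            smooth=config.smooth,
        )
        nv.table.to_csv(outdir / "netvar.tsv", sep="\t")
        step1 = nv.significant_hubs()
        counts["netvar_tested"] = len(nv.table)
        counts["step1_hubs"] = len(step1)

    with _Stage("semsim"):
        ss = prioritize_by_semsim(
            dag, ann, net, hubs,
            threshold=config.semsim_threshold,
            combine=config.combine,
        )
        ss.table.to_csv(outdir / "semsim.tsv", sep="\t")
        step2 = ss.selected_hubs()
        counts["semsim_scored"] = len(ss.table)
        counts["step2_hubs"] = len(step2)

    with _Stage("prioritize"):
        prioritized = combine_hubs(
            step1, step2,
            avg_pcc=nv.table["avg_pcc"].to_dict(),
            median_semsim=ss.table["median_similarity"].to_dict(),
        )
        ref_hits = reference_overlap(prioritized, reference)
        tissue = tissue_filter(
            prioritized, tissues, config.tissue_targets, housekeeping,
            fold=config.tissue_fold,
        )
        prioritized.table.to_csv(outdir / "prioritized_genes.tsv", sep="\t")
        counts["prioritized"] = len(prioritized)
        counts["reference_hits"] = len(ref_hits)
        counts["reference_size"] = len(reference)
        counts["tissue_passes"] = len(tissue.passed)
        counts["housekeeping_in_list"] = len(tissue.housekeeping)

    with _Stage("enrichment"):
        background = io.make_gene_set("background", expr.gene_ids)
        enrich = go_enrichment(
            prioritized.genes, background, ann, dag, alpha=config.enrichment_alpha
        )
        enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        counts["enriched_terms"] = int(enrich["enriched"].sum()) if len(enrich) else 0

    with _Stage("classify"):
        if len(prioritized) == 0:
            counts["auc"] = None
            counts["classified_hubs"] = 0
        else:
            features = coediff_features(expr, groups, net, prioritized.genes)
            features.values.to_csv(outdir / "features.tsv", sep="\t")
            clf = loocv_evaluate(
                features, n_trees=config.n_trees,
                seed=config.seed + _SEED_CLASSIFY,
            )
            counts["auc"] = round(clf.auc, 6)
            counts["classified_hubs"] = features.values.shape[1]
            (outdir / "classification.json").write_text(
                json.dumps(
                    {
                        "auc": clf.auc,
                        "scores": clf.scores.round(6).to_dict(),
                        "roc_points": clf.roc_points,
                        "n_trees": clf.n_trees,
                    },
                    indent=2,
                    sort_keys=True,
                )
                + "\n"
            )

    return {
        "counts": counts,
        "prioritized_genes": sorted(prioritized.table.index),
        "parameters": config.params_dict(),
        "seed": config.seed,
    }


def run_on_fixture(
    fixture, config: PipelineConfig | None = None, outdir: str | Path | None = None
) -> dict:
    """Run the stages directly on an in-memory synthetic fixture.

    Convenience for tests and simulations; identical computation to
    `run_pipeline`, minus file round-trips (an *outdir* may still be given
    to keep the intermediates).
    """
    import tempfile

    config = config or PipelineConfig()
    if outdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            return _run_stages(
                fixture.expression, fixture.groups, fixture.edges, fixture.dag,
                fixture.annotations, fixture.tissues, fixture.reference,
                fixture.housekeeping, config, Path(tmp),
            )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return _run_stages(
        fixture.expression, fixture.groups, fixture.edges, fixture.dag,
        fixture.annotations, fixture.tissues, fixture.reference,
        fixture.housekeeping, config, outdir,
    )
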