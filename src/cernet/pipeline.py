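"""End-to-end orchestration: profiling -> targets -> network -> ceRNA.

:func:`analyze_bundle` runs every analysis stage on an in-memory input
bundle and returns both the intermediate objects and a flat JSON-able
report of the counts the screen produces (differential features per
class, intersected targets, cis pairs, network size, modules, hubs and
sponge triads). :func:`run_pipeline` adds input resolution (synthetic /
directory / packaged fixture tables), output writing and cleanup on
failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import annotation as ann
from . import io as cio
from . import network as net
from .config import PipelineConfig
from .diffexpr import run_de, significant_records
from .enrichment import enrich
from .simulate import Bundle, GroundTruth, generate_bundle

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class AnalysisResult:
    """Objects produced by one full analysis pass."""

    de: dict[str, pd.DataFrame]
    lncrna_classes: pd.DataFrame
    cis_pairs: pd.DataFrame
    cis_de_pairs: pd.DataFrame
    mrna_intersection: ann.IntersectionResult
    lncrna_intersection: ann.IntersectionResult
    network: "net.nx.Graph"
    hubs: Optional[net.HubResult]
    modules: list[net.DenseModule]
    triads: list[net.CeRNATriad]
    restricted_triads: Optional[list[net.CeRNATriad]]
    enrichment: Optional[pd.DataFrame]
    report: dict = field(default_factory=dict)


def _de_counts(de: pd.DataFrame, prefix: str) -> dict:
    sig = significant_records(de)
    return {
        f"{prefix}": int(len(sig)),
        f"{prefix}_up": int((sig["regulation"] == "up").sum()),
        f"{prefix}_down": int((sig["regulation"] == "down").sum()),
    }


def analyze_bundle(bundle: Bundle, config: PipelineConfig) -> AnalysisResult:
    """Run DE -> annotation -> intersections -> network -> triads."""
    thresholds = config.thresholds

    de = {}
    for cls, panel in bundle.panels.items():
        de[cls] = run_de(panel, thresholds)
    de["mRNA"]["symbol"] = [bundle.symbols.get(f, f)
                            for f in de["mRNA"].index]

    classes = ann.classify_lncrna(bundle.lncrnas, bundle.coding,
                                  config.bidirectional_window)
    linc_ids = set(classes.loc[classes["positional_class"] == "intergenic",
                               "lncrna_id"])
    lincs = [f for f in bundle.lncrnas if f.feature_id in linc_ids]
    cis = ann.cis_targets(lincs, bundle.coding, config.cis_window)
    cis_de = ann.cis_differential_pairs(cis, de["lncRNA"], de["mRNA"])

    inter_m = ann.intersect_mrna_targets(bundle.targets_mrna, de["mRNA"])
    inter_l = ann.intersect_lncrna_targets(bundle.targets_lncrna,
                                           de["lncRNA"])

    combined = pd.concat([de[c] for c in ("mRNA", "lncRNA", "miRNA")])
    graph = net.build_network(inter_m.pairs, inter_l.pairs,
                              bundle.interactions, combined,
                              config.score_cutoff)
    hubs = net.hub_by_degree(graph) if graph.number_of_nodes() else None
    modules = net.mine_dense_modules(graph, config.mcode)
    triads = net.extract_cerna_triads(graph)
    restricted = (net.restrict_by_function(triads, config.functional_gene_set)
                  if config.functional_gene_set is not None else None)

    enrichment = None
    query = sorted(set(significant_records(de["mRNA"]).get(
        "symbol", pd.Series(dtype=str))))
    universe = sorted(set(bundle.symbols.values()))
    if query and bundle.terms:
        enrichment = enrich(query, bundle.terms, universe)

    class_counts = classes["positional_class"].value_counts()
    report = {
        **_de_counts(de["mRNA"], "n_deg"),
        **_de_counts(de["lncRNA"], "n_del"),
        **_de_counts(de["miRNA"], "n_dem"),
        "n_dem_rescued": int(significant_records(de["miRNA"])["rescued"].sum()),
        "intersected_mrnas": inter_m.distinct_targets,
        "intersected_lncrnas": inter_l.distinct_targets,
        "cis_pairs": int(len(cis)),
        "cis_de_pairs": int(len(cis_de)),
        "lncrna_class_counts": {c: int(class_counts.get(c, 0))
                                for c in ann.POSITIONAL_CLASSES},
        "network_nodes": graph.number_of_nodes(),
        "network_edges": graph.number_of_edges(),
        "n_modules": len(modules),
        "hubs": hubs.hubs if hubs else [],
        "hub_degree": (int(hubs.ranking["degree"].iloc[0]) if hubs else 0),
        "n_triads": len(triads),
        "n_restricted_triads": (len(restricted) if restricted is not None
                                else None),
    }
    return AnalysisResult(de, classes, cis, cis_de, inter_m, inter_l, graph,
                          hubs, modules, triads, restricted, enrichment,
                          report)


def analyze_fixture_tables(config: PipelineConfig) -> AnalysisResult:
    """Replay the packaged interaction tables through the network stages."""
    fixtures = cio.read_fixture_tables()
    de_records, mirna_mrna, mirna_lncrna = \
        cio.fixtures_to_network_inputs(fixtures)
    inter_m = ann.intersect_mrna_targets(mirna_mrna, de_records)
    inter_l = ann.intersect_lncrna_targets(mirna_lncrna, de_records)
    graph = net.build_network(inter_m.pairs, inter_l.pairs, None, de_records,
                              config.score_cutoff)
    hubs = net.hub_by_degree(graph)
    modules = net.mine_dense_modules(graph, config.mcode)
    triads = net.extract_cerna_triads(graph)
    restricted = (net.restrict_by_function(triads, config.functional_gene_set)
                  if config.functional_gene_set is not None else None)
    de_by_class = {
        cls: de_records[de_records["rna_class"] == cls]
        for cls in ("mRNA", "lncRNA", "miRNA")
    }
    empty = pd.DataFrame(columns=["lincrna_id", "gene_id", "gene_symbol",
                                  "gap_bp"])
    report = {
        "n_dem": int(len(de_by_class["miRNA"])),
        "n_dem_rescued": int(de_by_class["miRNA"]["rescued"].sum()),
        "table1_rows": int(len(fixtures.table1)),
        "table2_rows": int(len(fixtures.table2)),
        "intersected_mrnas": inter_m.distinct_targets,
        "intersected_lncrnas": inter_l.distinct_targets,
        "network_nodes": graph.number_of_nodes(),
        "network_edges": graph.number_of_edges(),
        "n_modules": len(modules),
        "hubs": hubs.hubs,
        "hub_degree": int(hubs.ranking["degree"].iloc[0]),
        "n_triads": len(triads),
        "n_restricted_triads": (len(restricted) if restricted is not None
                                else None),
    }
    return AnalysisResult(
        de_by_class,
        pd.DataFrame(columns=["lncrna_id", "positional_class"]),
        empty, empty, inter_m, inter_l, graph, hubs, modules, triads,
        restricted, None, report)


def run_pipeline(config: PipelineConfig
                 ) -> tuple[dict, AnalysisResult,
                            Optional[tuple[Bundle, GroundTruth]]]:
    """Execute the configured run and write all outputs.

    Returns ``(report, result, simulated)`` where ``simulated`` is the
    (bundle, truth) pair in synthetic mode. Any stage failure raises
    :class:`StageError` after removing partial outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def track(path: Path) -> Path:
        written.append(path)
        return path

    simulated = None
    stage = "input"
    try:
        if config.fixture_mode:
            stage = "fixtures"
            result = analyze_fixture_tables(config)
        else:
            if config.simulate is not None:
                stage = "simulate"
                simulated = generate_bundle(config.simulate)
                bundle = simulated[0]
                bundle_dir = track(outdir / "bundle")
                cio.write_bundle(bundle, bundle_dir, simulated[1])
            else:
                stage = "read_inputs"
                bundle = cio.read_bundle(config.input_dir)
            stage = "analysis"
            result = analyze_bundle(bundle, config)

        stage = "export"
        for cls, de in result.de.items():
            de.to_csv(track(outdir / f"de_{cls.lower()}.tsv"), sep="\t")
        if len(result.lncrna_classes):
            result.lncrna_classes.to_csv(
                track(outdir / "lncrna_classes.tsv"), sep="\t", index=False)
        result.cis_de_pairs.to_csv(track(outdir / "cis_de_pairs.tsv"),
                                   sep="\t", index=False)
        cio.write_network_sif(result.network,
                              track(outdir / "network_edges.sif"),
                              track(outdir / "network_nodes.tsv"))
        cio.write_triads(result.triads, track(outdir / "cerna_triads.tsv"))
        if result.restricted_triads is not None:
            cio.write_triads(result.restricted_triads,
                             track(outdir / "cerna_triads_functional.tsv"))
        if result.enrichment is not None:
            result.enrichment.to_csv(track(outdir / "enrichment.tsv"),
                                     sep="\t", index=False)
        report = dict(result.report)
        report["seed"] = config.seed
        report["thresholds"] = {
            "min_abs_fc": config.thresholds.min_abs_fc,
            "max_fdr": config.thresholds.max_fdr,
            "min_flagged_samples": config.thresholds.min_flagged_samples,
            "min_intensity": config.thresholds.min_intensity,
            "rescue_raw_p": config.thresholds.rescue_raw_p,
        }
        cio.write_json_report(report, track(outdir / "report.json"))
        logger.info("pipeline finished: %d output files", len(written))
        return report, result, simulated
    except Exception as exc:
        for path in written:
            if path.is_file():
                path.unlink(missing_ok=True)
            elif path.is_dir():
                import shutil
                shutil.rmtree(path, ignore_errors=True)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
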