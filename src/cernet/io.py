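"""Delimited readers/writers for every pipeline table.

All tables are tab-delimited UTF-8 with a header row. The genomic
annotation travels as 6-column BED-like text (chrom, start, end,
feature_id, biotype, strand) with a separate feature_id -> gene_symbol
map; term annotations as GMT lines; networks as SIF-style edge lists
plus a node-attribute table. The packaged fixture tables transcribe the
published miRNA-mRNA and miRNA-lncRNA interaction tables verbatim.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import GenomicFeature
from .diffexpr import IntensityPanel
from .enrichment import TermAnnotation
from .network import CeRNATriad, triads_to_frame
from .simulate import Bundle, GroundTruth, RNA_CLASSES


class TableParseError(ValueError):
    """A delimited table row failed numeric or categorical validation."""


class DirectionConflictError(ValueError):
    """One accession appears with contradictory regulation directions."""


# ---------------------------------------------------------------------------
# generic tables
# ---------------------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=True)


def read_matrix(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design(design: dict[str, str], path: Path) -> None:
    pd.DataFrame({"sample": list(design), "group": list(design.values())}
                 ).to_csv(path, sep="\t", index=False)


def read_design(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["group"]))


def write_annotation_bed(features: Iterable[GenomicFeature],
                         path: Path) -> None:
    rows = [(f.chrom, f.start, f.end, f.feature_id, f.biotype, f.strand)
            for f in features]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_annotation_bed(path: Path,
                        symbols: dict[str, str] | None = None
                        ) -> list[GenomicFeature]:
    names = ["chrom", "start", "end", "feature_id", "biotype", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, names=names)
    symbols = symbols or {}
    return [GenomicFeature(r.feature_id, symbols.get(r.feature_id,
                                                     r.feature_id),
                           r.chrom, int(r.start), int(r.end), r.strand,
                           r.biotype)
            for r in df.itertuples(index=False)]


def write_symbol_map(symbols: dict[str, str], path: Path) -> None:
    pd.DataFrame({"feature_id": list(symbols),
                  "gene_symbol": list(symbols.values())}
                 ).to_csv(path, sep="\t", index=False)


def read_symbol_map(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["feature_id"], df["gene_symbol"]))


def write_target_table(pairs: pd.DataFrame, path: Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_target_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"mirna_id", "target_id", "target_symbol", "target_class"}
    missing = required - set(df.columns)
    if missing:
        raise TableParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_interactions(edges: pd.DataFrame, path: Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_interactions(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"node_a", "node_b", "score"} <= set(df.columns):
        raise TableParseError(f"{path}: expected node_a, node_b, score")
    bad = df[(df["score"] < 0) | (df["score"] > 1)]
    if len(bad):
        raise TableParseError(
            f"{path}: scores outside [0, 1] at rows {list(bad.index[:5])}")
    return df


def write_terms_gmt(terms: Sequence[TermAnnotation], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in terms:
            members = "\t".join(sorted(t.members))
            fh.write(f"{t.term_id}\t{t.term_name}|{t.category}\t{members}\n")


def read_terms_gmt(path: Path) -> list[TermAnnotation]:
    terms = []
    for lineno, line in enumerate(Path(path).read_text(
            encoding="utf-8").splitlines(), 1):
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise TableParseError(f"{path}:{lineno}: fewer than 3 fields")
        name, _, category = parts[1].partition("|")
        terms.append(TermAnnotation(parts[0], name,
                                    frozenset(parts[2:]),
                                    category or "custom"))
    return terms


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

def write_bundle(bundle: Bundle, outdir: Path,
                 truth: GroundTruth | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cls in RNA_CLASSES:
        panel = bundle.panels[cls]
        tag = cls.lower()
        write_matrix(panel.foreground.round(4), outdir / f"{tag}_foreground.tsv")
        write_matrix(panel.background.round(4), outdir / f"{tag}_background.tsv")
        write_matrix(panel.flags, outdir / f"{tag}_flags.tsv")
    write_design(bundle.design, outdir / "design.tsv")
    write_annotation_bed(bundle.coding + bundle.lncrnas + bundle.mirnas,
                         outdir / "annotation.bed")
    write_symbol_map(bundle.symbols, outdir / "symbols.tsv")
    write_target_table(bundle.targets_mrna, outdir / "targets_mrna.tsv")
    write_target_table(bundle.targets_lncrna, outdir / "targets_lncrna.tsv")
    write_interactions(bundle.interactions, outdir / "interactions.tsv")
    write_terms_gmt(bundle.terms, outdir / "terms.gmt")
    if truth is not None:
        with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)


def read_bundle(indir: Path) -> Bundle:
    indir = Path(indir)
    design = read_design(indir / "design.tsv")
    symbols = read_symbol_map(indir / "symbols.tsv")
    features = read_annotation_bed(indir / "annotation.bed", symbols)
    panels = {}
    for cls in RNA_CLASSES:
        tag = cls.lower()
        panels[cls] = IntensityPanel(
            rna_class=cls,
            foreground=read_matrix(indir / f"{tag}_foreground.tsv"),
            background=read_matrix(indir / f"{tag}_background.tsv"),
            flags=read_matrix(indir / f"{tag}_flags.tsv"),
            design=design,
        )
    return Bundle(
        panels=panels,
        coding=[f for f in features if f.biotype == "protein_coding"],
        lncrnas=[f for f in features if f.biotype == "lncRNA"],
        mirnas=[f for f in features if f.biotype == "miRNA"],
        targets_mrna=read_target_table(indir / "targets_mrna.tsv"),
        targets_lncrna=read_target_table(indir / "targets_lncrna.tsv"),
        interactions=read_interactions(indir / "interactions.tsv"),
        terms=read_terms_gmt(indir / "terms.gmt"),
        design=design,
        symbols=symbols,
        effect_fold=float("nan"),
    )


def read_ground_truth(path: Path) -> GroundTruth:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return GroundTruth(
        de_features=data["de_features"],
        planted_triads=[tuple(t) for t in data["planted_triads"]],
        planted_lncrna_classes=data["planted_lncrna_classes"],
        planted_cis_pairs=[tuple(p) for p in data["planted_cis_pairs"]],
    )


# ---------------------------------------------------------------------------
# packaged fixture tables (published interaction tables)
# ---------------------------------------------------------------------------

class FixtureTables(NamedTuple):
    """Parsed miRNA-mRNA (table1) and miRNA-lncRNA (table2) rows."""

    table1: pd.DataFrame
    table2: pd.DataFrame


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("cernet").joinpath("data", name)))


def _parse_fixture(path: Path, target_class: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out_rows = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        fdr_raw = rec["mirna_fdr"]
        rescued = fdr_raw.endswith("*")
        numeric = {}
        for col in ("mirna_fc", "target_fc_abs", "target_fdr"):
            try:
                numeric[col] = float(rec[col])
            except ValueError:
                raise TableParseError(
                    f"{path.name} row {i}: malformed numeric "
                    f"{col}={rec[col]!r}") from None
        try:
            mirna_fdr = float(fdr_raw.rstrip("*"))
        except ValueError:
            raise TableParseError(
                f"{path.name} row {i}: malformed numeric "
                f"mirna_fdr={fdr_raw!r}") from None
        for col in ("mirna_regulation", "target_regulation"):
            if rec[col].strip().lower() not in {"up", "down"}:
                raise TableParseError(
                    f"{path.name} row {i}: regulation must be Up/Down, "
                    f"got {rec[col]!r}")
        out_rows.append({
            "mirna_id": rec["mirna_id"],
            "mirna_name": rec["mirna_name"],
            "mirna_fc": numeric["mirna_fc"],
            "mirna_fdr": mirna_fdr,
            "mirna_rescued": rescued,
            "mirna_regulation": rec["mirna_regulation"].strip().lower(),
            "target_id": rec["target_id"],
            "target_symbol": rec["target_symbol"],
            "target_fc_abs": numeric["target_fc_abs"],
            "target_fdr": numeric["target_fdr"],
            "target_regulation": rec["target_regulation"].strip().lower(),
            "target_class": target_class,
        })
    return pd.DataFrame(out_rows)


def read_fixture_tables(table1_path: Path | None = None,
                        table2_path: Path | None = None) -> FixtureTables:
    """Load the packaged interaction tables (or user-supplied copies).

    Numeric fields are validated per row; the asterisk footnote marking
    the raw-p-rescued miRNA FDR becomes the boolean ``mirna_rescued``
    column, and regulation labels are case-normalized.
    """
    t1 = _parse_fixture(Path(table1_path) if table1_path
                        else _fixture_path("table1_mirna_mrna.tsv"), "mRNA")
    t2 = _parse_fixture(Path(table2_path) if table2_path
                        else _fixture_path("table2_mirna_lncrna.tsv"),
                        "lncRNA")
    return FixtureTables(t1, t2)


def fixtures_to_network_inputs(fixtures: FixtureTables
                               ) -> tuple[pd.DataFrame, pd.DataFrame,
                                          pd.DataFrame]:
    """Adapt the fixture tables into DE records and target-pair tables.

    Every table row yields one miRNA->target pair; differential records
    are emitted for each distinct miRNA (direction from its regulation
    column, raw-p rescue from the footnote flag) and for each distinct
    target accession. A single accession carrying contradictory
    directions raises :class:`DirectionConflictError`.
    """
    both = pd.concat([fixtures.table1, fixtures.table2], ignore_index=True)
    records: dict[str, dict] = {}
    for row in both.itertuples(index=False):
        for fid, cls, symbol, direction, fc_abs, fdr, rescued in (
                (row.mirna_name, "miRNA", row.mirna_name,
                 row.mirna_regulation,
                 max(row.mirna_fc, 1.0 / row.mirna_fc), row.mirna_fdr,
                 row.mirna_rescued),
                (row.target_id, row.target_class, row.target_symbol,
                 row.target_regulation, row.target_fc_abs, row.target_fdr,
                 False)):
            fc_ratio = fc_abs if direction == "up" else 1.0 / fc_abs
            rec = {"rna_class": cls, "symbol": symbol,
                   "regulation": direction, "fc_abs": fc_abs,
                   "fc_ratio": fc_ratio, "fdr": fdr, "p_value": np.nan,
                   "significant": True, "rescued": rescued}
            prior = records.get(fid)
            if prior is not None and prior["regulation"] != direction:
                raise DirectionConflictError(
                    f"{fid} appears with both up and down regulation")
            records[fid] = rec
    de_records = pd.DataFrame.from_dict(records, orient="index")
    de_records.index.name = "feature_id"

    def pairs(table: pd.DataFrame, source: str) -> pd.DataFrame:
        out = table[["mirna_name", "target_id", "target_symbol",
                     "target_class"]].copy()
        out = out.rename(columns={"mirna_name": "mirna_id"})
        out["source"] = source
        return out.drop_duplicates(subset=["mirna_id", "target_id"]
                                   ).reset_index(drop=True)

    return (de_records, pairs(fixtures.table1, "table1"),
            pairs(fixtures.table2, "table2"))


# ---------------------------------------------------------------------------
# network / results export
# ---------------------------------------------------------------------------

def write_network_sif(network: nx.Graph, edge_path: Path,
                      node_path: Path) -> None:
    edges = sorted((min(a, b), d.get("etype", "pp"), max(a, b))
                   for a, b, d in network.edges(data=True))
    pd.DataFrame(edges, columns=["node_a", "edge_type", "node_b"]
                 ).to_csv(edge_path, sep="\t", index=False)
    rows = [(n, d.get("rna_class", ""), d.get("regulation", ""),
             d.get("symbol", n))
            for n, d in sorted(network.nodes(data=True))]
    pd.DataFrame(rows, columns=["node", "rna_class", "regulation", "symbol"]
                 ).to_csv(node_path, sep="\t", index=False)


def write_triads(triads: Sequence[CeRNATriad], path: Path) -> None:
    triads_to_frame(triads).to_csv(path, sep="\t", index=False)


def write_json_report(report: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
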