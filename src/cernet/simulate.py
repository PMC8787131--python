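"""Seeded synthetic input bundles with planted ground truth.

The generator emulates a two-group (3 pooled samples vs 3) microarray
experiment over mRNA, lncRNA and miRNA panels: log-normal baseline
intensities, multiplicative log-normal noise, planted fold changes for
a configurable fraction of features, detection flags tied to an
unexpressed-feature mechanism, a genomic annotation realizing all four
positional lncRNA classes plus cis lincRNA-gene pairs inside the 300-kb
window, miRNA target maps, a scored gene-gene interaction table and a
term annotation. Ground truth records every planted effect so the
downstream stages can be scored for recovery.

All randomness flows from one :class:`numpy.random.Generator` seeded by
``SimulationConfig.seed``; identical configurations therefore produce
identical bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import GenomicFeature
from .config import ConfigurationError, SimulationConfig
from .diffexpr import CASE_GROUP, CONTROL_GROUP, IntensityPanel
from .enrichment import TermAnnotation

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")

#: Target shares of the four positional lncRNA classes (as observed on
#: mouse arrays: half intergenic, about a quarter antisense).
CLASS_SHARES = {
    "intergenic": 0.50,
    "antisense_overlap": 0.26,
    "sense_overlap": 0.12,
    "bidirectional": 0.12,
}

_GENE_SPACING = 1_000_000       # bp between consecutive coding genes
_GENES_PER_CHROM = 40
_BACKGROUND_RANGE = (5.0, 15.0)  # uniform background fluorescence
_ABSENT_SIGNAL_MAX = 10.0        # unexpressed probes: background-level signal
_MARGINAL_RATE = 0.05            # Marginal share among detected cells


class ConsistencyError(ValueError):
    """A planted triad references a feature missing from the bundle."""


@dataclass
class GroundTruth:
    """Planted effects underlying one synthetic bundle."""

    de_features: dict[str, dict[str, str]] = field(default_factory=dict)
    planted_triads: list[tuple[str, str, str]] = field(default_factory=list)
    planted_lncrna_classes: dict[str, str] = field(default_factory=dict)
    planted_cis_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "de_features": self.de_features,
            "planted_triads": [list(t) for t in self.planted_triads],
            "planted_lncrna_classes": self.planted_lncrna_classes,
            "planted_cis_pairs": [list(p) for p in self.planted_cis_pairs],
        }


@dataclass
class Bundle:
    """One complete synthetic input set for the pipeline."""

    panels: dict[str, IntensityPanel]
    coding: list[GenomicFeature]
    lncrnas: list[GenomicFeature]
    mirnas: list[GenomicFeature]
    targets_mrna: pd.DataFrame
    targets_lncrna: pd.DataFrame
    interactions: pd.DataFrame
    terms: list[TermAnnotation]
    design: dict[str, str]
    symbols: dict[str, str]
    effect_fold: float


def _feature_ids(config: SimulationConfig) -> dict[str, list[str]]:
    return {
        "mRNA": [f"NM_{100000 + i}" for i in range(config.n_mrna)],
        "lncRNA": [f"ENSMUSTSIM{i:08d}" for i in range(config.n_lncrna)],
        "miRNA": [f"mmu-miR-sim-{i}" for i in range(config.n_mirna)],
    }


def _allocate_classes(n: int) -> list[str]:
    """Largest-remainder allocation of the positional-class shares."""
    quotas = {c: n * s for c, s in CLASS_SHARES.items()}
    counts = {c: math.floor(q) for c, q in quotas.items()}
    leftovers = sorted(quotas, key=lambda c: quotas[c] - counts[c],
                       reverse=True)
    for c in leftovers[: n - sum(counts.values())]:
        counts[c] += 1
    out: list[str] = []
    for c in ("intergenic", "antisense_overlap", "sense_overlap",
              "bidirectional"):
        out.extend([c] * counts[c])
    return out


def _plant_directions(rng: np.random.Generator, ids: list[str],
                      n_de: int, n_absent: int
                      ) -> tuple[dict[str, str], list[str]]:
    """Choose absent features, then DE features among the expressed rest."""
    if n_de + n_absent > len(ids):
        raise ConfigurationError(
            "frac_de + frac_absent leave no room for expressed null features")
    perm = rng.permutation(len(ids))
    absent = [ids[i] for i in perm[:n_absent]]
    de_ids = [ids[i] for i in perm[n_absent:n_absent + n_de]]
    directions = {fid: ("up" if rng.random() < 0.5 else "down")
                  for fid in de_ids}
    return directions, absent


def _draw_panel(rng: np.random.Generator, rna_class: str, ids: list[str],
                directions: dict[str, str], absent: set[str],
                design: dict[str, str], config: SimulationConfig
                ) -> IntensityPanel:
    samples = list(design)
    n, s = len(ids), len(samples)
    case_cols = np.array([design[x] == CASE_GROUP for x in samples])

    mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    base = np.power(2.0, mu)
    fold = np.ones(n)
    for i, fid in enumerate(ids):
        d = directions.get(fid)
        if d == "up":
            fold[i] = config.effect_fold
        elif d == "down":
            fold[i] = 1.0 / config.effect_fold
    means = np.outer(base, np.ones(s))
    means[:, case_cols] *= fold[:, None]

    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2))
        noise = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, (n, s)))
    else:
        noise = np.ones((n, s))
    signal = means * noise

    absent_mask = np.array([fid in absent for fid in ids])
    signal[absent_mask] = rng.uniform(0.0, _ABSENT_SIGNAL_MAX,
                                      (absent_mask.sum(), s))

    background = rng.uniform(*_BACKGROUND_RANGE, (n, s))
    foreground = background + signal

    flags = np.where(rng.random((n, s)) < _MARGINAL_RATE, "M", "P")
    flags[absent_mask] = "A"

    index = pd.Index(ids, name="feature_id")
    return IntensityPanel(
        rna_class=rna_class,
        foreground=pd.DataFrame(foreground, index=index, columns=samples),
        background=pd.DataFrame(background, index=index, columns=samples),
        flags=pd.DataFrame(flags, index=index, columns=samples),
        design=design,
    )


def _place_annotation(rng: np.random.Generator, ids: dict[str, list[str]],
                      symbols: dict[str, str], truth: GroundTruth,
                      config: SimulationConfig
                      ) -> tuple[list[GenomicFeature], list[GenomicFeature],
                                 list[GenomicFeature]]:
    """Lay out coding genes on a sparse grid and realize every lncRNA class.

    Genes sit 1 Mb apart so that a lincRNA placed in a gap (or planted
    near one host gene within the 300-kb window) is unambiguous: no
    second gene can fall inside the window.
    """
    coding: list[GenomicFeature] = []
    for i, fid in enumerate(ids["mRNA"]):
        chrom = f"chr{1 + i // _GENES_PER_CHROM}"
        start = 500_000 + (i % _GENES_PER_CHROM) * _GENE_SPACING
        length = int(rng.integers(5_000, 50_000))
        strand = "+" if rng.random() < 0.5 else "-"
        coding.append(GenomicFeature(fid, symbols[fid], chrom, start,
                                     start + length, strand, "protein_coding"))

    lnc_ids = list(ids["lncRNA"])
    de_lnc = [f for f in lnc_ids if f in truth.de_features["lncRNA"]]
    de_genes = [f for f in ids["mRNA"] if f in truth.de_features["mRNA"]]
    n_cis = min(config.n_cis_de_pairs, len(de_lnc), len(de_genes))
    cis_lnc = de_lnc[:n_cis]
    cis_genes = [coding[ids["mRNA"].index(g)] for g in de_genes[:n_cis]]

    classes = _allocate_classes(len(lnc_ids))
    # planted cis lincRNAs claim intergenic slots first
    remaining_classes = list(classes)
    for _ in cis_lnc:
        if "intergenic" in remaining_classes:
            remaining_classes.remove("intergenic")
        else:
            remaining_classes.pop()
    others = [f for f in lnc_ids if f not in set(cis_lnc)]
    rng.shuffle(remaining_classes)

    lncrnas: list[GenomicFeature] = []
    for lnc_id, gene in zip(cis_lnc, cis_genes):
        gap = int(rng.integers(10_000, 250_000))
        end = gene.start - gap
        feat = GenomicFeature(lnc_id, lnc_id, gene.chrom, end - 1_000, end,
                              "+" if rng.random() < 0.5 else "-", "lncRNA")
        lncrnas.append(feat)
        truth.planted_lncrna_classes[lnc_id] = "intergenic"
        truth.planted_cis_pairs.append((lnc_id, gene.feature_id))

    intergenic_slot = 0
    for lnc_id, cls in zip(others, remaining_classes):
        host = coding[int(rng.integers(len(coding)))]
        if cls == "sense_overlap":
            feat = GenomicFeature(lnc_id, lnc_id, host.chrom, host.start + 500,
                                  host.start + 3_000, host.strand, "lncRNA")
        elif cls == "antisense_overlap":
            strand = "-" if host.strand == "+" else "+"
            feat = GenomicFeature(lnc_id, lnc_id, host.chrom, host.start + 500,
                                  host.start + 3_000, strand, "lncRNA")
        elif cls == "bidirectional":
            if host.strand == "+":
                end = host.start - 200
                feat = GenomicFeature(lnc_id, lnc_id, host.chrom, end - 1_500,
                                      end, "-", "lncRNA")
            else:
                start = host.end + 200
                feat = GenomicFeature(lnc_id, lnc_id, host.chrom, start,
                                      start + 1_500, "+", "lncRNA")
        else:  # intergenic, far from every gene (mid-gap, > 300 kb away)
            anchor = coding[intergenic_slot % len(coding)]
            # stacked occupants stay well inside the mid-gap safe zone
            offset = 2_000 * ((intergenic_slot // len(coding)) % 75)
            start = anchor.start + 525_000 + offset
            feat = GenomicFeature(lnc_id, lnc_id, anchor.chrom, start,
                                  start + 1_000,
                                  "+" if rng.random() < 0.5 else "-", "lncRNA")
            intergenic_slot += 1
        lncrnas.append(feat)
        truth.planted_lncrna_classes[lnc_id] = cls

    mirnas = [GenomicFeature(fid, fid, "chr_mirna", 10_000 * i,
                             10_000 * i + 100, "+", "miRNA")
              for i, fid in enumerate(ids["miRNA"])]
    return coding, lncrnas, mirnas


def _draw_target_maps(rng: np.random.Generator, ids: dict[str, list[str]],
                      symbols: dict[str, str], config: SimulationConfig
                      ) -> tuple[list[tuple], list[tuple]]:
    mrna_rows, lncrna_rows = [], []
    lnc_rate = max(1.0, config.targets_per_mirna / 4.0)
    for mirna in ids["miRNA"]:
        k = int(rng.poisson(config.targets_per_mirna))
        k = min(k, len(ids["mRNA"]))
        for idx in rng.choice(len(ids["mRNA"]), size=k, replace=False):
            tid = ids["mRNA"][int(idx)]
            mrna_rows.append((mirna, tid, symbols[tid], "mRNA", "simulated"))
        k2 = min(int(rng.poisson(lnc_rate)), len(ids["lncRNA"]))
        for idx in rng.choice(len(ids["lncRNA"]), size=k2, replace=False):
            tid = ids["lncRNA"][int(idx)]
            lncrna_rows.append((mirna, tid, tid, "lncRNA", "simulated"))
    return mrna_rows, lncrna_rows


def _wire_triads(rng: np.random.Generator, truth: GroundTruth,
                 mrna_rows: list[tuple], lncrna_rows: list[tuple],
                 symbols: dict[str, str], config: SimulationConfig
                 ) -> list[tuple[str, str, str]]:
    """One candidate triad per DE miRNA over disjoint DE partners.

    The candidate's target-map edges are guaranteed (added when absent);
    a ``frac_coupled_triads`` share of the candidates is returned for
    sponge-consistent wiring.
    """
    de_mirnas = sorted(truth.de_features["miRNA"])
    mrna_pool = sorted(truth.de_features["mRNA"])
    lnc_pool = sorted(truth.de_features["lncRNA"])
    rng.shuffle(mrna_pool)
    rng.shuffle(lnc_pool)
    existing_m = {(r[0], r[1]) for r in mrna_rows}
    existing_l = {(r[0], r[1]) for r in lncrna_rows}
    candidates: list[tuple[str, str, str]] = []
    for mirna in de_mirnas:
        if not mrna_pool or not lnc_pool:
            break
        mrna = mrna_pool.pop()
        lnc = lnc_pool.pop()
        if (mirna, mrna) not in existing_m:
            mrna_rows.append((mirna, mrna, symbols[mrna], "mRNA", "simulated"))
        if (mirna, lnc) not in existing_l:
            lncrna_rows.append((mirna, lnc, lnc, "lncRNA", "simulated"))
        candidates.append((lnc, mirna, mrna))
    n_coupled = int(round(config.frac_coupled_triads * len(candidates)))
    order = rng.permutation(len(candidates))
    return [candidates[i] for i in sorted(order[:n_coupled])]


def plant_sponge_signal(bundle: Bundle, truth: GroundTruth,
                        config: SimulationConfig) -> Bundle:
    """Wire each planted triad sponge-consistently, in place.

    For every (lncRNA, miRNA, mRNA) in ``truth.planted_triads``, partners
    sharing the miRNA's planted direction have their direction flipped:
    the case-group net signal of the feature is rescaled by
    ``effect_fold**±2`` so the realized group-mean ratio inverts, and
    the ground truth is updated to match.
    """
    for lnc, mirna, mrna in truth.planted_triads:
        for cls, fid in (("lncRNA", lnc), ("miRNA", mirna), ("mRNA", mrna)):
            if fid not in set(bundle.panels[cls].feature_ids):
                raise ConsistencyError(
                    f"planted triad references unknown {cls} {fid!r}")
            if fid not in truth.de_features[cls]:
                raise ConsistencyError(
                    f"planted triad references non-DE {cls} {fid!r}")
        m_dir = truth.de_features["miRNA"][mirna]
        for cls, fid in (("mRNA", mrna), ("lncRNA", lnc)):
            if truth.de_features[cls][fid] != m_dir:
                continue
            flipped = "down" if m_dir == "up" else "up"
            factor = (config.effect_fold ** 2 if flipped == "up"
                      else config.effect_fold ** -2)
            panel = bundle.panels[cls]
            case_cols = [s for s in panel.sample_ids
                         if panel.design[s] == CASE_GROUP]
            net = panel.foreground.loc[fid, case_cols] \
                - panel.background.loc[fid, case_cols]
            panel.foreground.loc[fid, case_cols] = \
                panel.background.loc[fid, case_cols] + net * factor
            truth.de_features[cls][fid] = flipped
    return bundle


def _draw_interactions(rng: np.random.Generator, gene_symbols: list[str],
                       density: float) -> pd.DataFrame:
    n = len(gene_symbols)
    n_pairs = n * (n - 1) // 2
    m = int(rng.binomial(n_pairs, density)) if n_pairs and density > 0 else 0
    rows = set()
    while len(rows) < m:
        i, j = rng.integers(0, n, 2)
        if i == j:
            continue
        rows.add((min(i, j), max(i, j)))
    data = sorted(rows)
    return pd.DataFrame({
        "node_a": [gene_symbols[i] for i, _ in data],
        "node_b": [gene_symbols[j] for _, j in data],
        "score": np.round(rng.uniform(0.0, 1.0, len(data)), 3),
    })


def _draw_terms(rng: np.random.Generator, gene_symbols: list[str],
                de_symbols: list[str]) -> list[TermAnnotation]:
    terms = []
    for t in range(20):
        size = int(rng.integers(10, 41))
        size = min(size, len(gene_symbols))
        members = [gene_symbols[int(i)]
                   for i in rng.choice(len(gene_symbols), size, replace=False)]
        terms.append(TermAnnotation(f"SIM:{t:04d}", f"simulated term {t}",
                                    frozenset(members), "custom"))
    if de_symbols:
        k = min(len(de_symbols), 25)
        picked = [de_symbols[int(i)]
                  for i in rng.choice(len(de_symbols), k, replace=False)]
        terms.append(TermAnnotation("SIM:DE", "planted differential set",
                                    frozenset(picked), "custom"))
    return terms


def generate_bundle(config: SimulationConfig
                    ) -> tuple[Bundle, GroundTruth]:
    """Generate one complete input bundle plus its ground truth.

    Deterministic in ``config`` (including its seed). Differential
    effects are planted in exactly ``round(frac_de * n)`` expressed
    features per RNA class; an additional ``round(frac_absent * n)``
    features per class are unexpressed (all cells flagged Absent, with
    background-level signal). Candidate sponge triads are drawn over
    disjoint DE features and a ``frac_coupled_triads`` share of them is
    wired sponge-consistently via :func:`plant_sponge_signal`.
    """
    rng = np.random.default_rng(config.seed)
    ids = _feature_ids(config)
    symbols = {fid: f"Gene{i:04d}"
               for i, fid in enumerate(ids["mRNA"])}

    samples = ([f"dep_{i + 1}" for i in range(config.n_per_group)]
               + [f"hc_{i + 1}" for i in range(config.n_per_group)])
    design = {s: CASE_GROUP if s.startswith("dep") else CONTROL_GROUP
              for s in samples}

    truth = GroundTruth(de_features={c: {} for c in RNA_CLASSES})
    absent_sets: dict[str, set[str]] = {}
    for cls in RNA_CLASSES:
        n = len(ids[cls])
        directions, absent = _plant_directions(
            rng, ids[cls],
            int(round(config.frac_de * n)),
            int(round(config.frac_absent * n)))
        truth.de_features[cls] = directions
        absent_sets[cls] = set(absent)

    coding, lncrnas, mirnas = _place_annotation(rng, ids, symbols, truth,
                                                config)
    mrna_rows, lncrna_rows = _draw_target_maps(rng, ids, symbols, config)
    truth.planted_triads = _wire_triads(rng, truth, mrna_rows, lncrna_rows,
                                        symbols, config)

    panels = {cls: _draw_panel(rng, cls, ids[cls], truth.de_features[cls],
                               absent_sets[cls], design, config)
              for cls in RNA_CLASSES}

    target_cols = ["mirna_id", "target_id", "target_symbol", "target_class",
                   "source"]
    de_symbols = sorted(symbols[f] for f in truth.de_features["mRNA"])
    bundle = Bundle(
        panels=panels,
        coding=coding,
        lncrnas=lncrnas,
        mirnas=mirnas,
        targets_mrna=pd.DataFrame(mrna_rows, columns=target_cols),
        targets_lncrna=pd.DataFrame(lncrna_rows, columns=target_cols),
        interactions=_draw_interactions(rng, sorted(symbols.values()),
                                        config.interaction_density),
        terms=_draw_terms(rng, sorted(symbols.values()), de_symbols),
        design=design,
        symbols=symbols,
        effect_fold=config.effect_fold,
    )
    plant_sponge_signal(bundle, truth, config)
    return bundle, truth
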