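"""Parameter containers shared across the pipeline.

All thresholds default to the study's screening criteria: absolute fold
change >= 1.5 and Benjamini-Hochberg FDR < 0.05, detection in at least
three of six arrays, and (for miRNA panels) a mean raw intensity of at
least 30 fluorescence units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional


class ConfigurationError(ValueError):
    """A configuration field holds an invalid value."""


@dataclass(frozen=True)
class DEThresholds:
    """Screening thresholds for differential-expression calls.

    Parameters
    ----------
    min_abs_fc:
        Minimum absolute fold change, ``max(ratio, 1/ratio)`` on the
        linear scale.
    max_fdr:
        BH-adjusted significance cutoff (strict ``fdr < max_fdr``).
    min_flagged_samples:
        Minimum number of arrays in which a probe must carry a Present
        or Marginal detection flag to be retained.
    min_intensity:
        Minimum mean raw foreground intensity; applied to miRNA panels
        only, boundary inclusive.
    rescue_raw_p:
        Optional raw p-value cutoff. When set, features that pass the
        fold-change filter and this raw-p cutoff but fail ``max_fdr``
        are retained and marked ``rescued``. Disabled by default.
    """

    min_abs_fc: float = 1.5
    max_fdr: float = 0.05
    min_flagged_samples: int = 3
    min_intensity: float = 30.0
    rescue_raw_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_abs_fc < 1:
            raise ConfigurationError("min_abs_fc must be >= 1")
        for name in ("max_fdr", "min_intensity"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.min_flagged_samples < 0:
            raise ConfigurationError("min_flagged_samples must be >= 0")
        if self.rescue_raw_p is not None and not 0 < self.rescue_raw_p <= 1:
            raise ConfigurationError("rescue_raw_p must lie in (0, 1]")


@dataclass(frozen=True)
class McodeParams:
    """Dense-module mining parameters (canonical MCODE defaults)."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False

    def __post_init__(self) -> None:
        if self.degree_cutoff < 1:
            raise ConfigurationError("degree_cutoff must be >= 1")
        if not 0 <= self.node_score_cutoff <= 1:
            raise ConfigurationError("node_score_cutoff must lie in [0, 1]")
        if self.k_core < 1:
            raise ConfigurationError("k_core must be >= 1")


_FRACTION_FIELDS = ("frac_de", "frac_absent", "frac_coupled_triads",
                    "interaction_density")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic two-group microarray experiment.

    The defaults emulate the study design at desk scale: three pooled
    samples per group, 5% of features carrying a planted fold change of
    2.5, log-normal multiplicative noise with a 10% coefficient of
    variation, and panels of 2000 mRNAs, 500 lncRNAs and 200 miRNAs.
    """

    n_mrna: int = 2000
    n_lncrna: int = 500
    n_mirna: int = 200
    n_per_group: int = 3
    frac_de: float = 0.05
    effect_fold: float = 2.5
    noise_cv: float = 0.10
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    frac_absent: float = 0.10
    targets_per_mirna: float = 8.0
    frac_coupled_triads: float = 0.5
    interaction_density: float = 0.01
    n_cis_de_pairs: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_mirna"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        for name in _FRACTION_FIELDS:
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.effect_fold <= 1:
            raise ConfigurationError("effect_fold must be > 1")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.baseline_log2_sd < 0:
            raise ConfigurationError("baseline_log2_sd must be >= 0")
        if self.targets_per_mirna < 0:
            raise ConfigurationError("targets_per_mirna must be >= 0")
        if self.n_cis_de_pairs < 0:
            raise ConfigurationError("n_cis_de_pairs must be >= 0")


@dataclass
class PipelineConfig:
    """End-to-end run configuration (see :func:`cernet.pipeline.run_pipeline`).

    Either ``simulate`` is set (synthetic mode), or the input paths point
    at existing tables, or ``fixture_mode`` replays the packaged
    interaction tables through the network stages.
    """

    output_dir: Path = Path("cernet_out")
    simulate: Optional[SimulationConfig] = None
    fixture_mode: bool = False
    input_dir: Optional[Path] = None
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    mcode: McodeParams = field(default_factory=McodeParams)
    cis_window: int = 300_000
    score_cutoff: float = 0.4
    bidirectional_window: int = 1_000
    functional_gene_set: Optional[set] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.input_dir is not None:
            self.input_dir = Path(self.input_dir)
        if self.cis_window <= 0:
            raise ConfigurationError("cis_window must be positive")
        if not 0 <= self.score_cutoff <= 1:
            raise ConfigurationError("score_cutoff must lie in [0, 1]")
        modes = sum([self.simulate is not None, self.fixture_mode,
                     self.input_dir is not None])
        if modes != 1:
            raise ConfigurationError(
                "exactly one of simulate / fixture_mode / input_dir required")


def config_fields(cls) -> list[str]:
    return [f.name for f in fields(cls)]
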