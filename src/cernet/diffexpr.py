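"""Microarray-style differential expression.

The model is the one used for one-colour array screens of small
designs: per-sample background subtraction, median scaling,
detection-flag and intensity filtering, a two-sample test on log2
intensities (variance-moderated by default, with a plain Welch t as an
option), and Benjamini-Hochberg control of the false discovery rate. Fold changes are reported on the linear scale as the ratio of
group means, oriented ``depression / healthy`` so that "up" means
up-regulated in the depression-microbiota recipients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEThresholds

#: Group labels fixed by the two-group contrast; fold change = CASE / CONTROL.
CASE_GROUP = "depression"
CONTROL_GROUP = "healthy"

#: Floor applied to normalized intensities before ratios and log2.
INTENSITY_FLOOR = 1e-6

_FLAG_ALIASES = {
    "P": "P", "PRESENT": "P",
    "M": "M", "MARGINAL": "M",
    "A": "A", "ABSENT": "A",
}


class NormalizationError(ValueError):
    """A sample's median net intensity is nonpositive."""


class FlagParseError(ValueError):
    """A detection flag symbol is not Present/Marginal/Absent."""


def _canonical_flag(symbol: str) -> str:
    try:
        return _FLAG_ALIASES[str(symbol).strip().upper()]
    except KeyError:
        raise FlagParseError(f"unknown detection flag {symbol!r}") from None


@dataclass
class IntensityPanel:
    """Raw probe intensities for one RNA class.

    ``foreground``, ``background`` and ``flags`` are feature x sample
    DataFrames sharing index and columns; ``design`` maps each sample id
    to one of the two group labels.
    """

    rna_class: str
    foreground: pd.DataFrame
    background: pd.DataFrame
    flags: pd.DataFrame
    design: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.rna_class not in {"mRNA", "lncRNA", "miRNA"}:
            raise ValueError(f"unknown rna_class {self.rna_class!r}")
        for name in ("background", "flags"):
            other = getattr(self, name)
            if other.shape != self.foreground.shape:
                raise ValueError(f"{name} shape differs from foreground")
            if not (other.index.equals(self.foreground.index)
                    and other.columns.equals(self.foreground.columns)):
                raise ValueError(f"{name} index/columns differ from foreground")
        missing = [s for s in self.foreground.columns if s not in self.design]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")
        groups = set(self.design[s] for s in self.foreground.columns)
        if groups != {CASE_GROUP, CONTROL_GROUP}:
            raise ValueError(
                f"design must contain exactly the groups "
                f"{{{CASE_GROUP!r}, {CONTROL_GROUP!r}}}, got {sorted(groups)}")
        self.flags = self.flags.map(_canonical_flag)

    @property
    def feature_ids(self) -> pd.Index:
        return self.foreground.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.foreground.columns

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.design[s] == group]


def collapse_duplicates(panel: IntensityPanel) -> IntensityPanel:
    """Mean-collapse replicated probe ids (as done for replicated miRNAs).

    Foreground and background are averaged per duplicate group; the flag
    of each cell is the most detected one (Present > Marginal > Absent)
    among the replicates.
    """
    if panel.feature_ids.is_unique:
        return panel
    order = {"P": 0, "M": 1, "A": 2}
    inv = {v: k for k, v in order.items()}
    fg = panel.foreground.groupby(level=0, sort=False).mean()
    bg = panel.background.groupby(level=0, sort=False).mean()
    flags = (panel.flags.map(order.get)
             .groupby(level=0, sort=False).min().map(inv.get))
    return IntensityPanel(panel.rna_class, fg, bg, flags, dict(panel.design))


def filter_by_flags(panel: IntensityPanel,
                    thresholds: DEThresholds | None = None) -> list[str]:
    """Features detected (Present or Marginal) in enough samples."""
    thresholds = thresholds or DEThresholds()
    detected = panel.flags.isin(["P", "M"]).sum(axis=1)
    keep = detected >= thresholds.min_flagged_samples
    return list(panel.feature_ids[keep])


def filter_by_intensity(panel: IntensityPanel,
                        thresholds: DEThresholds | None = None) -> list[str]:
    """miRNA low-intensity filter: mean raw foreground >= ``min_intensity``.

    The boundary is inclusive; applying the filter to a non-miRNA panel
    is a usage error.
    """
    thresholds = thresholds or DEThresholds()
    if panel.rna_class != "miRNA":
        raise ValueError("the intensity filter applies to miRNA panels only")
    keep = panel.foreground.mean(axis=1) >= thresholds.min_intensity
    return list(panel.feature_ids[keep])


def normalize_panel(panel: IntensityPanel,
                    features: Sequence[str] | None = None) -> pd.DataFrame:
    """Background-subtract and median-scale each sample.

    ``value[f, s] = (foreground[f, s] - background[f, s]) / median_s``
    where ``median_s`` is sample *s*'s median net intensity over the
    retained features. Values are returned unfloored (zero or negative
    cells are possible when background exceeds foreground).
    """
    if features is not None:
        fg = panel.foreground.loc[list(features)]
        bg = panel.background.loc[list(features)]
    else:
        fg, bg = panel.foreground, panel.background
    net = fg - bg
    medians = net.median(axis=0)
    bad = medians[medians <= 0]
    if len(bad):
        raise NormalizationError(
            f"nonpositive median net intensity for sample(s) "
            f"{list(bad.index)}")
    return net / medians


def _trigamma_inverse(y: float, iterations: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    from scipy import special
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(iterations):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(s2: np.ndarray, df_resid: float
                       ) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of gene-wise variances.

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the observed
    residual variances by matching the mean and variance of ``log s^2``
    (the moment estimator used for array data), and returns the
    posterior variances ``(d0*s0^2 + d*s^2) / (d0 + d)`` together with
    the fitted prior. An infinite d0 (homogeneous variances) collapses
    every posterior to s0^2.
    """
    from scipy import special
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df_resid / 2.0))
    if not np.isfinite(evar) or evar <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    else:
        half_d0 = _trigamma_inverse(evar)
        d0 = 2.0 * half_d0
        s0_2 = float(np.exp(emean + special.digamma(half_d0)
                            - np.log(half_d0)))
    if np.isinf(d0):
        post = np.full_like(s2, s0_2)
    else:
        post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
    return post, d0, s0_2


def test_differential(normalized: pd.DataFrame,
                      design: Mapping[str, str],
                      method: str = "moderated") -> pd.DataFrame:
    """Per-feature fold change and two-sample p-value.

    Fold change is the ratio of linear group means (case / control,
    computed on floored values). The p-value is computed on log2 of the
    floored normalized intensities, with ``method`` one of:

    ``moderated`` (default)
        Pooled-variance t with empirical-Bayes variance shrinkage
        across features (the standard treatment for two-to-four-array
        groups, where per-feature variance estimates are too unstable
        for a plain t-test); degrees of freedom are ``d0 + n - 2``.
    ``welch``
        Plain unequal-variance two-sample t-test.

    Degenerate features with zero variance in both groups get p = 1
    when the group means agree (p = 0 otherwise under ``welch``).
    """
    case = [s for s in normalized.columns if design[s] == CASE_GROUP]
    control = [s for s in normalized.columns if design[s] == CONTROL_GROUP]
    if len(case) < 2 or len(control) < 2:
        raise ValueError("each group needs at least two samples")
    floored = normalized.clip(lower=INTENSITY_FLOOR)
    mean_case = floored[case].mean(axis=1)
    mean_control = floored[control].mean(axis=1)
    fc_ratio = mean_case / mean_control

    log2 = np.log2(floored)
    if method == "welch":
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(log2[case], log2[control],
                                   axis=1, equal_var=False)
        p = np.asarray(p, dtype=float)
        degenerate = ~np.isfinite(p)
        if degenerate.any():
            same = np.isclose(log2[case].mean(axis=1),
                              log2[control].mean(axis=1))
            p[degenerate] = np.where(same[degenerate], 1.0, 0.0)
    elif method == "moderated":
        n1, n2 = len(case), len(control)
        df_resid = n1 + n2 - 2
        delta = log2[case].mean(axis=1) - log2[control].mean(axis=1)
        pooled = (log2[case].var(axis=1, ddof=1) * (n1 - 1)
                  + log2[control].var(axis=1, ddof=1) * (n2 - 1)) / df_resid
        post, d0, _ = moderate_variances(pooled.to_numpy(), df_resid)
        se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(invalid="ignore", divide="ignore"):
            t = delta.to_numpy() / se
        t = np.where(np.isfinite(t), t, 0.0)
        if np.isinf(d0):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_resid + d0)
    else:
        raise ValueError(f"unknown test method {method!r}")
    return pd.DataFrame({"fc_ratio": fc_ratio, "p_value": p},
                        index=normalized.index)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(records: pd.DataFrame,
                      thresholds: DEThresholds | None = None,
                      rna_class: str = "mRNA") -> pd.DataFrame:
    """Attach fdr / regulation / significance columns to test results.

    Significant means ``fc_abs >= min_abs_fc`` and ``fdr < max_fdr``.
    With ``rescue_raw_p`` set, fold-change-passing features whose raw p
    clears the rescue cutoff are retained with ``rescued=True`` even
    though their FDR does not.
    """
    thresholds = thresholds or DEThresholds()
    out = records.copy()
    out["rna_class"] = rna_class
    out["fc_abs"] = np.maximum(out["fc_ratio"], 1.0 / out["fc_ratio"])
    out["regulation"] = np.where(out["fc_ratio"] > 1, "up", "down")
    out["fdr"] = bh_adjust(out["p_value"])
    fc_ok = out["fc_abs"] >= thresholds.min_abs_fc
    out["significant"] = fc_ok & (out["fdr"] < thresholds.max_fdr)
    if thresholds.rescue_raw_p is not None:
        rescued = (fc_ok & ~out["significant"]
                   & (out["p_value"] < thresholds.rescue_raw_p))
        out["rescued"] = rescued
        out["significant"] |= rescued
    else:
        out["rescued"] = False
    out.index.name = "feature_id"
    return out


def run_de(panel: IntensityPanel,
           thresholds: DEThresholds | None = None,
           method: str = "moderated") -> pd.DataFrame:
    """Full differential screen of one panel.

    Order of operations: collapse replicated probes, detection-flag
    filter, (miRNA only) raw-intensity filter, normalization over the
    retained features, two-sample test (see :func:`test_differential`),
    BH adjustment, threshold calls.
    """
    thresholds = thresholds or DEThresholds()
    panel = collapse_duplicates(panel)
    retained = set(filter_by_flags(panel, thresholds))
    if panel.rna_class == "miRNA":
        retained &= set(filter_by_intensity(panel, thresholds))
    features = [f for f in panel.feature_ids if f in retained]
    if not features:
        cols = ["fc_ratio", "p_value", "rna_class", "fc_abs", "regulation",
                "fdr", "significant", "rescued"]
        return pd.DataFrame(columns=cols)
    normalized = normalize_panel(panel, features)
    records = test_differential(normalized, panel.design, method=method)
    return call_differential(records, thresholds, rna_class=panel.rna_class)


def significant_records(de: pd.DataFrame) -> pd.DataFrame:
    """Rows called significant (including any raw-p rescues)."""
    return de[de["significant"]]
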