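"""Normalization, filtering, testing and FDR control on intensity panels."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cernet.config import DEThresholds
from cernet.diffexpr import (FlagParseError, NormalizationError, bh_adjust,
                             call_differential, collapse_duplicates,
                             filter_by_flags, filter_by_intensity,
                             normalize_panel)
from cernet.diffexpr import test_differential as differential_test

from conftest import make_panel


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_normalize_is_net_intensity_over_sample_median():
    # one cell with fg 130 / bg 30 in a sample whose median net value is 50
    fg = [[130, 60], [80, 60], [40, 60]]
    bg = [[30, 10], [30, 10], [30, 10]]
    panel = make_panel(fg, bg)
    norm = normalize_panel(panel)
    assert norm.iloc[0, 0] == pytest.approx(2.0)  # (130-30)/50


def test_normalize_zero_cell_and_median_identity():
    rng = np.random.default_rng(0)
    fg = rng.uniform(50, 500, (21, 6))
    bg = np.full_like(fg, 20.0)
    fg[3, 0] = bg[3, 0]  # foreground equals background
    norm = normalize_panel(make_panel(fg, bg))
    assert norm.iloc[3, 0] == 0.0
    # median scaling identity: each sample's median normalized value is 1
    assert np.allclose(norm.median(axis=0), 1.0)


def test_normalize_rejects_nonpositive_median():
    fg = [[10, 50], [10, 50], [10, 50]]
    bg = [[30, 10], [30, 10], [30, 10]]
    with pytest.raises(NormalizationError, match="dep_1"):
        normalize_panel(make_panel(fg, bg))


# ---------------------------------------------------------------------------
# detection filters
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("flags,kept", [
    (["P", "P", "M", "A", "A", "A"], True),   # three detected of six
    (["A", "A", "A", "A", "A", "A"], False),
    (["P", "M", "A", "A", "A", "A"], False),  # only two detected
])
def test_flag_filter_requires_three_of_six(flags, kept):
    panel = make_panel(np.full((1, 6), 100.0), flags=[flags])
    retained = filter_by_flags(panel, DEThresholds())
    assert (["f0"] if kept else []) == retained


def test_unknown_flag_symbol_rejected():
    with pytest.raises(FlagParseError):
        make_panel(np.full((1, 6), 100.0), flags=[["P", "P", "X",
                                                   "A", "A", "A"]])


def test_intensity_filter_boundary_and_class_guard():
    fg = np.array([[30.0] * 6, [29.9] * 6, [0.0] * 6])
    panel = make_panel(fg, rna_class="miRNA")
    assert filter_by_intensity(panel, DEThresholds()) == ["f0"]
    with pytest.raises(ValueError, match="miRNA"):
        filter_by_intensity(make_panel(fg, rna_class="mRNA"))


def test_duplicate_probes_are_mean_collapsed():
    panel = make_panel([[10] * 6, [30] * 6], rna_class="miRNA")
    dup_index = pd.Index(["x", "x"], name="feature_id")
    panel.foreground.index = dup_index
    panel.background.index = dup_index
    panel.flags.index = dup_index
    collapsed = collapse_duplicates(panel)
    assert list(collapsed.feature_ids) == ["x"]
    assert np.allclose(collapsed.foreground.iloc[0], 20.0)


# ---------------------------------------------------------------------------
# two-sample testing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", ["welch", "moderated"])
def test_identical_groups_are_null(method):
    values = pd.DataFrame(
        np.tile([[4.0, 5.0, 6.0, 4.0, 5.0, 6.0]], (5, 1)) + \
        np.arange(5)[:, None],
        columns=["dep_1", "dep_2", "dep_3", "hc_1", "hc_2", "hc_3"])
    design = {c: ("depression" if c.startswith("dep") else "healthy")
              for c in values.columns}
    res = differential_test(values, design, method=method)
    assert np.allclose(res["fc_ratio"], 1.0)
    assert np.allclose(res["p_value"], 1.0)


@pytest.mark.parametrize("method", ["welch", "moderated"])
def test_group_swap_inverts_fold_change_and_keeps_p(method):
    rng = np.random.default_rng(5)
    cols = ["dep_1", "dep_2", "dep_3", "hc_1", "hc_2", "hc_3"]
    values = pd.DataFrame(rng.uniform(1, 10, (30, 6)), columns=cols)
    design = {c: ("depression" if c.startswith("dep") else "healthy")
              for c in cols}
    swapped = {c: ("healthy" if g == "depression" else "depression")
               for c, g in design.items()}
    a = differential_test(values, design, method=method)
    b = differential_test(values, swapped, method=method)
    assert np.allclose(a["fc_ratio"], 1.0 / b["fc_ratio"])
    assert np.allclose(a["p_value"], b["p_value"])


def welch_p_oracle(x, y):
    """Textbook Welch t: statistic, Satterthwaite df, two-sided p."""
    from scipy.stats import t as tdist
    x, y = np.asarray(x), np.asarray(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return 2 * tdist.sf(abs(t), df)


def test_welch_p_matches_textbook_formula():
    case = [2.1, 2.9, 2.4]
    control = [1.1, 1.3, 0.9]
    values = pd.DataFrame(
        [np.exp2(case + control)],
        columns=["dep_1", "dep_2", "dep_3", "hc_1", "hc_2", "hc_3"])
    design = {c: ("depression" if c.startswith("dep") else "healthy")
              for c in values.columns}
    res = differential_test(values, design, method="welch")
    assert res["p_value"].iloc[0] == pytest.approx(
        welch_p_oracle(case, control), rel=1e-12)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript unavailable")
def test_moderated_t_matches_limma(tmp_path):
    """Cross-check the in-package variance shrinkage against limma."""
    rng = np.random.default_rng(42)
    n = 150
    # heterogeneous per-feature variances so the prior df is finite
    d0, s0 = 6.0, 0.3
    sd = s0 * np.sqrt(d0 / rng.chisquare(d0, n))
    log2x = rng.normal(7.0, 1.0, n)[:, None] + \
        rng.normal(0.0, sd[:, None], (n, 6))
    log2x[:10, :3] += 1.5  # a few real effects
    cols = ["dep_1", "dep_2", "dep_3", "hc_1", "hc_2", "hc_3"]
    values = pd.DataFrame(np.exp2(log2x), columns=cols)
    design = {c: ("depression" if c.startswith("dep") else "healthy")
              for c in cols}
    ours = differential_test(values, design, method="moderated")

    mat = tmp_path / "m.tsv"
    pd.DataFrame(log2x, columns=cols).to_csv(mat, sep="\t", index=False)
    out = tmp_path / "p.tsv"
    script = tmp_path / "limma.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{mat}"))
        design <- cbind(Intercept=1, Dep=c(1,1,1,0,0,0))
        fit <- eBayes(lmFit(x, design))
        write.table(data.frame(p=fit$p.value[, "Dep"]), "{out}",
                    sep="\t", row.names=FALSE)
    """))
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    limma_p = pd.read_csv(out, sep="\t")["p"].to_numpy()
    assert np.allclose(ours["p_value"], limma_p, rtol=1e-4, atol=1e-10)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def bh_oracle(p):
    """Direct evaluation of the step-up definition (O(m^2))."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    sorted_p = [p[i] for i in order]
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = min(1.0, min(sorted_p[j] * m / (j + 1)
                            for j in range(rank, m)))
    return q


def test_bh_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=12))
def test_bh_matches_bruteforce_oracle(p):
    assert np.allclose(bh_adjust(p), bh_oracle(p))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                max_size=12), st.randoms(use_true_random=False))
def test_bh_permutation_invariant_and_monotone(p, rnd):
    base = bh_adjust(p)
    perm = list(range(len(p)))
    rnd.shuffle(perm)
    shuffled = bh_adjust([p[i] for i in perm])
    assert np.allclose([base[i] for i in perm], shuffled)
    # monotone nondecreasing in sorted-p order
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(np.asarray(base)[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# significance calls
# ---------------------------------------------------------------------------

def test_thresholds_and_raw_p_rescue():
    records = pd.DataFrame(
        {"fc_ratio": [1.6, 1.49, 0.4718, 2.0],
         "p_value": [0.001, 0.0001, 0.04, 0.6]},
        index=["a", "b", "c", "d"])
    out = call_differential(records, DEThresholds(rescue_raw_p=0.05))
    assert bool(out.loc["a", "significant"])
    assert not bool(out.loc["b", "significant"])       # fc boundary
    assert not bool(out.loc["d", "significant"])
    # 'c' fails FDR (BH over the four p's) but passes raw p and fold change
    assert out.loc["c", "fdr"] >= 0.05
    assert bool(out.loc["c", "rescued"]) and bool(out.loc["c", "significant"])
    # without rescue it is simply not significant
    plain = call_differential(records, DEThresholds())
    assert not bool(plain.loc["c", "significant"])


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.floats(min_value=1e-3, max_value=1e3))
def test_absolute_fold_change_is_reciprocal_invariant(ratio):
    records = pd.DataFrame({"fc_ratio": [ratio, 1.0 / ratio],
                            "p_value": [0.5, 0.5]}, index=["x", "y"])
    out = call_differential(records)
    assert out["fc_abs"].iloc[0] == pytest.approx(out["fc_abs"].iloc[1])
    assert out["fc_abs"].iloc[0] >= 1.0
    expected = "up" if ratio > 1 else "down"
    if ratio != 1.0:
        assert out["regulation"].iloc[0] == expected
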