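"""Negative-binomial induction testing with the study thresholds.

Calls TPA-induced and downregulated genes per genetic background from
normalized counts. The per-gene test is a conditional exact NB test: given
the total normalized count of a gene across both conditions, how extreme is
the observed split between condition sums when each condition sum is NB with
a common per-sample mean? This is the split test of classical count-based
differential expression, summed exactly (numerically windowed for large
totals). A gene is *induced* when adj-p <= 0.01 with fold change >= 1.10 in
the concordant direction in at least one read class and no significant
opposite call in the other class; *downregulated* symmetrically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import CountTable

__all__ = [
    "adjust_bh",
    "estimate_dispersions",
    "nb_test",
    "test_contrast",
    "call_regulated",
    "InductionTester",
]

_DISPERSION_FLOOR = 1e-8


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_dispersions(
    counts_a: np.ndarray, counts_b: np.ndarray, floor: float = _DISPERSION_FLOOR
) -> np.ndarray:
    """Per-gene NB dispersion by method of moments, stabilized by a trend.

    The raw per-gene estimate pools within-condition variances:
    ``alpha_g = (s2_g - mu_g) / mu_g**2``. With few replicates this estimate
    collapses to zero for a sizeable fraction of genes even under genuine
    overdispersion, which makes downstream tests anti-conservative; we
    therefore take the maximum of the gene estimate and a mean-binned trend
    of the positive estimates (conservative "maximum" sharing, no shrinkage).
    """
    a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    mu = np.concatenate([a, b], axis=0).mean(axis=0)

    # pooled within-condition variance (ddof=1 where possible)
    parts, dofs = [], 0
    for m in (a, b):
        if m.shape[0] >= 2:
            parts.append(m.var(axis=0, ddof=1) * (m.shape[0] - 1))
            dofs += m.shape[0] - 1
    if dofs == 0:
        s2 = np.zeros_like(mu)
    else:
        s2 = sum(parts) / dofs

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - mu) / np.where(mu > 0, mu**2, np.inf)
    raw = np.where(np.isfinite(raw), raw, 0.0)

    # mean-binned trend of positive raw estimates
    trend = np.zeros_like(mu)
    ok = mu > 0
    if ok.sum() >= 10:
        logmu = np.log(mu[ok])
        edges = np.quantile(logmu, np.linspace(0, 1, 11))
        which = np.clip(np.searchsorted(edges, logmu, side="right") - 1, 0, 9)
        fills = np.zeros(10)
        overall = max(float(np.mean(np.maximum(raw[ok], 0.0))), 0.0)
        for k in range(10):
            in_bin = which == k
            if in_bin.sum() >= 5:
                fills[k] = float(np.mean(np.maximum(raw[ok][in_bin], 0.0)))
            else:
                fills[k] = overall
        trend[ok] = fills[which]

    return np.clip(np.maximum(raw, trend), floor, None)


def _nb_logpmf(k: np.ndarray, mean: float, alpha: float) -> np.ndarray:
    """log pmf of NB with Var = mean + alpha * mean**2 (Poisson as alpha->0)."""
    k = np.asarray(k, dtype=float)
    if mean <= 0:
        return np.where(k == 0, 0.0, -np.inf)
    if alpha < 1e-12:
        return k * np.log(mean) - mean - gammaln(k + 1.0)
    r = 1.0 / alpha
    return (
        gammaln(k + r) - gammaln(r) - gammaln(k + 1.0)
        + r * np.log(r / (r + mean)) + k * np.log(mean / (r + mean))
    )


def _exact_split_pvalue(sa: int, sb: int, n_a: int, n_b: int, alpha_disp: float) -> float:
    """Conditional exact NB p-value for the split (sa, sb) of K = sa + sb.

    Condition sums are NB with means ``n * mu0`` and dispersion ``alpha/n``;
    the two-sided p-value sums the joint probabilities of all splits no more
    likely than the observed one, normalized over all splits of K.
    """
    K = sa + sb
    if K == 0:
        return 1.0
    mu0 = K / (n_a + n_b)
    mean_a = n_a * mu0
    if K <= 30_000:
        grid = np.arange(K + 1)
    else:
        # the joint split pmf is log-concave in a, so only the mode
        # neighbourhood (denominator mass) and the neighbourhoods of the
        # observed split and its mirror (numerator boundary) matter
        var_a = mean_a + (alpha_disp / n_a) * mean_a**2
        w = int(12 * np.sqrt(var_a)) + 50
        mode = int(round(mean_a))
        mirror = int(round(2 * mean_a - sa))
        pieces = [
            np.arange(max(0, c - w), min(K, c + w) + 1)
            for c in (mode, sa, mirror)
        ]
        grid = np.unique(np.concatenate(pieces))
    la = _nb_logpmf(grid, mean_a, alpha_disp / n_a)
    lb = _nb_logpmf(K - grid, n_b * mu0, alpha_disp / n_b)
    joint = la + lb
    m = joint.max()
    probs = np.exp(joint - m)
    total = probs.sum()
    obs = probs[np.searchsorted(grid, sa)]
    p = probs[probs <= obs * (1.0 + 1e-12)].sum() / total
    return float(min(p, 1.0))


def nb_test(
    counts_condition_a,
    counts_condition_b,
    size_factors_a=None,
    size_factors_b=None,
    dispersion: float | np.ndarray | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Two-sided NB test per gene between two conditions.

    Parameters are per-replicate count matrices (replicates x genes or a
    Series/1-D array per single replicate) plus optional per-replicate size
    factors. Returns a DataFrame with base_mean, log2fc (B over A, computed on
    normalized means with a pseudocount), and the raw p-value. All-zero genes
    get p = 1 and log2fc = 0.
    """
    a = np.atleast_2d(np.asarray(counts_condition_a, dtype=float))
    b = np.atleast_2d(np.asarray(counts_condition_b, dtype=float))
    if size_factors_a is not None:
        a = a / np.asarray(size_factors_a, dtype=float)[:, None]
    if size_factors_b is not None:
        b = b / np.asarray(size_factors_b, dtype=float)[:, None]
    n_a, n_b = a.shape[0], b.shape[0]
    n_genes = a.shape[1]
    if b.shape[1] != n_genes:
        raise ValueError("conditions must cover the same genes")

    if dispersion is None:
        disp = estimate_dispersions(a, b)
    else:
        disp = np.broadcast_to(np.asarray(dispersion, dtype=float), (n_genes,))
        disp = np.clip(disp, _DISPERSION_FLOOR, None)

    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    lfc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)

    sa = np.rint(a.sum(axis=0)).astype(np.int64)
    sb = np.rint(b.sum(axis=0)).astype(np.int64)
    pvals = np.ones(n_genes)
    for g in range(n_genes):
        if sa[g] + sb[g] > 0:
            pvals[g] = _exact_split_pvalue(int(sa[g]), int(sb[g]), n_a, n_b,
                                           float(disp[g]))
    lfc = np.where(sa + sb == 0, 0.0, lfc)

    return pd.DataFrame(
        {
            "base_mean": (mean_a * n_a + mean_b * n_b) / (n_a + n_b),
            "log2fc": lfc,
            "pvalue": pvals,
            "dispersion": disp,
        }
    )


def test_contrast(
    table: CountTable,
    background: str,
    read_class: str,
    size_factors: pd.Series | None = None,
    condition_a: str = "resting",
    condition_b: str = "TPA",
    dispersion: float | None = None,
    alpha: float = 0.01,
    min_change: float = 0.10,
) -> pd.DataFrame:
    """Test stimulation response for one background and read class.

    ``size_factors`` must be comparable across the samples of this contrast
    (i.e. computed within the read class); they are used as given, so
    rescaling counts and factors by the same constant leaves calls unchanged.
    Returns per-gene statistics with BH-adjusted p-values and a per-class
    call in {induced, downregulated, unchanged}.
    """
    sub_a = table.select(read_class=read_class, background=background,
                         condition=condition_a)
    sub_b = table.select(read_class=read_class, background=background,
                         condition=condition_b)
    if len(sub_a.samples) == 0 or len(sub_b.samples) == 0:
        raise ValueError(f"no samples for background={background!r} class={read_class!r}")

    def _factors(sub):
        if size_factors is None:
            return np.ones(len(sub.samples))
        return np.array([size_factors[s.label()] for s in sub.samples])

    fa, fb = _factors(sub_a), _factors(sub_b)

    res = nb_test(
        sub_a.counts.to_numpy().T,
        sub_b.counts.to_numpy().T,
        fa,
        fb,
        dispersion=dispersion,
    )
    res.index = table.gene_ids
    res["padj"] = adjust_bh(res["pvalue"].to_numpy())
    min_lfc = np.log2(1.0 + min_change)
    call = np.where(
        (res["padj"] <= alpha) & (res["log2fc"] >= min_lfc), "induced",
        np.where((res["padj"] <= alpha) & (res["log2fc"] <= -min_lfc),
                 "downregulated", "unchanged"),
    )
    res["call"] = call
    res["read_class"] = read_class
    return res


def call_regulated(
    results_total: pd.DataFrame,
    results_intronic: pd.DataFrame,
    alpha: float = 0.01,
    min_change: float = 0.10,
    rule: str = "either",
) -> pd.Series:
    """Combine total and intronic evidence into one per-gene call.

    ``either`` (default): induced if at least one read class calls induced and
    the other does not call downregulated; symmetric for downregulation.
    ``both``: both classes must agree.
    A gene present in only one read class is evaluated on that class alone.
    """
    if rule not in {"either", "both"}:
        raise ValueError("rule must be 'either' or 'both'")
    genes = results_total.index.union(results_intronic.index)
    combined = pd.Series("unchanged", index=genes, dtype=object)
    for g in genes:
        calls = []
        for res in (results_total, results_intronic):
            if g in res.index:
                calls.append(res.at[g, "call"])
        if rule == "either":
            up = "induced" in calls and "downregulated" not in calls
            down = "downregulated" in calls and "induced" not in calls
        else:
            up = all(c == "induced" for c in calls) and calls
            down = all(c == "downregulated" for c in calls) and calls
        if up:
            combined[g] = "induced"
        elif down:
            combined[g] = "downregulated"
    return combined


class InductionTester(BaseEstimator):
    """Per-background induction calling over both read classes.

    Attributes (after ``fit``)
    --------------------------
    results_ : dict (background, read_class) -> per-gene statistics frame.
    calls_ : dict background -> combined per-gene call series.
    """

    def __init__(self, alpha: float = 0.01, min_change: float = 0.10,
                 dispersion: float | None = None, rule: str = "either"):
        self.alpha = alpha
        self.min_change = min_change
        self.dispersion = dispersion
        self.rule = rule

    def fit(self, table: CountTable, size_factors: pd.Series | None = None,
            backgrounds: tuple[str, ...] | None = None):
        if size_factors is None:
            from .normalization import per_class_size_factors

            size_factors = per_class_size_factors(table)
        self.size_factors_ = size_factors
        if backgrounds is None:
            backgrounds = tuple(dict.fromkeys(s.background for s in table.samples))
        results: dict[tuple[str, str], pd.DataFrame] = {}
        calls: dict[str, pd.Series] = {}
        for bg in backgrounds:
            for rc in ("total", "intronic"):
                results[(bg, rc)] = test_contrast(
                    table, bg, rc, size_factors,
                    dispersion=self.dispersion,
                    alpha=self.alpha, min_change=self.min_change,
                )
            calls[bg] = call_regulated(
                results[(bg, "total")], results[(bg, "intronic")],
                self.alpha, self.min_change, self.rule,
            )
        self.results_ = results
        self.calls_ = calls
        return self
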