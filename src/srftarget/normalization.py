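"""Invariant-gene normalization of count tables across samples.

For each sample the per-gene difference to a reference sample is computed
(log2 scale with a pseudocount by default). Genes whose difference lies
within one standard deviation of the mean difference (``mu_diff``), under a
quasi-normal assumption, form the sample's *invariant set*; the sample's
size factor is ``2 ** mean(d over invariant genes)``, so dividing raw counts
by it puts every sample on the reference scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import CountTable

__all__ = [
    "pairwise_log_differences",
    "select_invariant_genes",
    "compute_size_factors",
    "InvariantNormalizer",
]


def pairwise_log_differences(
    table: CountTable | pd.DataFrame,
    sample_a: str,
    sample_b: str,
    pseudocount: float = 0.5,
    diff_scale: str = "log2",
) -> pd.Series:
    """Per-gene difference of sample_b relative to sample_a.

    ``log2`` scale: ``d_g = log2(count_b + pc) - log2(count_a + pc)``;
    ``linear`` scale: plain count difference (pseudocount ignored).
    """
    if pseudocount <= 0 and diff_scale == "log2":
        raise ValueError("pseudocount must be > 0 on the log2 scale")
    counts = table.counts if isinstance(table, CountTable) else table
    for s in (sample_a, sample_b):
        if s not in counts.columns:
            raise KeyError(f"unknown sample {s!r}")
    a = counts[sample_a].astype(float)
    b = counts[sample_b].astype(float)
    if diff_scale == "log2":
        return np.log2(b + pseudocount) - np.log2(a + pseudocount)
    if diff_scale == "linear":
        return b - a
    raise ValueError(f"diff_scale must be 'log2' or 'linear', got {diff_scale!r}")


def select_invariant_genes(d: pd.Series) -> pd.Index:
    """Genes with ``|d_g - mu_diff| <= sigma_diff`` (population sigma).

    If every difference is identical (sigma = 0) all genes are kept.
    """
    if len(d) < 2:
        raise ValueError("need at least 2 genes to select an invariant set")
    mu = float(d.mean())
    sigma = float(d.std(ddof=0))
    if sigma == 0.0:
        return d.index
    return d.index[(d - mu).abs() <= sigma]


@dataclass
class NormalizationResult:
    """Per-sample statistics of one invariant-gene normalization."""

    reference: str
    mu_diff: pd.Series
    sigma_diff: pd.Series
    n_invariant: pd.Series
    size_factors: pd.Series
    invariant_genes: dict[str, pd.Index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mu_diff": self.mu_diff,
                "sigma_diff": self.sigma_diff,
                "n_invariant": self.n_invariant,
                "size_factor": self.size_factors,
            }
        )


class InvariantNormalizer(BaseEstimator):
    """Scales samples to a reference via invariant-gene size factors.

    Parameters
    ----------
    reference : sample label to normalize against; default first column.
    pseudocount : added before taking log2 of counts.
    diff_scale : ``log2`` (default) or ``linear`` differences.

    Attributes (after ``fit``)
    --------------------------
    size_factors_ : per-sample factors; the reference's is exactly 1.
    mu_diff_, sigma_diff_ : mean/population-sd of the difference vectors.
    invariant_genes_ : per-sample invariant gene index.
    """

    def __init__(self, reference: str | None = None, pseudocount: float = 0.5,
                 diff_scale: str = "log2"):
        self.reference = reference
        self.pseudocount = pseudocount
        self.diff_scale = diff_scale

    def fit(self, table: CountTable | pd.DataFrame, y=None):
        counts = table.counts if isinstance(table, CountTable) else table
        if counts.shape[0] == 0 or counts.shape[1] == 0:
            raise ValueError("empty count table")
        ref = self.reference if self.reference is not None else counts.columns[0]
        if ref not in counts.columns:
            raise KeyError(f"reference sample {ref!r} not in table")

        mu, sigma, n_inv, factors = {}, {}, {}, {}
        inv_sets: dict[str, pd.Index] = {}
        for col in counts.columns:
            if col == ref:
                mu[col], sigma[col] = 0.0, 0.0
                inv_sets[col] = counts.index
                n_inv[col] = len(counts.index)
                factors[col] = 1.0
                continue
            # genes with zero counts in both samples carry no scale information
            informative = (counts[col] > 0) | (counts[ref] > 0)
            if informative.sum() < 2:
                raise ValueError(f"sample {col!r} shares no informative genes with reference")
            d = pairwise_log_differences(
                counts.loc[informative], ref, col, self.pseudocount, self.diff_scale
            )
            inv = select_invariant_genes(d)
            mu[col] = float(d.mean())
            sigma[col] = float(d.std(ddof=0))
            inv_sets[col] = inv
            n_inv[col] = len(inv)
            if self.diff_scale == "log2":
                factors[col] = float(2.0 ** d.loc[inv].mean())
            else:
                ref_mean = counts.loc[inv, ref].mean()
                factors[col] = float(counts.loc[inv, col].mean() / max(ref_mean, 1e-12))

        self.reference_ = ref
        self.mu_diff_ = pd.Series(mu)
        self.sigma_diff_ = pd.Series(sigma)
        self.n_invariant_ = pd.Series(n_inv)
        self.size_factors_ = pd.Series(factors)
        self.invariant_genes_ = inv_sets
        return self

    def transform(self, table: CountTable | pd.DataFrame) -> pd.DataFrame:
        """Raw counts divided by the fitted size factors (float result)."""
        counts = table.counts if isinstance(table, CountTable) else table
        missing = [c for c in counts.columns if c not in self.size_factors_.index]
        if missing:
            raise KeyError(f"samples not seen during fit: {missing}")
        return counts / self.size_factors_[counts.columns]

    def fit_transform(self, table, y=None) -> pd.DataFrame:
        return self.fit(table).transform(table)

    def result_(self) -> NormalizationResult:
        return NormalizationResult(
            self.reference_, self.mu_diff_, self.sigma_diff_, self.n_invariant_,
            self.size_factors_, self.invariant_genes_,
        )


def per_class_size_factors(
    table: CountTable,
    pseudocount: float = 0.5,
    diff_scale: str = "log2",
) -> pd.Series:
    """Size factors computed separately within each read class.

    Total and intronic columns are different count universes (intronic reads
    are a small subset of the library), so each read class is normalized
    against its own first sample; the returned factors are comparable within
    a class, which is what differential testing needs.
    """
    out = {}
    for rc in dict.fromkeys(s.read_class for s in table.samples):
        sub = table.select(read_class=rc)
        norm = InvariantNormalizer(pseudocount=pseudocount,
                                   diff_scale=diff_scale).fit(sub)
        out.update(norm.size_factors_.to_dict())
    all_labels = [s.label() for s in table.samples]
    return pd.Series(out)[all_labels]


def compute_size_factors(
    table: CountTable | pd.DataFrame,
    reference_sample: str | None = None,
    pseudocount: float = 0.5,
    diff_scale: str = "log2",
) -> NormalizationResult:
    """Functional wrapper around :class:`InvariantNormalizer`."""
    norm = InvariantNormalizer(reference_sample, pseudocount, diff_scale).fit(table)
    return norm.result_()
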