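"""Significant-interaction calling, A/B compartment PCA, and TSS linking.

The expected model accounts for linear genomic distance and sequencing depth:
``expected(i, j) = distance_mean(|i - j|) * c_i * c_j`` with per-bin coverage
factors ``c_i = bin_total / mean(bin_total)`` and per-distance mean contacts
(log2-pooled above 20 bins to stabilize sparse long-range distances). A bin
pair is a significant interaction when the Poisson upper-tail p <= 0.05 and
``Z = (obs - exp) / sqrt(exp) >= 2``. Compartments are the first principal
component of the Pearson correlation matrix of observed/expected, oriented
so score correlates positively with gene (TSS) density and scaled by the
fraction of variance PC1 explains; bins with score > +100 are A, < -100 B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import ContactMap, GenomicIntervalSet

__all__ = [
    "ExpectedModel",
    "fit_expected",
    "call_interactions",
    "InteractionCaller",
    "CompartmentTrack",
    "compartment_pca",
    "CompartmentPCA",
    "link_tss",
]

SMOOTH_ABOVE = 20  # bins; larger distances pooled into log2-spaced bands


@dataclass
class ExpectedModel:
    """Distance- and coverage-aware expected contact counts."""

    n_bins: int
    coverage: np.ndarray  # c_i, nan for masked (zero-coverage) bins
    covered: np.ndarray  # bool mask
    raw_distance_means: np.ndarray  # per-distance mean over covered pairs
    smoothed_distance_means: np.ndarray
    distance_pair_counts: np.ndarray  # covered pairs per distance

    def expected(self, i, j) -> np.ndarray:
        d = np.abs(np.asarray(j) - np.asarray(i))
        return self.smoothed_distance_means[d] * self.coverage[i] * self.coverage[j]

    def expected_matrix(self) -> np.ndarray:
        idx = np.arange(self.n_bins)
        return self.expected(idx[:, None], idx[None, :])


def fit_expected(cmap: ContactMap, smooth_above: int = SMOOTH_ABOVE) -> ExpectedModel:
    """Fit the distance/coverage expected model on one contact map.

    Distance means average over *all* covered-bin pairs at each separation
    (zeros included); bins with zero total coverage are masked and never
    contribute.
    """
    n = cmap.n_bins
    dense = cmap.to_dense()
    totals = dense.sum(axis=1)
    covered = totals > 0
    n_cov = int(covered.sum())
    if n_cov < 50:
        raise ValueError(f"need >= 50 covered bins, got {n_cov}")
    coverage = np.full(n, np.nan)
    coverage[covered] = totals[covered] / totals[covered].mean()

    cov_idx = np.flatnonzero(covered)
    sub = dense[np.ix_(cov_idx, cov_idx)]
    d_sub = np.abs(np.subtract.outer(cov_idx, cov_idx))
    iu = np.triu_indices(n_cov)
    dists = d_sub[iu]
    obs = sub[iu]
    obs_sum = np.bincount(dists, weights=obs, minlength=n)
    pair_n = np.bincount(dists, minlength=n).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(pair_n > 0, obs_sum / pair_n, 0.0)

    smoothed = raw.copy()
    lo = smooth_above + 1
    while lo < n:
        hi = min(n, lo * 2)
        band = slice(lo, hi)
        tot_pairs = pair_n[band].sum()
        if tot_pairs > 0:
            smoothed[band] = obs_sum[band].sum() / tot_pairs
        lo = hi
    return ExpectedModel(n, coverage, covered, raw, smoothed, pair_n)


def call_interactions(
    cmap: ContactMap,
    model: ExpectedModel,
    alpha: float = 0.05,
    z_min: float = 2.0,
    min_distance_bins: int = 2,
) -> pd.DataFrame:
    """Score every stored pair at distance >= ``min_distance_bins``.

    Pairs touching a masked bin are skipped. Unstored (zero-count) pairs are
    never significant under an upper-tail test and are not evaluated.
    """
    i, j, c = cmap.bins_i, cmap.bins_j, cmap.counts
    keep = (j - i >= min_distance_bins) & model.covered[i] & model.covered[j]
    i, j, c = i[keep], j[keep], c[keep].astype(float)
    exp = model.expected(i, j)
    ok = exp > 0
    i, j, c, exp = i[ok], j[ok], c[ok], exp[ok]
    z = (c - exp) / np.sqrt(exp)
    p = stats.poisson.sf(c - 1, exp)
    return pd.DataFrame(
        {
            "bin_i": i,
            "bin_j": j,
            "observed": c.astype(int),
            "expected": exp,
            "z": z,
            "p": p,
            "significant": (p <= alpha) & (z >= z_min),
        }
    )


class InteractionCaller(BaseEstimator):
    """Estimator facade: fit the expected model, then call interactions.

    Attributes (after ``fit``): ``model_`` (:class:`ExpectedModel`) and
    ``calls_`` (the interaction table for the fitted map).
    """

    def __init__(self, alpha: float = 0.05, z_min: float = 2.0,
                 min_distance_bins: int = 2, smooth_above: int = SMOOTH_ABOVE):
        self.alpha = alpha
        self.z_min = z_min
        self.min_distance_bins = min_distance_bins
        self.smooth_above = smooth_above

    def fit(self, cmap: ContactMap, y=None):
        self.model_ = fit_expected(cmap, self.smooth_above)
        self.calls_ = call_interactions(
            cmap, self.model_, self.alpha, self.z_min, self.min_distance_bins
        )
        return self

    def predict(self, cmap: ContactMap) -> pd.DataFrame:
        """Interaction calls for a map under the already-fitted model."""
        return call_interactions(cmap, self.model_, self.alpha, self.z_min,
                                 self.min_distance_bins)


@dataclass
class CompartmentTrack:
    """Per-bin compartment score and A/B label."""

    scores: np.ndarray  # nan for masked bins
    labels: np.ndarray  # "A", "B" or "." (unassigned / masked)
    threshold: float


def compartment_pca(
    cmap: ContactMap,
    model: ExpectedModel,
    orientation_track: np.ndarray,
    threshold: float = 100.0,
) -> CompartmentTrack:
    """PC1 of the O/E correlation matrix, oriented and scaled.

    Sign is chosen so the score correlates positively with
    ``orientation_track`` (gene/TSS density per bin: A regions are
    gene-rich). Scores carry the strength of the compartment signal:
    ``score_i = 1000 * (lambda_1 / (trace/2)) * sqrt(n) * v1_i``, the unit
    PC1 loading weighted by the variance it explains, normalized so that a
    PC1 explaining half the correlation variance (a strongly
    compartmentalized map) sends unit loadings to +-1000. A structureless
    map explains only the random-matrix share of the variance and nearly all
    bins stay inside the +-100 unassigned band.
    """
    cov_idx = np.flatnonzero(model.covered)
    if len(cov_idx) < 50:
        raise ValueError("need >= 50 covered bins for compartment PCA")
    dense = cmap.to_dense()[np.ix_(cov_idx, cov_idx)]
    exp = model.expected_matrix()[np.ix_(cov_idx, cov_idx)]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(exp > 0, dense / exp, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr, nan=0.0)
    vals, vecs = np.linalg.eigh(corr)
    pc1 = vecs[:, -1]
    explained = vals[-1] / max(vals.sum(), 1e-12)

    track = np.asarray(orientation_track, dtype=float)[cov_idx]
    if np.std(track) > 0 and np.std(pc1) > 0:
        if np.corrcoef(pc1, track)[0, 1] < 0:
            pc1 = -pc1
    scores_cov = 1000.0 * (explained / 0.5) * np.sqrt(len(cov_idx)) * pc1

    scores = np.full(model.n_bins, np.nan)
    scores[cov_idx] = scores_cov
    labels = np.full(model.n_bins, ".", dtype=object)
    labels[cov_idx] = np.where(
        scores_cov > threshold, "A", np.where(scores_cov < -threshold, "B", ".")
    )
    return CompartmentTrack(scores, labels, threshold)


class CompartmentPCA(BaseEstimator):
    """Estimator facade over :func:`compartment_pca`.

    Attributes (after ``fit``): ``scores_``, ``labels_``, ``track_``.
    """

    def __init__(self, threshold: float = 100.0, smooth_above: int = SMOOTH_ABOVE):
        self.threshold = threshold
        self.smooth_above = smooth_above

    def fit(self, cmap: ContactMap, orientation_track: np.ndarray,
            model: ExpectedModel | None = None):
        if model is None:
            model = fit_expected(cmap, self.smooth_above)
        self.model_ = model
        self.track_ = compartment_pca(cmap, model, orientation_track,
                                      self.threshold)
        self.scores_ = self.track_.scores
        self.labels_ = self.track_.labels
        return self

    def fit_transform(self, cmap, orientation_track, model=None) -> np.ndarray:
        return self.fit(cmap, orientation_track, model).scores_


def link_tss(
    tss: GenomicIntervalSet,
    sites,
    calls: pd.DataFrame,
    bin_size: int,
) -> dict[str, list[int]]:
    """Map each TSS to the site-bearing bins it significantly interacts with.

    ``sites`` is a consensus peak frame (summit column) or an interval set;
    a site's bin is the bin of its summit. A TSS is linked to a site bin iff
    the (tss_bin, site_bin) pair is a significant interaction call.
    """
    if isinstance(sites, pd.DataFrame):
        sub = sites[sites["retained"]] if "retained" in sites else sites
        site_bins = {int(s) // bin_size for s in sub["summit"]}
    else:
        site_bins = {iv.bin(bin_size) for iv in sites}

    sig = calls[calls["significant"]]
    partners: dict[int, set[int]] = {}
    for bi, bj in zip(sig["bin_i"], sig["bin_j"]):
        partners.setdefault(int(bi), set()).add(int(bj))
        partners.setdefault(int(bj), set()).add(int(bi))

    links: dict[str, list[int]] = {}
    for k, iv in enumerate(tss):
        name = iv.name if iv.name is not None else f"tss{k}"
        tbin = iv.tss // bin_size
        linked = sorted(partners.get(tbin, set()) & site_bins)
        links[name] = linked
    return links
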