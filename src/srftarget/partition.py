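"""Iterative partition of induced genes into dependent and independent sets.

Genes induced in a reference (wild-type) background are compared against
their induction in a second (knockout) background. Genes whose knockout
induction follows a systematic attenuated relation ``y = beta * x`` (in log2
induction space, ``beta < 1``) are labeled *dependent*; genes that keep their
induction (``y ~ x``) are *independent*. The slope is fit by least absolute
deviations through the origin and membership is refined iteratively with a
residual band applied to both the total and intronic read classes.

The same machinery, with the slope expectation inverted, classifies rescue:
a dependent gene is *rescued* when its induction in a reconstituted
background rejoins the systematic relation with wild-type induction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator

__all__ = [
    "induction_ratios",
    "lad_slope_through_origin",
    "fit_relation",
    "PartitionFit",
    "DependencePartitioner",
    "iterate_partition",
    "classify_rescue",
]


def induction_ratios(
    de_ref: pd.DataFrame,
    de_other: pd.DataFrame,
    induced_genes,
) -> pd.DataFrame:
    """Paired log2 induction per gene: x = reference lfc, y = other lfc.

    Genes missing from either result set are excluded.
    """
    genes = pd.Index(induced_genes)
    keep = genes.intersection(de_ref.index).intersection(de_other.index)
    return pd.DataFrame(
        {"x": de_ref.loc[keep, "log2fc"], "y": de_other.loc[keep, "log2fc"]},
        index=keep,
    )


def lad_slope_through_origin(x: np.ndarray, y: np.ndarray) -> float:
    """Least-absolute-deviation slope of ``y = beta * x`` (weighted median).

    Minimizing ``sum |y_i - beta x_i|`` over beta is the weighted median of
    the per-point slopes ``y_i / x_i`` with weights ``|x_i|``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = x != 0
    if mask.sum() == 0:
        raise ValueError("need at least one nonzero x")
    ratios = y[mask] / x[mask]
    weights = np.abs(x[mask])
    order = np.argsort(ratios)
    ratios, weights = ratios[order], weights[order]
    cum = np.cumsum(weights)
    idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(ratios[min(idx, len(ratios) - 1)])


@dataclass
class PartitionFit:
    """Summary of one systematic-relation fit."""

    slope: float
    spearman_r: float
    tau: float
    n_iter: int
    converged: bool
    n_points: int


def fit_relation(pairs: pd.DataFrame, tau: float = 0.75) -> PartitionFit:
    """LAD slope through the origin plus Spearman r of the fitted set."""
    if len(pairs) < 10:
        raise ValueError("need at least 10 pairs to fit a relation")
    beta = lad_slope_through_origin(pairs["x"].to_numpy(), pairs["y"].to_numpy())
    r = float(spearmanr(pairs["x"], pairs["y"]).statistic) if len(pairs) > 2 else np.nan
    return PartitionFit(beta, r, tau, 0, True, len(pairs))


class DependencePartitioner(BaseEstimator):
    """Iterative dependent/independent labeling of induced genes.

    Parameters
    ----------
    tau : residual band |y - beta x| (log2 units) a gene must satisfy in both
        read classes to stay in the dependent set. Default 0.75 (~2.5 sigma of
        the intronic-class log2FC noise at typical depths).
    delta_min : the fitted slope must satisfy beta < 1 - delta_min for any
        dependence to be declared (guards the null where y ~ x).
    max_iter : iteration cap; non-convergence returns the last labels with
        ``converged=False``.

    Attributes (after ``fit``)
    --------------------------
    labels_ : per-gene Series in {dependent, independent}.
    fit_ : :class:`PartitionFit` with slope, Spearman r (dependent set),
        iteration count and convergence flag.
    residuals_ : per-gene residuals in each read class at the final slope.
    """

    def __init__(self, tau: float = 0.75, delta_min: float = 0.2,
                 max_iter: int = 50):
        self.tau = tau
        self.delta_min = delta_min
        self.max_iter = max_iter

    def fit(self, pairs_total: pd.DataFrame, pairs_intronic: pd.DataFrame,
            init_labels: pd.Series | None = None):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        merged = pairs_total.join(pairs_intronic, how="inner",
                                  lsuffix="_tot", rsuffix="_int")
        # genes without reference induction carry no slope information
        merged = merged[(merged["x_tot"] > 0) & (merged["x_int"] > 0)]
        if len(merged) < 10:
            raise ValueError("need at least 10 usable pairs")

        if init_labels is None:
            dependent = (merged["y_tot"] < merged["x_tot"]) & (
                merged["y_int"] < merged["x_int"]
            )
        else:
            dependent = init_labels.reindex(merged.index).fillna(False).astype(bool)

        beta = np.nan
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            if dependent.sum() < 2:
                dependent[:] = False
                converged = True
                break
            sub = merged[dependent]
            x = np.concatenate([sub["x_tot"], sub["x_int"]])
            y = np.concatenate([sub["y_tot"], sub["y_int"]])
            beta = lad_slope_through_origin(x, y)
            if beta >= 1.0 - self.delta_min:
                dependent[:] = False
                converged = True
                break
            new = (
                ((merged["y_tot"] - beta * merged["x_tot"]).abs() <= self.tau)
                & ((merged["y_int"] - beta * merged["x_int"]).abs() <= self.tau)
            )
            if new.equals(dependent):
                converged = True
                break
            dependent = new

        labels = pd.Series(
            np.where(dependent, "dependent", "independent"),
            index=merged.index, dtype=object,
        )
        if dependent.sum() > 2 and np.isfinite(beta):
            sub = merged[dependent]
            r = float(
                spearmanr(
                    np.concatenate([sub["x_tot"], sub["x_int"]]),
                    np.concatenate([sub["y_tot"], sub["y_int"]]),
                ).statistic
            )
        else:
            r = np.nan
        self.labels_ = labels
        self.fit_ = PartitionFit(float(beta) if np.isfinite(beta) else np.nan,
                                 r, self.tau, n_iter, converged, len(merged))
        self.residuals_ = pd.DataFrame(
            {
                "total": merged["y_tot"] - (beta if np.isfinite(beta) else 0) * merged["x_tot"],
                "intronic": merged["y_int"] - (beta if np.isfinite(beta) else 0) * merged["x_int"],
            }
        )
        return self

    def predict(self, pairs_total: pd.DataFrame, pairs_intronic: pd.DataFrame) -> pd.Series:
        """Label new pairs with the fitted slope and residual band."""
        merged = pairs_total.join(pairs_intronic, how="inner",
                                  lsuffix="_tot", rsuffix="_int")
        beta = self.fit_.slope
        if not np.isfinite(beta) or beta >= 1.0 - self.delta_min:
            return pd.Series("independent", index=merged.index, dtype=object)
        dep = (
            ((merged["y_tot"] - beta * merged["x_tot"]).abs() <= self.tau)
            & ((merged["y_int"] - beta * merged["x_int"]).abs() <= self.tau)
        )
        return pd.Series(np.where(dep, "dependent", "independent"),
                         index=merged.index, dtype=object)


def iterate_partition(
    pairs_total: pd.DataFrame,
    pairs_intronic: pd.DataFrame,
    tau: float = 0.75,
    max_iter: int = 50,
    delta_min: float = 0.2,
) -> tuple[PartitionFit, pd.Series]:
    """Functional wrapper around :class:`DependencePartitioner`."""
    part = DependencePartitioner(tau=tau, delta_min=delta_min,
                                 max_iter=max_iter).fit(pairs_total, pairs_intronic)
    return part.fit_, part.labels_


def classify_rescue(
    pairs_total: pd.DataFrame,
    pairs_intronic: pd.DataFrame,
    dependent_genes,
    tau: float = 0.75,
    min_slope: float = 0.5,
    max_iter: int = 50,
) -> tuple[PartitionFit, pd.Series]:
    """Label dependent genes rescued/refractory in a reconstituted background.

    ``pairs_*`` carry x = wild-type log2 induction, y = rescue-background
    log2 induction. A gene is *rescued* when it lies within the residual band
    of the systematic rescue relation, provided the fitted rescue slope is at
    least ``min_slope`` (a background identical to the knockout fits an
    attenuated slope and yields zero rescued genes).
    """
    genes = pd.Index(dependent_genes)
    merged = pairs_total.loc[pairs_total.index.intersection(genes)].join(
        pairs_intronic.loc[pairs_intronic.index.intersection(genes)],
        how="inner", lsuffix="_tot", rsuffix="_int",
    )
    merged = merged[(merged["x_tot"] > 0) & (merged["x_int"] > 0)]
    if len(merged) < 10:
        raise ValueError("need at least 10 dependent genes with usable pairs")

    # initialize with genes whose rescue induction reaches at least half of
    # the wild-type level in both classes
    rescued = (merged["y_tot"] >= 0.5 * merged["x_tot"]) & (
        merged["y_int"] >= 0.5 * merged["x_int"]
    )
    beta = np.nan
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if rescued.sum() < 2:
            rescued[:] = False
            converged = True
            break
        sub = merged[rescued]
        beta = lad_slope_through_origin(
            np.concatenate([sub["x_tot"], sub["x_int"]]),
            np.concatenate([sub["y_tot"], sub["y_int"]]),
        )
        if beta < min_slope:
            rescued[:] = False
            converged = True
            break
        new = (
            ((merged["y_tot"] - beta * merged["x_tot"]).abs() <= tau)
            & ((merged["y_int"] - beta * merged["x_int"]).abs() <= tau)
        )
        if new.equals(rescued):
            converged = True
            break
        rescued = new

    labels = pd.Series(np.where(rescued, "rescued", "refractory"),
                       index=merged.index, dtype=object)
    if rescued.sum() > 2 and np.isfinite(beta):
        sub = merged[rescued]
        r = float(
            spearmanr(
                np.concatenate([sub["x_tot"], sub["x_int"]]),
                np.concatenate([sub["y_tot"], sub["y_int"]]),
            ).statistic
        )
    else:
        r = np.nan
    fit = PartitionFit(float(beta) if np.isfinite(beta) else np.nan, r, tau,
                       n_iter, converged, len(merged))
    return fit, labels
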