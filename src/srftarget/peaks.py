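"""Pseudo-replicate peak consensus, differential occupancy, and coincidence.

High-confidence binding sites are defined by reproducibility across
pseudo-replicate peak calls: peaks are clustered across replicates by >= 1 bp
overlap (single linkage) and a cluster is retained when at least
``min_support`` distinct replicates contribute a peak below the caller
p-value threshold (scores are -log10 p). Retained sites can additionally be
filtered by differential read occupancy against a control (>= 1.5-fold,
p <= 0.05 by the NB test), and a second factor's sites are labeled by
coincidence with the first's (summit within the partner interval +- slop).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .induction import nb_test
from .io import GenomicInterval, GenomicIntervalSet

__all__ = ["consensus", "differential_occupancy", "coincide", "consensus_to_intervals"]


def consensus(
    replicate_peaks: list[GenomicIntervalSet],
    p_threshold: float = 1e-4,
    min_support: int = 3,
) -> pd.DataFrame:
    """Cluster pseudo-replicate peaks and apply the reproducibility filter.

    Returns one row per overlap cluster: union interval, support-weighted
    summit, number of distinct supporting replicates (counting only peaks
    with p < ``p_threshold``), best -log10 p, and the retained flag.
    """
    if len(replicate_peaks) < min_support:
        raise ValueError(
            f"need at least min_support={min_support} replicate sets, "
            f"got {len(replicate_peaks)}"
        )
    score_min = -np.log10(p_threshold)
    rows = []
    for rep_idx, peakset in enumerate(replicate_peaks):
        for iv in peakset:
            rows.append((iv.chrom, iv.start, iv.end, iv.summit, iv.score, rep_idx))
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "summit", "support",
                     "best_neg_log10_p", "retained"]
        )
    pooled = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "summit", "score", "rep"]
    ).sort_values(["chrom", "start", "end"], kind="mergesort")

    clusters = []
    for chrom, grp in pooled.groupby("chrom", sort=True):
        cur = None
        for row in grp.itertuples(index=False):
            if cur is None or row.start >= cur["end"]:
                if cur is not None:
                    clusters.append(cur)
                cur = {"chrom": chrom, "start": row.start, "end": row.end,
                       "members": [row]}
            else:  # >= 1 bp overlap with the growing cluster (single linkage)
                cur["end"] = max(cur["end"], row.end)
                cur["members"].append(row)
        if cur is not None:
            clusters.append(cur)

    out = []
    for cl in clusters:
        members = cl["members"]
        passing = {m.rep for m in members
                   if m.score is not None and m.score > score_min}
        best = max((m.score for m in members if m.score is not None),
                   default=np.nan)
        summit = int(round(np.mean([m.summit for m in members])))
        out.append(
            {
                "chrom": cl["chrom"],
                "start": cl["start"],
                "end": cl["end"],
                "summit": summit,
                "support": len(passing),
                "best_neg_log10_p": best,
                "retained": len(passing) >= min_support,
            }
        )
    return pd.DataFrame(out)


def differential_occupancy(
    peaks: pd.DataFrame,
    chip_counts,
    control_counts,
    min_fold: float = 1.5,
    alpha: float = 0.05,
    dispersion: float | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Filter consensus peaks by ChIP enrichment over a control.

    ``chip_counts`` / ``control_counts`` are per-peak normalized read counts
    (replicates x peaks, or 1-D for single libraries). A peak stays retained
    when fold >= ``min_fold`` and the NB-test p <= ``alpha``.
    """
    chip = np.atleast_2d(np.asarray(chip_counts, dtype=float))
    ctrl = np.atleast_2d(np.asarray(control_counts, dtype=float))
    if chip.shape[1] != len(peaks) or ctrl.shape[1] != len(peaks):
        raise ValueError("per-peak counts must match the number of peaks")
    res = nb_test(ctrl, chip, dispersion=dispersion, pseudocount=pseudocount)
    out = peaks.copy()
    fold = (chip.mean(axis=0) + pseudocount) / (ctrl.mean(axis=0) + pseudocount)
    out["fold"] = fold
    out["diff_p"] = res["pvalue"].to_numpy()
    out["retained"] = (
        out["retained"] & (out["fold"] >= min_fold) & (out["diff_p"] <= alpha)
    )
    return out


def coincide(
    elk_peaks: pd.DataFrame,
    srf_peaks: pd.DataFrame,
    slop: int = 100,
) -> pd.Series:
    """Label each retained Elk-1 peak SRF-associated or solo.

    A peak is *SRF-associated* when its summit lies within a retained SRF
    peak interval extended by ``slop`` bp on both sides.
    """
    srf = srf_peaks[srf_peaks["retained"]] if "retained" in srf_peaks else srf_peaks
    elk = elk_peaks[elk_peaks["retained"]] if "retained" in elk_peaks else elk_peaks
    labels = {}
    by_chrom = dict(tuple(srf.groupby("chrom"))) if len(srf) else {}
    for idx, row in elk.iterrows():
        hit = False
        grp = by_chrom.get(row["chrom"])
        if grp is not None:
            hit = bool(
                ((grp["start"] - slop <= row["summit"])
                 & (row["summit"] < grp["end"] + slop)).any()
            )
        labels[idx] = "SRF-associated" if hit else "solo"
    return pd.Series(labels, dtype=object, name="coincidence")


def consensus_to_intervals(peaks: pd.DataFrame, retained_only: bool = True) -> GenomicIntervalSet:
    """Convert consensus rows to intervals (score = best -log10 p)."""
    sub = peaks[peaks["retained"]] if retained_only and "retained" in peaks else peaks
    return GenomicIntervalSet(
        [
            GenomicInterval(r.chrom, int(r.start), int(r.end),
                            name=f"peak{idx}",
                            score=None if pd.isna(r.best_neg_log10_p)
                            else float(r.best_neg_log10_p))
            for idx, r in sub.iterrows()
        ]
    )
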