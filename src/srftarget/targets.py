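"""Direct/Indirect target classification and gene-set enrichment.

A TPA-induced, TCF-dependent gene is a *Direct* target when its TSS is
within 10 kb of a retained SRF site or physically linked to a site-bearing
bin by a significant Hi-C interaction at any distance; it is *Indirect* when
its TSS is more than 100 kb from every SRF site with no Hi-C link to one.
Genes in the 10-100 kb gap without a link satisfy neither definition and are
reported as Unassigned, never silently merged. Gene-set enrichment is the
upper-tail hypergeometric test with Bonferroni adjustment.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GenomicInterval, GenomicIntervalSet

__all__ = [
    "nearest_site_distance",
    "classify",
    "hypergeom_enrichment",
    "summarize",
    "percentage",
]

PROXIMAL_BP = 10_000
DISTAL_BP = 100_000


def nearest_site_distance(tss, sites) -> float:
    """Distance in bp from a TSS base to the closest site interval.

    0 when the TSS base lies inside a site; +inf when no site shares the
    chromosome. Strand-agnostic.
    """
    if isinstance(tss, GenomicInterval):
        chrom, pos = tss.chrom, tss.tss
    else:
        chrom, pos = tss
    best = math.inf
    iterator = sites.itertuples(index=False) if isinstance(sites, pd.DataFrame) else iter(sites)
    for site in iterator:
        s_chrom = site.chrom
        start, end = site.start, site.end
        if s_chrom != chrom:
            continue
        if pos < start:
            d = start - pos
        elif pos >= end:
            d = pos - (end - 1)
        else:
            d = 0
        best = min(best, d)
    return best


def classify(
    genes,
    tss_map: dict[str, list[GenomicInterval]],
    srf_sites,
    links: dict[str, list[int]],
    induction_calls: pd.Series,
    dependence_calls: pd.Series,
    proximal_bp: int = PROXIMAL_BP,
    distal_bp: int = DISTAL_BP,
) -> pd.DataFrame:
    """Per-gene Direct / Indirect / Unassigned classification.

    Multi-TSS genes use the TSS minimizing the nearest-site distance and are
    linked when any of their TSSs is linked. Direct genes are additionally
    partitioned into proximal (nearest site <= 10 kb) and remote-controlled
    (qualified only through a Hi-C link).
    """
    rows = []
    for g in genes:
        tss_list = tss_map.get(g, [])
        if not tss_list:
            rows.append((g, np.nan, math.inf, 0, "no-TSS", "Unassigned", False))
            continue
        dist = min(nearest_site_distance(t, srf_sites) for t in tss_list)
        linked_bins = links.get(g, [])
        linked = len(linked_bins) > 0
        induced = induction_calls.get(g) == "induced"
        dependent = dependence_calls.get(g) == "dependent"
        if induced and dependent:
            if dist <= proximal_bp or linked:
                cls = "Direct"
            elif dist > distal_bp and not linked:
                cls = "Indirect"
            else:
                cls = "Unassigned"
        else:
            cls = "Unassigned"
        remote = cls == "Direct" and dist > proximal_bp
        status = (
            "induced-dependent" if induced and dependent
            else ("induced" if induced else "not-induced")
        )
        tss_used = min(tss_list, key=lambda t: nearest_site_distance(t, srf_sites))
        rows.append((g, tss_used.tss, dist, len(linked_bins), status, cls, remote))
    return pd.DataFrame(
        rows,
        columns=["gene", "tss", "nearest_site_bp", "n_links", "status",
                 "target_class", "remote"],
    ).set_index("gene")


def hypergeom_enrichment(
    query,
    annotated_sets: dict[str, set],
    universe,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with Bonferroni adjustment.

    Each annotated set is intersected with the universe before testing; the
    query must be a subset of the universe.
    """
    uni = set(universe)
    q = set(query)
    if not q <= uni:
        raise ValueError("query must be a subset of the universe")
    m = len(uni)
    n_sets = len(annotated_sets)
    rows = []
    for name, members in annotated_sets.items():
        s = set(members) & uni
        overlap = len(q & s)
        p = float(hypergeom.sf(overlap - 1, m, len(s), len(q)))
        rows.append(
            {
                "set": name,
                "universe": m,
                "set_size": len(s),
                "query_size": len(q),
                "overlap": overlap,
                "p": p,
                "p_bonferroni": min(1.0, p * n_sets),
            }
        )
    return pd.DataFrame(rows).set_index("set")


def percentage(numerator: float, denominator: float) -> float:
    """100 * numerator / denominator, 0 for an empty denominator."""
    return 100.0 * numerator / denominator if denominator else 0.0


def summarize(
    classifications: pd.DataFrame | None = None,
    induction_calls: pd.Series | None = None,
    dependence_calls: pd.Series | None = None,
    coincidence: pd.Series | None = None,
    compartments=None,
    srf_sites: pd.DataFrame | GenomicIntervalSet | None = None,
    bin_size: int | None = None,
    rescue_labels: pd.Series | None = None,
) -> dict:
    """Count/percentage report across all pipeline outputs.

    Any input may be omitted; missing sections report zeros. Percentages are
    always 100 * numerator / denominator of the reported counts.
    """
    rep: dict[str, float] = {}

    n_induced = int((induction_calls == "induced").sum()) if induction_calls is not None else 0
    n_down = int((induction_calls == "downregulated").sum()) if induction_calls is not None else 0
    n_dep = int((dependence_calls == "dependent").sum()) if dependence_calls is not None else 0
    n_part = int(len(dependence_calls)) if dependence_calls is not None else 0
    rep["n_induced"] = n_induced
    rep["n_downregulated"] = n_down
    rep["n_dependent"] = n_dep
    rep["dependent_pct"] = percentage(n_dep, n_part)

    if classifications is not None and len(classifications):
        counts = classifications["target_class"].value_counts()
        n_direct = int(counts.get("Direct", 0))
        n_indirect = int(counts.get("Indirect", 0))
        n_unassigned = int(counts.get("Unassigned", 0))
        n_remote = int(classifications["remote"].sum())
    else:
        n_direct = n_indirect = n_unassigned = n_remote = 0
    rep["n_direct"] = n_direct
    rep["n_indirect"] = n_indirect
    rep["n_unassigned"] = n_unassigned
    rep["n_remote_direct"] = n_remote
    rep["remote_direct_pct"] = percentage(n_remote, n_direct)

    if coincidence is not None and len(coincidence):
        n_assoc = int((coincidence == "SRF-associated").sum())
        n_solo = int((coincidence == "solo").sum())
    else:
        n_assoc = n_solo = 0
    rep["n_elk1_srf_associated"] = n_assoc
    rep["n_elk1_solo"] = n_solo
    rep["elk1_srf_associated_pct"] = percentage(n_assoc, n_assoc + n_solo)

    n_sites = n_in_a = 0
    if compartments is not None and srf_sites is not None and bin_size:
        labels = getattr(compartments, "labels", compartments)
        if isinstance(srf_sites, pd.DataFrame):
            sub = srf_sites[srf_sites["retained"]] if "retained" in srf_sites else srf_sites
            summits = [int(s) for s in sub["summit"]]
        else:
            summits = [iv.summit for iv in srf_sites]
        for s in summits:
            b = s // bin_size
            if 0 <= b < len(labels):
                n_sites += 1
                if labels[b] == "A":
                    n_in_a += 1
    rep["n_srf_sites"] = n_sites
    rep["n_srf_sites_in_A"] = n_in_a
    rep["srf_sites_in_A_pct"] = percentage(n_in_a, n_sites)

    if rescue_labels is not None and len(rescue_labels):
        n_resc = int((rescue_labels == "rescued").sum())
        rep["n_rescued"] = n_resc
        rep["rescued_pct"] = percentage(n_resc, len(rescue_labels))
    else:
        rep["n_rescued"] = 0
        rep["rescued_pct"] = 0.0
    return rep
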