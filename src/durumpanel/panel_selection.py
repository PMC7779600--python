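"""Core-collection selection from a reference panel.

The procedure mirrors how a curated core panel is assembled from a larger
reference collection of inbred lines: Ward hierarchical clustering on
genetic distances defines strata; duplicates (IBS above a cut) collapse to
one representative; each group's quota is spread across that group's Ward
sub-clusters proportionally to size with the sub-cluster medoid (and then
the most central members) picked first; a fraction of each quota is
reserved for rare haplotypes — accessions with the lowest mean similarity
to everything else; forced includes are always selected and counted
against quotas. A retention report compares per-locus diversity (MAF, He,
Shannon H, evenness E5) and the site frequency spectrum between the full
panel and the selected subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_io import GenotypeMatrix, GroupScheme
from .curation import ibs_matrix
from .diversity import SfsHistogram, haploid_freqs, nei_gene_diversity, sfs, shannon_evenness

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------


@dataclass
class WardTree:
    """Ward dendrogram over accessions with k-cut membership retrieval."""

    accession_ids: list[str]
    linkage_matrix: np.ndarray

    def memberships(self, k: int) -> dict[str, int]:
        labels = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.accession_ids, labels.astype(int)))


def ward_tree(
    G: GenotypeMatrix | None = None,
    distance: np.ndarray | None = None,
    accession_ids: list[str] | None = None,
) -> WardTree:
    """Agglomerative Ward clustering on accession genetic distances.

    By default the distance is 1 - IBS computed from the genotype matrix; a
    precomputed square distance matrix can be supplied instead. Undefined
    distances raise with the offending pairs listed.
    """
    if distance is None:
        if G is None:
            raise ValueError("supply a genotype matrix or a distance matrix")
        distance = 1.0 - ibs_matrix(G)
        accession_ids = list(G.accession_ids)
    if accession_ids is None:
        raise ValueError("accession_ids required with a precomputed distance")
    if len(accession_ids) < 2:
        raise ValueError("clustering needs at least two accessions")
    d = np.asarray(distance, dtype=float)
    if np.isnan(d).any():
        i, j = np.argwhere(np.isnan(np.triu(d, k=1)))[0]
        raise ValueError(
            f"undefined distances, e.g. {accession_ids[i]!r} vs {accession_ids[j]!r}"
        )
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="ward")
    return WardTree(list(accession_ids), Z)


# ---------------------------------------------------------------------------
# stratified sampling
# ---------------------------------------------------------------------------


@dataclass
class SelectionPlan:
    """Quotas and constraints for core-panel sampling."""

    quotas: dict[str, int]  # group label -> target count
    forced_include: list[str] = field(default_factory=list)
    duplicate_cut: float = 0.95
    rare_fraction: float = 0.10
    max_subclusters: int = 10
    min_subcluster_size: int = 3

    def __post_init__(self) -> None:
        if any(q <= 0 for q in self.quotas.values()):
            raise ValueError("quotas must be positive")


def _subcluster_k(tree: WardTree, plan: SelectionPlan) -> int:
    """Finest cut (largest k <= cap) whose smallest sub-cluster has >= 3 members."""
    n = len(tree.accession_ids)
    best = 1
    for k in range(2, min(plan.max_subclusters, n) + 1):
        labels = np.array(list(tree.memberships(k).values()))
        sizes = np.bincount(labels)[1:]
        if sizes[sizes > 0].min() >= plan.min_subcluster_size:
            best = k
    return best


def _largest_remainder(weights: np.ndarray, total: int, minimum: int = 1) -> np.ndarray:
    """Allocate ``total`` slots proportionally with a per-bin minimum."""
    k = len(weights)
    alloc = np.full(k, minimum, dtype=int)
    remaining = total - alloc.sum()
    if remaining < 0:  # more bins than quota: largest bins first
        alloc[:] = 0
        order = np.argsort(-weights, kind="stable")
        alloc[order[:total]] = 1
        return alloc
    share = weights / weights.sum() * remaining
    alloc += np.floor(share).astype(int)
    left = total - alloc.sum()
    frac = share - np.floor(share)
    order = np.argsort(-frac, kind="stable")
    for i in range(left):
        alloc[order[i % k]] += 1
    return alloc


def stratified_sample(
    G: GenotypeMatrix,
    scheme: GroupScheme,
    plan: SelectionPlan,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Select a stratified core set with duplicate exclusion and rare reserve.

    Steps per group: (1) collapse IBS-duplicate components to one member;
    (2) cut the group's Ward tree into sub-clusters and spread the quota
    proportionally (minimum one per non-empty sub-cluster), picking the
    medoid and then the most central members; (3) a ``rare_fraction`` share
    of the quota is reserved for accessions with the lowest mean IBS to the
    rest of the panel; (4) forced includes are always selected and counted.
    Deterministic given the input: ties break on accession id; the seed is
    accepted for interface stability but no random draw is needed.

    Returns (selected ids in panel order, audit DataFrame).
    """
    del seed  # deterministic procedure: canonical id sort breaks all ties
    scheme.validate_against(G)
    unknown_forced = set(plan.forced_include) - set(G.accession_ids)
    if unknown_forced:
        raise ValueError(f"forced includes absent from panel: {sorted(unknown_forced)}")
    ibs = ibs_matrix(G)
    acc_index = {a: i for i, a in enumerate(G.accession_ids)}
    mean_ibs = (np.nansum(np.nan_to_num(ibs), axis=1) - 1.0) / (G.n_accessions - 1)
    audit: list[dict] = []
    selected: set[str] = set()

    from .curation import find_duplicates

    for label, ids in scheme.groups().items():
        quota = plan.quotas.get(label)
        if quota is None:
            continue
        ids = sorted(ids)
        idx = np.array([acc_index[a] for a in ids])
        sub_ibs = ibs[np.ix_(idx, idx)]
        groups, retained = find_duplicates(sub_ibs, ids, cut=plan.duplicate_cut)
        for g in groups:
            for dropped in g[1:]:
                audit.append({"accession": dropped, "group": label,
                              "action": "excluded", "reason": f"IBS duplicate of {g[0]}"})
        pool = sorted(retained)
        if quota > len(pool):
            shortfall = quota - len(pool)
            audit.append({"accession": "", "group": label, "action": "shortfall",
                          "reason": f"quota {quota} exceeds {len(pool)} distinct members "
                                    f"by {shortfall}"})
            quota = len(pool)
        forced = [a for a in plan.forced_include if a in pool]
        for a in forced:
            selected.add(a)
            audit.append({"accession": a, "group": label, "action": "selected",
                          "reason": "forced include"})
        quota_left = quota - len(forced)
        if quota_left <= 0:
            continue

        # rare-haplotype reserve: lowest mean IBS to all panel members
        n_rare = int(round(plan.rare_fraction * quota))
        candidates = [a for a in pool if a not in selected]
        rare_order = sorted(candidates, key=lambda a: (mean_ibs[acc_index[a]], a))
        rare_pick = rare_order[: min(n_rare, quota_left)]
        for a in rare_pick:
            selected.add(a)
            audit.append({"accession": a, "group": label, "action": "selected",
                          "reason": f"rare haplotype (mean IBS {mean_ibs[acc_index[a]]:.3f})"})
        quota_left -= len(rare_pick)
        if quota_left <= 0:
            continue

        # stratified pick over Ward sub-clusters
        candidates = [a for a in pool if a not in selected]
        if len(candidates) <= quota_left:
            for a in candidates:
                selected.add(a)
                audit.append({"accession": a, "group": label, "action": "selected",
                              "reason": "whole remaining pool (quota >= pool)"})
            continue
        cidx = np.array([acc_index[a] for a in candidates])
        dist = 1.0 - np.nan_to_num(ibs[np.ix_(cidx, cidx)], nan=0.0)
        if len(candidates) >= 2:
            tree = ward_tree(distance=dist, accession_ids=candidates)
            k = _subcluster_k(tree, plan)
            member = tree.memberships(k)
        else:
            member = {candidates[0]: 1}
            k = 1
        sub_ids: dict[int, list[str]] = {}
        for a, lab in member.items():
            sub_ids.setdefault(lab, []).append(a)
        labs = sorted(sub_ids)
        sizes = np.array([len(sub_ids[l]) for l in labs], dtype=float)
        alloc = _largest_remainder(sizes, quota_left)
        for l, m in zip(labs, alloc):
            members = sorted(sub_ids[l])
            midx = [candidates.index(a) for a in members]
            centrality = dist[np.ix_(midx, midx)].mean(axis=1)
            order = [members[i] for i in np.argsort(centrality, kind="stable")]
            for rank, a in enumerate(order[: int(m)]):
                selected.add(a)
                why = "sub-cluster medoid" if rank == 0 else f"central rank {rank + 1}"
                audit.append({"accession": a, "group": label, "action": "selected",
                              "reason": f"{why} (sub-cluster {l} of {k})"})

    ordered = [a for a in G.accession_ids if a in selected]
    return ordered, pd.DataFrame(audit, columns=["accession", "group", "action", "reason"])


# ---------------------------------------------------------------------------
# retention diagnostics
# ---------------------------------------------------------------------------


@dataclass
class RetentionReport:
    corr_maf: float
    corr_he: float
    corr_shannon: float
    corr_evenness: float
    sfs_full: SfsHistogram
    sfs_subset: SfsHistogram
    n_loci_compared: int

    @property
    def correlations(self) -> dict[str, float]:
        return {
            "MAF": self.corr_maf,
            "He": self.corr_he,
            "Shannon": self.corr_shannon,
            "Evenness": self.corr_evenness,
        }

    @property
    def diversity_loss(self) -> tuple[float, float]:
        """(min, max) of 1 - correlation over the four indices."""
        vals = list(self.correlations.values())
        return (1.0 - max(vals), 1.0 - min(vals))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return np.nan
    if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return 1.0 if np.allclose(x[ok], y[ok]) else np.nan
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def retention_report(G_full: GenotypeMatrix, subset_ids) -> RetentionReport:
    """Diversity retained by a subset: per-locus correlations and SFS.

    Loci monomorphic in both sets are excluded from the correlations.
    """
    subset_ids = list(subset_ids)
    missing = set(subset_ids) - set(G_full.accession_ids)
    if missing:
        raise ValueError(f"subset ids not in panel: {sorted(missing)[:3]}")
    if len(subset_ids) < 2:
        raise ValueError("per-locus diversity undefined for a subset of < 2 accessions")
    G_sub = G_full.subset_accessions(subset_ids)
    p_f, n_f = haploid_freqs(G_full)
    p_s, n_s = haploid_freqs(G_sub)
    poly = (
        np.isfinite(p_f) & np.isfinite(p_s)
        & ~(((p_f <= 0) | (p_f >= 1)) & ((p_s <= 0) | (p_s >= 1)))
    )
    maf_f = np.minimum(p_f, 1 - p_f)[poly]
    maf_s = np.minimum(p_s, 1 - p_s)[poly]
    he_f = nei_gene_diversity(p_f, n_f)[poly]
    he_s = nei_gene_diversity(p_s, n_s)[poly]
    h_f, e_f = shannon_evenness(p_f[poly])
    h_s, e_s = shannon_evenness(p_s[poly])
    return RetentionReport(
        corr_maf=_pearson(maf_f, maf_s),
        corr_he=_pearson(he_f, he_s),
        corr_shannon=_pearson(h_f, h_s),
        corr_evenness=_pearson(e_f, e_s),
        sfs_full=sfs(maf_f[maf_f > 0]),
        sfs_subset=sfs(maf_s[maf_s > 0]),
        n_loci_compared=int(poly.sum()),
    )
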