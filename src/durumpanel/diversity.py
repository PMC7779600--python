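"""Diversity and differentiation statistics for inbred SNP panels.

Inbred-line convention: durum lines are near-fully homozygous, so for every
statistic in this module genotypes are haploid-coded — a homozygote
contributes one gene copy (0 or 1) and heterozygous calls are treated as
missing. Allele frequencies, Nei gene diversity, PIC, pairwise differences,
AMOVA distances and Nei distance all use this coding. The alternative
diploid convention can be obtained by recoding upstream.

Implements: per-locus Nei unbiased gene diversity He, Botstein PIC,
Shannon-Wiener H with Hill-evenness E5, the minor-allele site frequency
spectrum, mean pairwise differences (pi), one-level AMOVA with permutation
significance, pairwise Fst matrices, Nei (1972) standard genetic distance,
and the unique/rare allele catalogue per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, GroupScheme

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# haploid frequency helpers
# ---------------------------------------------------------------------------


def haploid_freqs(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(alternate-allele frequency, gene copies n) per marker, haploid coding.

    Frequency is NaN where no haploid-codable call exists.
    """
    H = G.haploid()
    n = np.sum(np.isfinite(H), axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.nansum(H, axis=0) / np.where(n > 0, n, np.nan)
    return p, n


# ---------------------------------------------------------------------------
# per-locus closed forms
# ---------------------------------------------------------------------------


def nei_gene_diversity(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Nei unbiased gene diversity He = n/(n-1) * (1 - p^2 - q^2).

    ``p`` is the (alternate) allele frequency, ``n`` the number of gene
    copies it was estimated from. Undefined (NaN) for n < 2.
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    het = 1.0 - p**2 - (1.0 - p) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        he = np.where(n >= 2, n / (n - 1.0) * het, np.nan)
    return he


def pic(p: np.ndarray) -> np.ndarray:
    """Botstein polymorphism information content for a biallelic locus.

    PIC = 1 - (p^2 + q^2) - 2 p^2 q^2; maximum 0.375 at p = 0.5.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2


def shannon_evenness(p) -> tuple[np.ndarray, np.ndarray]:
    """Shannon-Wiener H and Hill evenness E5 per locus.

    H = -sum p_i ln p_i (0 ln 0 = 0); E5 = (1/lambda - 1)/(e^H - 1) with
    lambda = sum p_i^2. E5 = 1 at equal frequencies and is undefined (NaN)
    at fixation.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    q = 1.0 - p
    with np.errstate(invalid="ignore", divide="ignore"):
        h = -(np.where(p > 0, p * np.log(p), 0.0) + np.where(q > 0, q * np.log(q), 0.0))
        lam = p**2 + q**2
        denom = np.expm1(h)
        e5 = np.where(denom > 0, (1.0 / lam - 1.0) / denom, np.nan)
    # exact-equal frequencies: define E5 = 1 (limit and convention agree)
    e5 = np.where(np.isclose(p, 0.5), 1.0, e5)
    return h, e5


@dataclass
class SfsHistogram:
    """Minor-allele site frequency spectrum in 0.05-wide bins over (0, 0.5]."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "low": self.bin_edges[:-1],
            "high": self.bin_edges[1:],
            "count": self.counts,
        })


def sfs(maf_values, bin_width: float = 0.05) -> SfsHistogram:
    """Bin minor-allele frequencies into [k*w, (k+1)*w) bins, last bin closed.

    Values must lie in (0, 0.5]; zeros (monomorphic) are excluded upstream.
    """
    v = np.asarray(maf_values, dtype=float)
    v = v[np.isfinite(v)]
    if (v > 0.5 + 1e-12).any():
        raise ValueError("minor allele frequency above 0.5")
    if (v <= 0).any():
        raise ValueError("SFS input must be strictly positive (polymorphic loci only)")
    edges = np.round(np.arange(0.0, 0.5 + bin_width / 2, bin_width), 10)
    idx = np.minimum(np.floor(v / bin_width).astype(int), len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    return SfsHistogram(edges, counts)


# ---------------------------------------------------------------------------
# pairwise differences
# ---------------------------------------------------------------------------


def _pairwise_diff_matrix(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(rescaled difference count, shared loci) matrices, haploid coding.

    diff[a, b] = (count of differing loci among pairwise-complete loci)
    * (total loci / complete loci) — the raw count when nothing is missing.
    """
    H = G.haploid()
    Mv = np.isfinite(H).astype(np.float64)
    X = np.nan_to_num(H) * Mv
    shared = Mv @ Mv.T
    diff = X @ (Mv - X).T + (Mv - X) @ X.T
    L = G.n_markers
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(shared > 0, diff * (L / shared), np.nan)
    return scaled, shared


def mean_pairwise_differences(G: GenotypeMatrix) -> float:
    """Mean count of differing loci over all accession pairs (pi).

    Haploid coding; each pair's count is rescaled by total/complete loci.
    Pairs sharing no complete locus are excluded with a warning.
    """
    if G.n_accessions < 2:
        raise ValueError("pi needs at least two accessions")
    d, _ = _pairwise_diff_matrix(G)
    iu = np.triu_indices(G.n_accessions, k=1)
    vals = d[iu]
    if np.isnan(vals).any():
        logger.warning("%d accession pairs share no complete locus; excluded",
                       int(np.isnan(vals).sum()))
    return float(np.nanmean(vals))


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------


@dataclass
class DiversitySummary:
    """Per-group diversity panel in the layout of a diversity table row."""

    group: str
    n_accessions: int
    n_polymorphic_loci: int
    nei_gene_diversity: float  # mean He over loci polymorphic in the group
    mean_pairwise_differences: float
    pic: float  # mean PIC over polymorphic loci
    he_per_locus: np.ndarray = field(repr=False)
    pic_per_locus: np.ndarray = field(repr=False)
    maf_per_locus: np.ndarray = field(repr=False)
    shannon_per_locus: np.ndarray = field(repr=False)
    evenness_per_locus: np.ndarray = field(repr=False)


def group_summaries(G: GenotypeMatrix, scheme: GroupScheme) -> list[DiversitySummary]:
    """Diversity summary per group of the scheme (Table-style output)."""
    out = []
    for label, ids in scheme.groups().items():
        sub = G.subset_accessions(ids)
        p, n = haploid_freqs(sub)
        he = nei_gene_diversity(p, n)
        pc = pic(p)
        mafv = np.minimum(p, 1 - p)
        h, e5 = shannon_evenness(p)
        poly = np.isfinite(p) & (p > 0) & (p < 1)
        out.append(DiversitySummary(
            group=label,
            n_accessions=len(ids),
            n_polymorphic_loci=int(poly.sum()),
            nei_gene_diversity=float(np.nanmean(he[poly])) if poly.any() else 0.0,
            mean_pairwise_differences=(
                mean_pairwise_differences(sub) if len(ids) >= 2 else np.nan
            ),
            pic=float(np.nanmean(pc[poly])) if poly.any() else 0.0,
            he_per_locus=he,
            pic_per_locus=pc,
            maf_per_locus=mafv,
            shannon_per_locus=h,
            evenness_per_locus=e5,
        ))
    return out


def summaries_frame(summaries: list[DiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "group": s.group,
            "n_accessions": s.n_accessions,
            "n_polymorphic_loci": s.n_polymorphic_loci,
            "nei_gene_diversity": s.nei_gene_diversity,
            "mean_pairwise_differences": s.mean_pairwise_differences,
            "PIC": s.pic,
        }
        for s in summaries
    ])


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    var_among: float
    var_within: float
    pct_among: float
    pct_within: float
    fst: float
    p_value: float | None
    n_permutations: int


def _amova_from_d2(d2: np.ndarray, group_idx: list[np.ndarray]) -> AmovaResult:
    """One-level AMOVA from a squared-distance matrix and group index lists."""
    n = sum(len(g) for g in group_idx)
    g = len(group_idx)
    d2 = np.nan_to_num(d2)  # pairs with no shared locus contribute 0 (warned upstream)
    ss_total = float(d2.sum()) / 2.0 / n  # diagonal is zero
    ss_within = 0.0
    for idx in group_idx:
        ss_within += float(d2[np.ix_(idx, idx)].sum()) / 2.0 / len(idx)
    ss_among = ss_total - ss_within
    df_among = g - 1
    df_within = n - g
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else np.nan
    sizes = np.array([len(idx) for idx in group_idx], dtype=float)
    n_c = (n - (sizes**2).sum() / n) / df_among
    var_within = ms_within
    var_among = (ms_among - ms_within) / n_c
    total = var_among + var_within
    fst = var_among / total if total > 0 else 0.0
    pct_among = 100.0 * var_among / total if total > 0 else 0.0
    return AmovaResult(
        ss_among=ss_among, ss_within=ss_within,
        df_among=df_among, df_within=df_within,
        var_among=var_among, var_within=var_within,
        pct_among=pct_among, pct_within=100.0 - pct_among,
        fst=fst, p_value=None, n_permutations=0,
    )


def amova(
    G: GenotypeMatrix,
    scheme: GroupScheme,
    n_perm: int = 10000,
    seed: int = 0,
) -> AmovaResult:
    """One-level AMOVA on squared inter-accession distances.

    The squared distance between two accessions is the (pairwise-complete,
    rescaled) count of differing haploid-coded loci. Variance components use
    the standard unequal-sample-size coefficient; Fst is the among-group
    share of the total. Significance: fraction of random label permutations
    with Fst >= observed, with the (b+1)/(m+1) correction.

    Groups of size 1 are excluded with a warning.
    """
    groups = {lab: ids for lab, ids in scheme.groups().items()}
    for lab in [l for l, ids in groups.items() if len(ids) < 2]:
        logger.warning("group %r has a single accession; excluded from AMOVA", lab)
        del groups[lab]
    if len(groups) < 2:
        raise ValueError("AMOVA needs at least two groups of size >= 2")
    order = [a for ids in groups.values() for a in ids]
    sub = G.subset_accessions(order)
    d2, _ = _pairwise_diff_matrix(sub)
    d2 = np.nan_to_num(d2)
    sizes = [len(ids) for ids in groups.values()]
    bounds = np.cumsum([0] + sizes)
    group_idx = [np.arange(bounds[i], bounds[i + 1]) for i in range(len(sizes))]
    res = _amova_from_d2(d2, group_idx)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        n = len(order)
        b = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            perm_idx = [perm[idx] for idx in group_idx]
            if _amova_from_d2(d2, perm_idx).fst >= res.fst:
                b += 1
        res.p_value = (b + 1) / (n_perm + 1)
        res.n_permutations = n_perm
    return res


def pairwise_fst(
    G: GenotypeMatrix,
    scheme: GroupScheme,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """AMOVA-based Fst for every group pair.

    Returns (Fst matrix, p-value matrix, between-group mean pairwise
    difference matrix) as labelled DataFrames. The difference matrix's
    diagonal holds within-group pi.
    """
    groups = scheme.groups()
    labels = list(groups)
    k = len(labels)
    fst = pd.DataFrame(np.zeros((k, k)), index=labels, columns=labels)
    pval = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    dxy = pd.DataFrame(np.zeros((k, k)), index=labels, columns=labels)
    rng = np.random.default_rng(seed)
    for i in range(k):
        sub_i = G.subset_accessions(groups[labels[i]])
        dxy.iloc[i, i] = mean_pairwise_differences(sub_i) if len(groups[labels[i]]) > 1 else np.nan
        for j in range(i + 1, k):
            pair = GroupScheme(
                f"{labels[i]}|{labels[j]}",
                {**{a: labels[i] for a in groups[labels[i]]},
                 **{a: labels[j] for a in groups[labels[j]]}},
            )
            res = amova(G, pair, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
            fst.iloc[i, j] = fst.iloc[j, i] = res.fst
            pval.iloc[i, j] = pval.iloc[j, i] = res.p_value
            both = G.subset_accessions(groups[labels[i]] + groups[labels[j]])
            d2, _ = _pairwise_diff_matrix(both)
            ni = len(groups[labels[i]])
            cross = d2[:ni, ni:]
            dxy.iloc[i, j] = dxy.iloc[j, i] = float(np.nanmean(cross))
    return fst, pval, dxy


# ---------------------------------------------------------------------------
# Nei standard distance
# ---------------------------------------------------------------------------


def nei_distance(G: GenotypeMatrix, scheme: GroupScheme) -> pd.DataFrame:
    """Nei (1972) standard genetic distance between groups.

    D = -ln( Jxy / sqrt(Jx * Jy) ), with the J identity terms averaged over
    loci shared (frequency defined) by both groups. Infinite when Jxy = 0.
    """
    groups = scheme.groups()
    labels = list(groups)
    freqs = {}
    for lab in labels:
        p, _ = haploid_freqs(G.subset_accessions(groups[lab]))
        freqs[lab] = p
    k = len(labels)
    D = pd.DataFrame(np.zeros((k, k)), index=labels, columns=labels)
    for i in range(k):
        for j in range(i + 1, k):
            px, py = freqs[labels[i]], freqs[labels[j]]
            ok = np.isfinite(px) & np.isfinite(py)
            jx = float(np.mean(px[ok] ** 2 + (1 - px[ok]) ** 2))
            jy = float(np.mean(py[ok] ** 2 + (1 - py[ok]) ** 2))
            jxy = float(np.mean(px[ok] * py[ok] + (1 - px[ok]) * (1 - py[ok])))
            if jxy <= 0:
                logger.warning("Jxy = 0 for %s vs %s; distance infinite", labels[i], labels[j])
                d = np.inf
            else:
                d = -np.log(jxy / np.sqrt(jx * jy))
            D.iloc[i, j] = D.iloc[j, i] = d
    return D


# ---------------------------------------------------------------------------
# unique alleles
# ---------------------------------------------------------------------------


def unique_alleles(G: GenotypeMatrix, scheme: GroupScheme, rare_maf: float = 0.05):
    """Catalogue group-private minor alleles on a MAF-unfiltered marker set.

    The minor allele of each marker (haploid coding, panel-wide; ties break
    to the alternate allele) is *unique* to a group when its copy count is
    positive there and zero in every other group. A unique allele is *rare*
    when its frequency within the owner group is below ``rare_maf``.

    Returns (per-allele catalogue DataFrame, per-group summary DataFrame).
    """
    groups = scheme.groups()
    labels = list(groups)
    ids_all = [a for ids in groups.values() for a in ids]
    sub = G.subset_accessions(ids_all)
    H = sub.haploid()
    sizes = [len(groups[lab]) for lab in labels]
    bounds = np.cumsum([0] + sizes)
    # panel-wide minor allele
    fin = np.isfinite(H)
    tot = fin.sum(axis=0).astype(float)
    alt = np.nansum(H, axis=0)
    with np.errstate(invalid="ignore"):
        p_alt = alt / np.where(tot > 0, tot, np.nan)
    minor_is_alt = p_alt <= 0.5
    minor = np.where(minor_is_alt[None, :], H, 1.0 - H)  # NaN propagates
    counts = np.zeros((len(labels), G.n_markers))
    obs = np.zeros((len(labels), G.n_markers))
    for gi in range(len(labels)):
        rows = slice(bounds[gi], bounds[gi + 1])
        counts[gi] = np.nansum(minor[rows], axis=0)
        obs[gi] = fin[rows].sum(axis=0)
    present = counts > 0
    owner_count = present.sum(axis=0)
    is_unique = (owner_count == 1) & (np.nansum(counts, axis=0) > 0)
    owner_idx = np.argmax(present, axis=0)
    records = []
    for j in np.flatnonzero(is_unique):
        gi = owner_idx[j]
        freq = counts[gi, j] / obs[gi, j] if obs[gi, j] > 0 else np.nan
        records.append({
            "marker_id": sub.marker_ids[j],
            "allele": "alt" if minor_is_alt[j] else "ref",
            "owner_group": labels[gi],
            "freq_in_owner": freq,
            "rare": bool(freq < rare_maf),
        })
    catalogue = pd.DataFrame(
        records, columns=["marker_id", "allele", "owner_group", "freq_in_owner", "rare"]
    )
    rows = []
    for lab in labels:
        own = catalogue[catalogue["owner_group"] == lab] if len(catalogue) else catalogue
        rows.append({
            "group": lab,
            "n_unique": int(len(own)),
            "n_unique_maf_gt": int((own["freq_in_owner"] > rare_maf).sum()) if len(own) else 0,
            "mean_freq": float(own["freq_in_owner"].mean()) if len(own) else np.nan,
        })
    summary = pd.DataFrame(rows).sort_values("n_unique", ascending=False, ignore_index=True)
    return catalogue, summary
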