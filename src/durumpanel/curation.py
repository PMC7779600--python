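"""Marker- and accession-level curation of SNP panels.

Implements the stepwise array-curation pipeline for an inbred panel:
minor-allele carrier and MAF filters, windowed LD pruning (merge or thin),
LD-based placement of multi-hit markers, identity-by-state similarity with
duplicate detection, and a masking harness that scores any pluggable
imputer by concordance on hidden calls.

Allele frequencies here are computed over observed (non-missing) calls with
two gene copies per accession — the usual array convention; the diversity
module uses haploid coding instead (see its docstring).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core_io import MISSING, GenotypeMatrix, GroupScheme, MarkerMap

logger = logging.getLogger(__name__)


class ParameterError(ValueError):
    """Out-of-range curation parameter."""


class ContractError(RuntimeError):
    """A pluggable component violated its contract."""


# ---------------------------------------------------------------------------
# frequency helpers (diploid convention)
# ---------------------------------------------------------------------------


def allele_counts(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(alt copies, observed copies) per marker, 2 copies per accession."""
    obs = G.observed()
    calls = np.where(obs, G.calls, 0)
    alt = calls.sum(axis=0).astype(float)
    total = 2.0 * obs.sum(axis=0)
    return alt, total


def maf(G: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per marker over observed calls (NaN if none)."""
    alt, total = allele_counts(G)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, alt / total, np.nan)
    return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_min_carriers(G: GenotypeMatrix, min_carriers: int = 3) -> GenotypeMatrix:
    """Drop markers whose minor allele is carried by fewer accessions.

    A carrier is an accession holding at least one copy of the minor allele
    (a heterozygote counts once). Monomorphic markers are dropped too.
    """
    if G.n_markers == 0 or G.n_accessions == 0:
        raise ValueError("empty genotype matrix")
    alt, total = allele_counts(G)
    ref = total - alt
    alt_is_minor = alt <= ref
    carriers_alt = (G.calls >= 1).sum(axis=0)  # dosage 1 or 2
    obs = G.observed()
    carriers_ref = ((G.calls <= 1) & obs).sum(axis=0)  # dosage 0 or 1
    minor_copies = np.minimum(alt, ref)
    minor_carriers = np.where(alt_is_minor, carriers_alt, carriers_ref)
    keep = (minor_copies > 0) & (minor_carriers >= min_carriers)
    return G.subset_markers(keep)


def filter_maf(
    G: GenotypeMatrix,
    threshold: float = 0.05,
    by_group: GroupScheme | None = None,
) -> GenotypeMatrix:
    """Keep markers with MAF strictly greater than ``threshold``.

    With ``by_group`` the MAF is computed within each group and a marker is
    kept if it clears the threshold in at least one group.
    """
    if not 0 < threshold <= 0.5:
        raise ParameterError(f"MAF threshold {threshold} outside (0, 0.5]")
    if by_group is None:
        keep = maf(G) > threshold
    else:
        keep = np.zeros(G.n_markers, dtype=bool)
        for ids in by_group.groups().values():
            keep |= maf(G.subset_accessions(ids)) > threshold
    keep &= ~np.isnan(maf(G))
    if not keep.any():
        logger.warning("MAF filter removed every marker")
    return G.subset_markers(keep)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _pairwise_complete_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns over complete pairs."""
    m = (x != MISSING) & (y != MISSING)
    n = int(m.sum())
    if n < 2:
        return np.nan
    xv = x[m].astype(float)
    yv = y[m].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


@dataclass
class MergeGroup:
    representative: str
    members: list[str]


def ld_prune(
    G: GenotypeMatrix,
    M: MarkerMap,
    r2_cut: float,
    mode: str = "thin",
    window: int = 250,
    step: int = 25,
) -> tuple[GenotypeMatrix, list[MergeGroup]]:
    """Greedy windowed LD prune within each chromosome.

    Scans markers left to right; a marker joins the group of the first kept
    representative within ``window`` markers upstream whose pairwise r2 is at
    least ``r2_cut``, otherwise it starts a new group. In ``thin`` mode the
    representative call is kept as is; in ``merge`` mode its missing cells
    are filled by the consensus of the group members (members are
    sign-aligned to the representative first, so complementary coding merges
    too). The representative is the leftmost member by position.

    The ``step`` parameter is kept for interface compatibility with
    window-stepping implementations; the scan here advances one marker at a
    time, which is equivalent for grouping purposes.
    """
    if r2_cut <= 0 or r2_cut > 1:
        raise ParameterError(f"r2_cut {r2_cut} outside (0, 1]")
    if not M.is_sorted():
        raise ValueError("marker map must be sorted by chromosome/position")
    del step  # one-marker advance subsumes any coarser step

    chrom = np.asarray(M.chromosomes)
    groups: list[list[int]] = []  # member indices, first = representative
    rep_of_chrom: dict[str, list[int]] = {}  # group indices per chromosome
    for j in range(G.n_markers):
        c = chrom[j]
        placed = False
        for gi in rep_of_chrom.get(c, []):
            rep = groups[gi][0]
            if j - rep > window:
                continue
            r2 = _pairwise_complete_r2(G.calls[:, rep], G.calls[:, j])
            if np.isfinite(r2) and r2 >= r2_cut:
                groups[gi].append(j)
                placed = True
                break
        if not placed:
            groups.append([j])
            rep_of_chrom.setdefault(c, []).append(len(groups) - 1)

    keep_idx = [g[0] for g in groups]
    calls = G.calls[:, keep_idx].copy()
    report = [
        MergeGroup(G.marker_ids[g[0]], [G.marker_ids[j] for j in g])
        for g in groups
        if len(g) > 1
    ]
    if mode == "merge":
        for out_col, g in enumerate(groups):
            if len(g) == 1:
                continue
            rep = g[0]
            col = calls[:, out_col]
            hole = col == MISSING
            if not hole.any():
                continue
            aligned = []
            for j in g[1:]:
                other = G.calls[:, j]
                m = (G.calls[:, rep] != MISSING) & (other != MISSING)
                flip = False
                if m.sum() >= 2:
                    a = G.calls[m, rep].astype(float)
                    b = other[m].astype(float)
                    if a.std() > 0 and b.std() > 0 and np.corrcoef(a, b)[0, 1] < 0:
                        flip = True
                aligned.append(np.where(other == MISSING, MISSING, 2 - other if flip else other))
            stack = np.stack(aligned, axis=1)  # accessions x members
            for i in np.flatnonzero(hole):
                vals = stack[i][stack[i] != MISSING]
                if vals.size:
                    # consensus = most frequent aligned member call, low dosage on ties
                    u, cnt = np.unique(vals, return_counts=True)
                    col[i] = u[np.argmax(cnt)]
        calls = calls.astype(np.int8)
    elif mode != "thin":
        raise ParameterError(f"unknown prune mode {mode!r}")

    ids = [G.marker_ids[j] for j in keep_idx]
    Gp = GenotypeMatrix(list(G.accession_ids), ids, calls)
    Mp = M.subset(ids)
    # keep matrix/map paired for callers that need coordinates
    Gp.pruned_map = Mp  # type: ignore[attr-defined]
    return Gp, report


# ---------------------------------------------------------------------------
# multi-hit placement
# ---------------------------------------------------------------------------


def assign_multihit_position(
    marker_calls: np.ndarray,
    candidates: Sequence[tuple[str, int]],
    G: GenotypeMatrix,
    M: MarkerMap,
    r2_floor: float = 0.3,
    window_bp: int = 5_000_000,
    k_neighbors: int = 10,
):
    """Place a marker with several candidate map positions by local LD.

    For each candidate (chromosome, bp) the mean r2 between the marker's
    calls and the ``k_neighbors`` nearest mapped markers within ``window_bp``
    is computed; the best candidate wins if its mean exceeds ``r2_floor``.

    Returns ``(chromosome, position)`` or ``(None, reason)``.
    """
    if not candidates:
        raise ValueError("no candidate positions supplied")
    best = None
    best_mean = -np.inf
    any_neighbors = False
    for c_chrom, c_pos in candidates:
        on = np.asarray(M.chromosomes) == c_chrom
        d = np.abs(M.positions - int(c_pos))
        near = on & (d <= window_bp)
        idx = np.flatnonzero(near)
        if idx.size == 0:
            continue
        any_neighbors = True
        idx = idx[np.argsort(d[idx])][:k_neighbors]
        r2s = [
            _pairwise_complete_r2(marker_calls, G.calls[:, j]) for j in idx
        ]
        r2s = [v for v in r2s if np.isfinite(v)]
        if not r2s:
            continue
        mean_r2 = float(np.mean(r2s))
        if mean_r2 > best_mean:
            best_mean = mean_r2
            best = (c_chrom, int(c_pos))
    if not any_neighbors:
        return None, "no mapped neighbors within window at any candidate"
    if best is None or best_mean <= r2_floor:
        return None, f"best mean r2 {max(best_mean, 0):.3f} not above floor {r2_floor}"
    return best


# ---------------------------------------------------------------------------
# identity-by-state
# ---------------------------------------------------------------------------


def ibs_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Pairwise identity-by-state over pairwise-complete markers.

    IBS(a, b) = mean over shared markers of (2 - |dosage_a - dosage_b|) / 2.
    Symmetric, unit diagonal; a pair with no shared markers is NaN (flagged
    via log warning).
    """
    if G.n_accessions < 2:
        raise ValueError("IBS needs at least two accessions")
    obs = G.observed().astype(np.float64)
    ind = [(G.calls == d).astype(np.float64) for d in (0, 1, 2)]
    n = [[ind[u] @ ind[v].T for v in range(3)] for u in range(3)]
    shared = obs @ obs.T
    diffsum = (n[0][1] + n[1][0] + n[1][2] + n[2][1]) + 2.0 * (n[0][2] + n[2][0])
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = (2.0 * shared - diffsum) / (2.0 * shared)
    if np.isnan(ibs[~np.eye(G.n_accessions, dtype=bool)]).any():
        logger.warning("accession pairs with zero shared markers: IBS undefined (NaN)")
    np.fill_diagonal(ibs, 1.0)
    return ibs


def find_duplicates(
    ibs: np.ndarray, accession_ids: Sequence[str], cut: float = 0.95
) -> tuple[list[list[str]], list[str]]:
    """Single-linkage duplicate groups over IBS > ``cut``.

    Returns (groups of size >= 2, retained accession list). The first-listed
    member of each group is retained; all other accessions are retained too.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(accession_ids)
    adj = np.nan_to_num(ibs, nan=0.0) > cut
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    comp: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        comp.setdefault(int(lab), []).append(i)
    groups = [
        [accession_ids[i] for i in members]
        for members in comp.values()
        if len(members) > 1
    ]
    drop = {a for g in groups for a in g[1:]}
    retained = [a for a in accession_ids if a not in drop]
    return groups, retained


# ---------------------------------------------------------------------------
# imputation-accuracy harness
# ---------------------------------------------------------------------------


def mode_imputer(G: GenotypeMatrix) -> GenotypeMatrix:
    """Fill missing calls with the per-marker mode (ties -> lower dosage).

    A deliberately simple bundled imputer used to exercise the masking
    harness; any function GenotypeMatrix -> GenotypeMatrix with no missing
    cells left can be plugged in instead.
    """
    calls = G.calls.copy()
    for j in range(G.n_markers):
        col = calls[:, j]
        hole = col == MISSING
        if not hole.any():
            continue
        vals = col[~hole]
        if vals.size == 0:
            fill = 0
        else:
            u, cnt = np.unique(vals, return_counts=True)
            fill = int(u[np.argmax(cnt)])
        col[hole] = fill
    return GenotypeMatrix(list(G.accession_ids), list(G.marker_ids), calls)


@dataclass
class ImputationAccuracy:
    mean: float
    std: float
    per_replicate: np.ndarray
    mask_fraction: float
    replicates: int


def imputation_accuracy(
    G: GenotypeMatrix,
    imputer: Callable[[GenotypeMatrix], GenotypeMatrix],
    mask_fraction: float = 0.01,
    replicates: int = 1000,
    seed: int = 0,
) -> ImputationAccuracy:
    """Score an imputer by randomly masking called genotypes.

    Each replicate independently masks ``mask_fraction`` of the non-missing
    cells, runs the imputer, and scores the fraction of masked cells
    recovered exactly. Deterministic given ``seed``.
    """
    if not 0 < mask_fraction < 1:
        raise ParameterError("mask_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    obs_idx = np.flatnonzero(G.observed().ravel())
    if obs_idx.size == 0:
        raise ValueError("no called genotypes to mask")
    n_mask = max(1, int(round(mask_fraction * obs_idx.size)))
    acc = np.empty(replicates)
    for r in range(replicates):
        pick = rng.choice(obs_idx, size=n_mask, replace=False)
        flat = G.calls.ravel().copy()
        truth = flat[pick].copy()
        flat[pick] = MISSING
        masked = GenotypeMatrix(
            list(G.accession_ids), list(G.marker_ids), flat.reshape(G.calls.shape)
        )
        filled = imputer(masked)
        out = filled.calls.ravel()[pick]
        if (out == MISSING).any():
            raise ContractError("imputer left masked cells missing")
        acc[r] = float(np.mean(out == truth))
    return ImputationAccuracy(
        mean=float(acc.mean()),
        std=float(acc.std(ddof=1)) if replicates > 1 else 0.0,
        per_replicate=acc,
        mask_fraction=mask_fraction,
        replicates=replicates,
    )
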