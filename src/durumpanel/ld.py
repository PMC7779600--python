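"""Linkage-disequilibrium computation and decay modelling.

Pairwise r2 is the squared Pearson correlation of dosage vectors over
pairwise-complete accessions (composite LD — no phasing needed in a selfing
panel). The decay curve is the drift-recombination expectation of r2 under
a sample of n gene copies (Hill & Weir form),

    E[r2] = (10 + C) / ((2 + C)(11 + C))
            * (1 + ((3 + C)(12 + 12 C + C^2)) / (n (2 + C)(11 + C))),

with C = a * d for physical distance d in bp; the single scale parameter a
is fitted by least squares. Critical distances are read off the fitted
curve by monotone inversion; background LD is the 95th quantile of r2 over
inter-chromosomal (unlinked) marker pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .core_io import MISSING, GenotypeMatrix, MarkerMap

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pairwise r2
# ---------------------------------------------------------------------------


def _offset_r2(calls: np.ndarray, d: int) -> np.ndarray:
    """r2 between column j and column j+d for all j, pairwise-complete.

    Vectorised over markers; returns an array of length n_markers - d with
    NaN where a member of the pair has zero variance or < 3 complete pairs.
    """
    x = calls[:, :-d].astype(np.float64)
    y = calls[:, d:].astype(np.float64)
    m = (calls[:, :-d] != MISSING) & (calls[:, d:] != MISSING)
    x = np.where(m, x, 0.0)
    y = np.where(m, y, 0.0)
    n = m.sum(axis=0).astype(np.float64)
    sx = x.sum(axis=0)
    sy = y.sum(axis=0)
    sxx = (x * x).sum(axis=0)
    syy = (y * y).sum(axis=0)
    sxy = (x * y).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        r2 = (cov * cov) / (vx * vy)
    r2[(n < 3) | (vx <= 0) | (vy <= 0)] = np.nan
    return r2


def pairwise_r2(
    G: GenotypeMatrix,
    M: MarkerMap,
    max_dist_bp: float = 50e6,
    max_offset: int | None = None,
) -> pd.DataFrame:
    """Within-chromosome marker-pair r2 up to a physical distance cap.

    Returns a DataFrame (chromosome, id1, id2, dist_bp, r2); pairs where a
    marker has zero variance are skipped. The distance cap bounds the pair
    count — decay is flat beyond background LD anyway.
    """
    if not M.is_sorted():
        raise ValueError("marker map must be sorted by chromosome/position")
    chroms = np.asarray(M.chromosomes)
    pos = M.positions
    frames = []
    for c in M.chromosome_labels():
        idx = np.flatnonzero(chroms == c)
        if idx.size < 2:
            continue
        sub = G.calls[:, idx]
        p = pos[idx]
        top = idx.size - 1 if max_offset is None else min(max_offset, idx.size - 1)
        for d in range(1, top + 1):
            dist = p[d:] - p[:-d]
            sel = dist <= max_dist_bp
            if not sel.any():
                break  # positions sorted: larger offsets only increase distance
            r2 = _offset_r2(sub, d)
            ok = sel & np.isfinite(r2)
            if not ok.any():
                continue
            j = np.flatnonzero(ok)
            frames.append(pd.DataFrame({
                "chromosome": c,
                "id1": [G.marker_ids[idx[a]] for a in j],
                "id2": [G.marker_ids[idx[a + d]] for a in j],
                "dist_bp": dist[j],
                "r2": r2[j],
            }))
    if not frames:
        return pd.DataFrame(columns=["chromosome", "id1", "id2", "dist_bp", "r2"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# decay model
# ---------------------------------------------------------------------------


def expected_r2(C: np.ndarray, n: float) -> np.ndarray:
    """Drift-recombination expectation of r2 at scaled distance C = a*d."""
    C = np.clip(np.asarray(C, dtype=float), 0.0, 1e9)  # curve is flat ~1/C beyond
    base = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    corr = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (
        n * (2.0 + C) * (11.0 + C)
    )
    return base * corr


@dataclass
class LDDecayModel:
    """Fitted single-parameter LD decay curve."""

    n: float  # gene copies (accessions, haploid convention)
    a: float  # recombination scale: C = a * d
    rss: float
    n_pairs: int
    poor_fit: bool = False

    def predict(self, d) -> np.ndarray:
        return expected_r2(self.a * np.asarray(d, dtype=float), self.n)


def fit_decay(pairs: pd.DataFrame, n: float, min_pairs: int = 50) -> LDDecayModel:
    """Least-squares fit of the decay expectation to observed (d, r2) pairs.

    ``n`` is the number of gene copies (= accessions for inbred lines).
    A fit collapsing to zero decay (a at the lower bound) is flagged
    ``poor_fit``.
    """
    d = np.asarray(pairs["dist_bp"], dtype=float)
    r2 = np.asarray(pairs["r2"], dtype=float)
    ok = np.isfinite(d) & np.isfinite(r2)
    d, r2 = d[ok], r2[ok]
    if d.size < min_pairs:
        raise ValueError(f"need >= {min_pairs} pairs to fit the decay curve, got {d.size}")
    lo = 1e-15

    def resid(log_a):
        return expected_r2(np.exp(log_a) * d, n) - r2

    # log-parameterisation keeps a positive; multi-start over decades of scale
    best = None
    for a0 in 10.0 ** np.arange(-10, -2):
        sol = optimize.least_squares(resid, x0=np.log(a0), method="lm", max_nfev=400)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:  # pragma: no cover - lm rarely fails here
        raise RuntimeError("decay fit did not converge")
    a = float(np.exp(best.x[0]))
    poor = False
    if a < lo:
        logger.warning("decay parameter collapsed to zero; flagged poor fit")
        a, poor = lo, True
    rss = float(2.0 * best.cost)
    return LDDecayModel(n=float(n), a=a, rss=rss, n_pairs=int(d.size), poor_fit=poor)


def critical_distance(model: LDDecayModel, level: float = 0.5) -> float:
    """Distance (bp) at which the fitted curve crosses ``level``.

    Monotone bisection on the strictly decreasing fitted curve; raises if
    the curve never reaches the level (level >= r2 at distance 0).
    """
    at0 = float(model.predict(0.0))
    if level >= at0:
        raise ValueError(f"level {level} >= fitted r2 at zero distance ({at0:.4f}): no crossing")
    hi = 1.0
    while model.predict(hi) > level:
        hi *= 10.0
        if hi > 1e15:
            raise ValueError("curve does not reach the level within 1e15 bp")
    sol = optimize.brentq(lambda d: float(model.predict(d)) - level, 0.0, hi, xtol=1e-6)
    return float(sol)


# ---------------------------------------------------------------------------
# background and local LD
# ---------------------------------------------------------------------------


def _r2_for_index_pairs(calls: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Vectorised pairwise-complete r2 for explicit column index pairs."""
    x = calls[:, i].astype(np.float64)
    y = calls[:, j].astype(np.float64)
    m = (calls[:, i] != MISSING) & (calls[:, j] != MISSING)
    x = np.where(m, x, 0.0)
    y = np.where(m, y, 0.0)
    n = m.sum(axis=0).astype(np.float64)
    sx, sy = x.sum(axis=0), y.sum(axis=0)
    sxx, syy, sxy = (x * x).sum(axis=0), (y * y).sum(axis=0), (x * y).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        r2 = (cov * cov) / (vx * vy)
    r2[(n < 3) | (vx <= 0) | (vy <= 0)] = np.nan
    return r2


def background_r2(
    G: GenotypeMatrix,
    M: MarkerMap,
    n_pairs: int = 10000,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Background (unlinked) LD: the 95th quantile of inter-chromosome r2.

    A random subsample of cross-chromosome marker pairs is used; the
    quantile is linear-interpolated between order statistics.
    """
    chroms = np.asarray(M.chromosomes)
    labels = M.chromosome_labels()
    if len(labels) < 2:
        raise ValueError("background LD needs markers on at least two chromosomes")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, G.n_markers, size=4 * n_pairs)
    j = rng.integers(0, G.n_markers, size=4 * n_pairs)
    keep = chroms[i] != chroms[j]
    i, j = i[keep][:n_pairs], j[keep][:n_pairs]
    if i.size == 0:
        raise ValueError("no inter-chromosomal pairs sampled")
    r2 = _r2_for_index_pairs(G.calls, i, j)
    r2 = r2[np.isfinite(r2)]
    return float(np.quantile(r2, quantile))  # linear interpolation (numpy default)


def local_ld(
    G: GenotypeMatrix,
    M: MarkerMap,
    k: int = 50,
    smooth_window: int = 15,
) -> np.ndarray:
    """Per-marker local LD: mean r2 with the k nearest markers by bp.

    Chromosomes with fewer than k+1 markers use all available neighbours
    (flagged with a warning). The raw per-marker track is then smoothed
    with a centred step-sliding window mean (same convention as the sweep
    scans). Returns the smoothed track aligned with the map.
    """
    from .sweepscan import smooth_track

    if not M.is_sorted():
        raise ValueError("marker map must be sorted by chromosome/position")
    chroms = np.asarray(M.chromosomes)
    raw = np.full(G.n_markers, np.nan)
    for c in M.chromosome_labels():
        idx = np.flatnonzero(chroms == c)
        m = idx.size
        if m < 2:
            continue
        if m <= k:
            logger.warning("chromosome %s has %d markers; using all %d neighbours", c, m, m - 1)
        sub = G.calls[:, idx]
        pos = M.positions[idx]
        # r2 between i and i+d for offsets up to k (neighbours live within k index steps)
        R = np.full((m, m), np.nan)
        for d in range(1, min(k, m - 1) + 1):
            v = _offset_r2(sub, d)
            for a in range(m - d):
                R[a, a + d] = R[a + d, a] = v[a]
        for a in range(m):
            others = np.delete(np.arange(m), a)
            dist = np.abs(pos[others] - pos[a])
            take = others[np.argsort(dist, kind="stable")][: min(k, m - 1)]
            vals = R[a, take]
            vals = vals[np.isfinite(vals)]
            raw[idx[a]] = np.mean(vals) if vals.size else np.nan
    return smooth_track(raw, chroms, window=smooth_window)
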