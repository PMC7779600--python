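"""Putative-selection-sweep scanning.

Two per-marker indices are scanned between a pair of accession groups:

* **Fst** — the single-locus Weir–Cockerham variance-component estimator on
  haploid-coded calls (one gene copy per inbred line);
* **DRI** — the diversity reduction index, an epsilon-regularised ratio of
  unbiased Nei gene diversities, DRI = (He_ref + eps) / (He_target + eps);
  values above 1 mark reduced diversity in the target (derived) group.

Raw tracks are smoothed with a centred 15-marker sliding window (one-marker
step), and significance is decided in two steps: (1) contiguous runs of
smoothed values at or above the 90th percentile of the genome-wide smoothed
distribution become candidate peaks, with neighbouring apexes closer than
the merge distance (by default the group pair's LD critical distance at
r2 = 0.5) collapsed into the highest; (2) the distribution is re-formed
with each merged peak region represented once by its apex value, and the
95th percentile of the re-formed distribution is the final index-specific
threshold. Significant peaks from several comparisons/indices that overlap
(or nearly overlap) are grouped into putative-selection-sweep clusters and
can be annotated with features from BED/GFF3 intervals.

All intervals here are half-open ``[start, end)`` bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, MarkerMap
from .diversity import haploid_freqs, nei_gene_diversity

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------


@dataclass
class ScanConfig:
    """Knobs of the two-step significance procedure."""

    window: int = 15  # smoothing window, markers
    step: int = 1  # window step, markers
    candidate_percentile: float = 90.0
    final_percentile: float = 95.0
    merge_distance_bp: float = 5e6  # default when no LD-derived distance given
    dri_epsilon: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.candidate_percentile < 100 and 0 < self.final_percentile < 100):
            raise ValueError("percentiles must lie in (0, 100)")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("smoothing window must be odd and >= 1")


@dataclass
class ScanTrack:
    """Per-marker raw and smoothed values of one index for one comparison."""

    comparison: str
    index_type: str  # "FST" or "DRI"
    raw: np.ndarray
    smoothed: np.ndarray
    marker_map: MarkerMap

    def to_frame(self) -> pd.DataFrame:
        M = self.marker_map
        return pd.DataFrame({
            "chromosome": M.chromosomes,
            "start": M.positions - 1,  # half-open bedgraph-style
            "end": M.positions,
            "marker_id": M.marker_ids,
            "raw": self.raw,
            "smoothed": self.smoothed,
        })


@dataclass
class SweepPeak:
    chromosome: str
    start: int  # half-open bp
    end: int
    apex_marker: str
    apex_value: float
    index_type: str
    comparison: str
    significant: bool = False


@dataclass
class PSWCluster:
    cluster_id: str
    chromosome: str
    start: int
    end: int
    members: list[SweepPeak]
    indices: set[str] = field(default_factory=set)
    comparisons: set[str] = field(default_factory=set)
    features: list[dict] = field(default_factory=list)

    @property
    def size_mbp(self) -> float:
        return (self.end - self.start) / 1e6


# ---------------------------------------------------------------------------
# per-marker indices
# ---------------------------------------------------------------------------


def _group_freqs(G: GenotypeMatrix, ids: Sequence[str]):
    return haploid_freqs(G.subset_accessions(list(ids)))


def wc_fst_per_marker(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> np.ndarray:
    """Single-locus Weir–Cockerham Fst for two haploid samples.

    Mean-square decomposition for haploid data: with population frequencies
    p_i from n_i gene copies,

        MSP = sum n_i (p_i - p_bar)^2 / (r - 1)
        MSG = sum n_i p_i (1 - p_i) / sum (n_i - 1)
        theta = (MSP - MSG) / (MSP + (n_c - 1) MSG)

    with n_c = (N - sum n_i^2 / N)/(r - 1). Markers monomorphic across both
    samples get 0; markers absent from one sample get NaN.
    """
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    N = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (n1 * p1 + n2 * p2) / N
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r - 1 = 1
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (N - 2.0)
        nc = (N - (n1**2 + n2**2) / N)  # / (r - 1) = 1
        theta = (msp - msg) / (msp + (nc - 1.0) * msg)
    mono = np.isfinite(pbar) & ((pbar <= 0) | (pbar >= 1))
    theta = np.where(mono, 0.0, theta)
    undef = ~np.isfinite(p1) | ~np.isfinite(p2) | (n1 < 2) | (n2 < 2)
    theta = np.where(undef, np.nan, theta)
    return theta


def wc_fst_multilocus(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> float:
    """Multilocus Weir–Cockerham Fst: per-locus variance components summed
    over loci before taking the ratio (the standard genome-wide estimate;
    averaging per-locus ratios instead is biased when drift is strong).

    Loci monomorphic across both samples, or absent from one, are excluded.
    """
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    N = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (n1 * p1 + n2 * p2) / N
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (N - 2.0)
        nc = N - (n1**2 + n2**2) / N
    ok = (
        np.isfinite(msp) & np.isfinite(msg)
        & np.isfinite(pbar) & (pbar > 0) & (pbar < 1)
        & (n1 >= 2) & (n2 >= 2)
    )
    num = float((msp - msg)[ok].sum())
    den = float((msp + (nc - 1.0) * msg)[ok].sum())
    if den <= 0:
        raise ValueError("no usable polymorphic loci for the multilocus estimate")
    return num / den


def snp_fst_scan(
    G: GenotypeMatrix,
    M: MarkerMap,
    group_a: Sequence[str],
    group_b: Sequence[str],
    comparison: str | None = None,
    config: ScanConfig | None = None,
) -> ScanTrack:
    """Per-marker two-population Fst track with sliding-window smoothing."""
    config = config or ScanConfig()
    if len(group_a) < 5 or len(group_b) < 5:
        raise ValueError("each group needs at least 5 accessions for the scan")
    p1, n1 = _group_freqs(G, group_a)
    p2, n2 = _group_freqs(G, group_b)
    raw = wc_fst_per_marker(p1, n1, p2, n2)
    if np.isnan(raw).any():
        logger.warning("%d markers missing in one group; excluded from smoothing",
                       int(np.isnan(raw).sum()))
    smoothed = smooth_track(raw, np.asarray(M.chromosomes), window=config.window,
                            step=config.step)
    label = comparison or "A_vs_B"
    return ScanTrack(label, "FST", raw, smoothed, M)


def snp_dri_scan(
    G: GenotypeMatrix,
    M: MarkerMap,
    reference_group: Sequence[str],
    target_group: Sequence[str],
    comparison: str | None = None,
    config: ScanConfig | None = None,
) -> ScanTrack:
    """Per-marker diversity reduction index track (reference over target)."""
    config = config or ScanConfig()
    if len(reference_group) < 5 or len(target_group) < 5:
        raise ValueError("each group needs at least 5 accessions for the scan")
    eps = config.dri_epsilon
    p_r, n_r = _group_freqs(G, reference_group)
    p_t, n_t = _group_freqs(G, target_group)
    he_r = nei_gene_diversity(p_r, n_r)
    he_t = nei_gene_diversity(p_t, n_t)
    raw = (np.nan_to_num(he_r) + eps) / (np.nan_to_num(he_t) + eps)
    raw = np.where(np.isfinite(he_r) & np.isfinite(he_t), raw, np.nan)
    smoothed = smooth_track(raw, np.asarray(M.chromosomes), window=config.window,
                            step=config.step)
    label = comparison or "ref_vs_target"
    return ScanTrack(label, "DRI", raw, smoothed, M)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def smooth_track(
    values: np.ndarray,
    chromosomes: np.ndarray,
    window: int = 15,
    step: int = 1,
) -> np.ndarray:
    """Centred moving average per chromosome with truncated edges.

    Missing values are left out of both numerator and denominator. The
    one-marker step yields a smoothed value at every marker; coarser steps
    evaluate every ``step``-th marker and leave NaN between.
    """
    values = np.asarray(values, dtype=float)
    out = np.full_like(values, np.nan)
    kernel = np.ones(window)
    for c in pd.unique(chromosomes):
        idx = np.flatnonzero(chromosomes == c)
        v = values[idx]
        if idx.size < 2:
            out[idx] = v  # passthrough, too short to smooth
            continue
        fin = np.isfinite(v)
        # centred slice of the full convolution (np.convolve 'same' misbehaves
        # when the kernel is longer than a short chromosome)
        half = (window - 1) // 2
        num = np.convolve(np.where(fin, v, 0.0), kernel, mode="full")[half:half + idx.size]
        den = np.convolve(fin.astype(float), kernel, mode="full")[half:half + idx.size]
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / den
        if step > 1:
            mask = np.zeros(idx.size, dtype=bool)
            mask[::step] = True
            sm = np.where(mask, sm, np.nan)
        out[idx] = sm
    return out


# ---------------------------------------------------------------------------
# two-step significance
# ---------------------------------------------------------------------------


def _runs_above(values: np.ndarray, level: float) -> list[tuple[int, int]]:
    """Half-open index runs where values >= level (NaN breaks a run)."""
    above = np.isfinite(values) & (values >= level)
    runs = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(values)))
    return runs


def detect_significant(
    track: ScanTrack,
    config: ScanConfig | None = None,
    merge_distance_bp: float | None = None,
) -> list[SweepPeak]:
    """Two-step peak significance on a smoothed track.

    Step 1: contiguous runs of smoothed values at or above the candidate
    percentile (genome-wide) are candidate peaks; apexes on the same
    chromosome closer than the merge distance collapse into the highest.
    Step 2: the smoothed-value distribution is re-formed with each merged
    peak region contributing its apex value once; peaks whose apex reaches
    the final percentile of that distribution are significant. Peak
    intervals are the contiguous run around the apex staying above the
    step-1 level, reported half-open in bp.
    """
    config = config or ScanConfig()
    merge_bp = config.merge_distance_bp if merge_distance_bp is None else merge_distance_bp
    sm = track.smoothed
    M = track.marker_map
    finite = sm[np.isfinite(sm)]
    if finite.size == 0 or finite.max() == finite.min():
        return []  # empty or flat track carries no signal
    q1 = float(np.percentile(finite, config.candidate_percentile))
    chroms = np.asarray(M.chromosomes)
    pos = M.positions

    candidates = []  # (chrom, run_start, run_end, apex_index)
    for c in M.chromosome_labels():
        idx = np.flatnonzero(chroms == c)
        for s, e in _runs_above(sm[idx], q1):
            run = idx[s:e]
            apex = run[int(np.nanargmax(sm[run]))]
            candidates.append((c, run[0], run[-1], apex))

    # merge neighbouring apexes on the same chromosome
    merged = []
    for c in M.chromosome_labels():
        on = sorted((x for x in candidates if x[0] == c), key=lambda x: pos[x[3]])
        group: list[tuple] = []
        for cand in on:
            if group and pos[cand[3]] - pos[group[-1][3]] < merge_bp:
                group.append(cand)
            else:
                if group:
                    merged.append(max(group, key=lambda x: sm[x[3]]))
                group = [cand]
        if group:
            merged.append(max(group, key=lambda x: sm[x[3]]))

    # re-formed distribution: non-candidate values + one apex per merged peak
    in_candidate = np.zeros(len(sm), dtype=bool)
    for _, s, e, _ in candidates:
        in_candidate[s:e + 1] = True
    reformed = np.concatenate([
        sm[np.isfinite(sm) & ~in_candidate],
        np.array([sm[apex] for _, _, _, apex in merged]),
    ])
    q2 = float(np.percentile(reformed, config.final_percentile)) if reformed.size else np.inf

    peaks = []
    for c, s, e, apex in sorted(merged, key=lambda x: (str(x[0]), pos[x[3]])):
        peaks.append(SweepPeak(
            chromosome=str(c),
            start=int(pos[s]) - 1,  # 1-based inclusive -> half-open
            end=int(pos[e]),
            apex_marker=M.marker_ids[apex],
            apex_value=float(sm[apex]),
            index_type=track.index_type,
            comparison=track.comparison,
            significant=bool(sm[apex] >= q2),
        ))
    return peaks


# ---------------------------------------------------------------------------
# PSW clustering and annotation
# ---------------------------------------------------------------------------


def cluster_psw(
    peak_sets: Iterable[Sequence[SweepPeak]],
    merge_gap_bp: float = 0.0,
) -> list[PSWCluster]:
    """Group significant peaks across comparisons/indices into clusters.

    Peaks on the same chromosome that overlap (half-open) or whose gap is
    below ``merge_gap_bp`` are connected; connected components with at
    least two member signals — or one signal supported by both indices —
    become clusters named ``Cls-chr<label>.<n>`` ordered by position.
    """
    peaks = [p for ps in peak_sets for p in ps if p.significant]
    clusters: list[PSWCluster] = []
    by_chrom: dict[str, list[SweepPeak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chromosome, []).append(p)
    for c, plist in by_chrom.items():
        plist = sorted(plist, key=lambda p: (p.start, p.end))
        comp: list[SweepPeak] = []
        comp_end = -np.inf
        comps: list[list[SweepPeak]] = []
        for p in plist:
            if comp and p.start < comp_end + merge_gap_bp:
                comp.append(p)
                comp_end = max(comp_end, p.end)
            else:
                if comp:
                    comps.append(comp)
                comp = [p]
                comp_end = p.end
        if comp:
            comps.append(comp)
        n = 0
        for members in comps:
            indices = {p.index_type for p in members}
            if len(members) < 2 and len(indices) < 2:
                continue
            n += 1
            clusters.append(PSWCluster(
                cluster_id=f"Cls-chr{c}.{n}",
                chromosome=c,
                start=min(p.start for p in members),
                end=max(p.end for p in members),
                members=members,
                indices=indices,
                comparisons={p.comparison for p in members},
            ))
    return clusters


def read_features(path) -> pd.DataFrame:
    """Read feature intervals from BED or GFF3 into half-open bp intervals.

    Columns of the result: chromosome, start, end, name.
    """
    import pyranges as pr

    path = str(path)
    if path.endswith((".gff", ".gff3", ".gtf")):
        gr = pr.read_gff3(path)
    else:
        gr = pr.read_bed(path)
    df = gr.df
    name_col = next((c for c in ("Name", "ID", "Feature") if c in df.columns), None)
    return pd.DataFrame({
        "chromosome": df["Chromosome"].astype(str),
        "start": df["Start"].astype(int),
        "end": df["End"].astype(int),
        "name": df[name_col].astype(str) if name_col else [
            f"feature{i}" for i in range(len(df))
        ],
    })


def annotate(
    clusters: Sequence[PSWCluster],
    features: pd.DataFrame,
    known_chromosomes: Iterable[str] | None = None,
) -> list[PSWCluster]:
    """Attach overlapping features to each cluster (half-open intersection).

    Features on chromosomes absent from ``known_chromosomes`` are skipped
    with a warning. Feature lists are sorted by overlap length, longest
    first. Mutates and returns the cluster list.
    """
    if known_chromosomes is not None:
        known = set(map(str, known_chromosomes))
        bad = ~features["chromosome"].isin(known)
        if bad.any():
            logger.warning("%d features on unknown chromosomes skipped", int(bad.sum()))
            features = features[~bad]
    for cl in clusters:
        sub = features[features["chromosome"] == cl.chromosome]
        ov_start = np.maximum(sub["start"].to_numpy(), cl.start)
        ov_end = np.minimum(sub["end"].to_numpy(), cl.end)
        ov = ov_end - ov_start
        hit = ov > 0
        rows = sub[hit].assign(overlap=ov[hit])
        rows = rows.sort_values("overlap", ascending=False, kind="stable")
        cl.features = rows.to_dict("records")
    return list(clusters)


def peaks_frame(peaks: Sequence[SweepPeak]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chromosome": p.chromosome, "start": p.start, "end": p.end,
        "apex_marker": p.apex_marker, "apex_value": p.apex_value,
        "index": p.index_type, "comparison": p.comparison,
        "significant": p.significant,
    } for p in peaks])


def clusters_frame(clusters: Sequence[PSWCluster]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cluster_id": c.cluster_id, "chromosome": c.chromosome,
        "start": c.start, "end": c.end, "size_mbp": c.size_mbp,
        "n_members": len(c.members),
        "indices": ",".join(sorted(c.indices)),
        "comparisons": ",".join(sorted(c.comparisons)),
        "features": ",".join(f["name"] for f in c.features),
    } for c in clusters])
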