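"""Synthetic multi-population inbred SNP panels with controlled structure.

The generator is the test substrate for every other module: it produces
panels of near-homozygous lines from several populations with

* calibrated divergence — per-population allele frequencies follow the
  Balding–Nichols model, Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral
  frequency p ~ Uniform(0.05, 0.95), so the realised per-marker fixation
  index matches the configured F;
* block-wise LD — within each (population, block) every line copies one of
  K founder "ranks" and a site's minor allele occupies the first
  m = K * p_i founder ranks (stochastic rounding keeps the realised
  frequency unbiased). Sites in a block therefore carry nested allele
  sets (high r2); blocks are independent (r2 ~ 0 across blocks). Block
  lengths are exponential with a per-population mean, giving a
  landrace-like short-LD group and a modern-like long-LD group;
* selfing-level homozygosity and random missing calls at configured rates;
* injected sweeps — intervals where the target population's major-allele
  frequency is pushed to a final value (default 0.98), collapsing He and
  inflating Fst locally.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    MISSING,
    AccessionMetadata,
    GenotypeMatrix,
    GroupScheme,
    MarkerMap,
    write_hapmap,
    write_metadata,
)

logger = logging.getLogger(__name__)

_CHROM_LABELS = [f"{i}{g}" for i in range(1, 8) for g in ("A", "B")]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PopulationSpec:
    label: str
    size: int
    fst: float = 0.13  # Balding–Nichols divergence parameter F
    block_length_bp: float = 10e6  # mean LD block length
    germplasm_class: str = "modern"

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValueError(f"F must lie in [0, 1), got {self.fst}")
        if self.size < 2:
            raise ValueError("population size must be >= 2")


@dataclass
class SweepSpec:
    population: str
    chromosome: str
    start: int  # half-open bp interval
    end: int
    final_freq: float = 0.98


@dataclass
class SimConfig:
    populations: list[PopulationSpec]
    n_chromosomes: int = 14
    markers_per_chromosome: int = 360
    chromosome_length_bp: int = 600_000_000
    founder_pool: int = 24
    homozygosity: float = 0.98
    missing_rate: float = 0.02
    sweeps: list[SweepSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.sweeps:
            if not 0 <= s.start < s.end <= self.chromosome_length_bp:
                raise ValueError(
                    f"sweep interval [{s.start}, {s.end}) outside chromosome "
                    f"of length {self.chromosome_length_bp}"
                )
        for p in self.populations:
            if p.block_length_bp > self.chromosome_length_bp:
                raise ValueError("LD block longer than the chromosome")

    def chromosome_labels(self) -> list[str]:
        labs = list(_CHROM_LABELS[: self.n_chromosomes])
        labs += [f"chr{i}" for i in range(len(labs) + 1, self.n_chromosomes + 1)]
        return labs[: self.n_chromosomes]


@dataclass
class SimulatedPanel:
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    metadata: dict[str, AccessionMetadata]
    truth: dict

    def __iter__(self):  # unpack as (G, M, metadata)
        return iter((self.genotypes, self.marker_map, self.metadata))

    def scheme(self, name: str = "population") -> GroupScheme:
        return GroupScheme(name, {
            a: m.breeding_program for a, m in self.metadata.items()
        })


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _block_bounds(rng, length_bp: int, mean_block: float) -> np.ndarray:
    """Half-open block breakpoints covering [0, length_bp)."""
    cuts = [0]
    while cuts[-1] < length_bp:
        cuts.append(cuts[-1] + max(1, int(rng.exponential(mean_block))))
    cuts[-1] = length_bp
    return np.asarray(cuts, dtype=np.int64)


def _stochastic_round(rng, x: np.ndarray) -> np.ndarray:
    f = np.floor(x)
    return (f + (rng.random(x.shape) < (x - f))).astype(int)


def simulate_panel(config: SimConfig) -> SimulatedPanel:
    """Draw a panel under the configured model (deterministic given seed)."""
    rng = np.random.default_rng(config.seed)
    chrom_labels = config.chromosome_labels()
    mpc = config.markers_per_chromosome
    L = config.chromosome_length_bp
    K = config.founder_pool

    marker_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    for c in chrom_labels:
        # distinct positions without materialising the full coordinate range
        pos = np.unique(rng.integers(1, L + 1, size=2 * mpc))
        while pos.size < mpc:
            pos = np.unique(np.concatenate([pos, rng.integers(1, L + 1, size=2 * mpc)]))
        pos = np.sort(rng.choice(pos, size=mpc, replace=False))
        positions.extend(int(x) for x in pos)
        chroms.extend([c] * mpc)
        marker_ids.extend(f"snp_{c}_{i:05d}" for i in range(mpc))
    n_markers = len(marker_ids)
    pos_arr = np.asarray(positions, dtype=np.int64)
    chrom_arr = np.asarray(chroms, dtype=object)

    p_anc = rng.uniform(0.05, 0.95, size=n_markers)

    acc_ids: list[str] = []
    metadata: dict[str, AccessionMetadata] = {}
    call_rows: list[np.ndarray] = []
    for pop in config.populations:
        if pop.fst > 0:
            a = p_anc * (1 - pop.fst) / pop.fst
            b = (1 - p_anc) * (1 - pop.fst) / pop.fst
            p_pop = rng.beta(a, b)
        else:
            p_pop = p_anc.copy()
        hap = np.empty((pop.size, n_markers), dtype=np.int8)
        for c in chrom_labels:
            midx = np.flatnonzero(chrom_arr == c)
            cuts = _block_bounds(rng, L, pop.block_length_bp)
            block_of = np.searchsorted(cuts, pos_arr[midx] - 1, side="right") - 1
            n_blocks = len(cuts) - 1
            # one founder rank per (line, block); nested prefix coding per site
            ranks = rng.integers(0, K, size=(pop.size, n_blocks))
            m_site = _stochastic_round(rng, K * p_pop[midx])
            hap[:, midx] = (ranks[:, block_of] < m_site[None, :]).astype(np.int8)
        calls = (2 * hap).astype(np.int8)
        het = rng.random(calls.shape) < (1.0 - config.homozygosity)
        calls[het] = 1
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = MISSING
        ids = [f"{pop.label}_{i:04d}" for i in range(pop.size)]
        acc_ids.extend(ids)
        call_rows.append(calls)
        for a_id in ids:
            metadata[a_id] = AccessionMetadata(
                accession_id=a_id,
                germplasm_class=pop.germplasm_class,
                breeding_program=pop.label,
                country="SYN",
            )

    G = GenotypeMatrix(acc_ids, marker_ids, np.vstack(call_rows))
    M = MarkerMap(marker_ids, chrom_arr, pos_arr)
    truth = {
        "seed": config.seed,
        "populations": [
            {"label": p.label, "size": p.size, "fst": p.fst,
             "block_length_bp": p.block_length_bp}
            for p in config.populations
        ],
        "sweeps": [],
    }
    panel = SimulatedPanel(G, M, metadata, truth)
    for sw in config.sweeps:
        panel = inject_sweep(panel, sw, config, rng)
    return panel


def inject_sweep(
    panel: SimulatedPanel,
    spec: SweepSpec,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedPanel:
    """Push the target population's major allele to ``final_freq`` in place.

    Genotypes inside the interval are re-drawn i.i.d. for the target
    population only (local haplotype structure inside a swept interval is
    not emulated); the rest of the panel is untouched.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    G, M = panel.genotypes, panel.marker_map
    in_iv = (
        (np.asarray(M.chromosomes) == spec.chromosome)
        & (M.positions - 1 >= spec.start)
        & (M.positions - 1 < spec.end)
    )
    midx = np.flatnonzero(in_iv)
    if midx.size == 0:
        raise ValueError(f"sweep interval {spec.chromosome}:[{spec.start},{spec.end}) "
                         "contains no markers")
    rows = [i for i, a in enumerate(G.accession_ids)
            if panel.metadata[a].breeding_program == spec.population]
    if not rows:
        raise ValueError(f"no accessions in population {spec.population!r}")
    rows = np.asarray(rows)
    sub = G.calls[np.ix_(rows, midx)].astype(float)
    sub[sub == MISSING] = np.nan
    sub[sub == 1] = np.nan
    with np.errstate(invalid="ignore"):
        freq_alt = np.nanmean(sub / 2.0, axis=0)
    major_is_alt = np.nan_to_num(freq_alt, nan=0.5) >= 0.5
    carry_major = rng.random((rows.size, midx.size)) < spec.final_freq
    hap_alt = np.where(major_is_alt[None, :], carry_major, ~carry_major)
    calls = (2 * hap_alt.astype(np.int8)).astype(np.int8)
    het = rng.random(calls.shape) < (1.0 - config.homozygosity)
    calls[het] = 1
    miss = rng.random(calls.shape) < config.missing_rate
    calls[miss] = MISSING
    G.calls[np.ix_(rows, midx)] = calls
    panel.truth["sweeps"].append({
        "population": spec.population,
        "chromosome": spec.chromosome,
        "start": int(spec.start),
        "end": int(spec.end),
        "final_freq": spec.final_freq,
        "n_markers": int(midx.size),
    })
    if midx.size < 15:
        logger.warning("sweep interval spans only %d markers (< smoothing window)",
                       midx.size)
    return panel


# ---------------------------------------------------------------------------
# canned profiles and fixture writing
# ---------------------------------------------------------------------------


def default_config(profile: str = "default", seed: int = 0) -> SimConfig:
    """Canned study conditions: two-population inbred panels.

    * ``tiny`` — 2 x 12 lines, 2 chromosomes x 80 markers, for hand checks;
    * ``default`` — landrace-like (short LD) and modern-like (long LD)
      populations, 2 x 150 lines, 14 chromosomes x 360 markers, divergence
      F = 0.13, one injected sweep in the modern-like group;
    * ``ldcontrast`` — as default but without sweeps, for LD-decay work.
    """
    if profile == "tiny":
        return SimConfig(
            populations=[
                PopulationSpec("landrace", 12, fst=0.15, block_length_bp=5e6,
                               germplasm_class="landrace"),
                PopulationSpec("modern", 12, fst=0.15, block_length_bp=10e6),
            ],
            n_chromosomes=2, markers_per_chromosome=80,
            chromosome_length_bp=50_000_000, seed=seed,
        )
    pops = [
        PopulationSpec("landrace", 150, fst=0.13, block_length_bp=4e6,
                       germplasm_class="landrace"),
        PopulationSpec("modern", 150, fst=0.13, block_length_bp=18e6),
    ]
    if profile == "default":
        return SimConfig(
            populations=pops,
            sweeps=[SweepSpec("modern", "3B", 200_000_000, 260_000_000)],
            seed=seed,
        )
    if profile == "ldcontrast":
        # Small groups: the decay expectation at zero distance is
        # (10/22)(1 + 36/(22 n)), which exceeds 0.5 only for n <~ 14 gene
        # copies, so a critical distance at r2 = 0.5 is only defined for
        # small samples. 12 lines per group keeps both 0.3 and 0.5 readable.
        small = [
            PopulationSpec("landrace", 12, fst=0.13, block_length_bp=4e6,
                           germplasm_class="landrace"),
            PopulationSpec("modern", 12, fst=0.13, block_length_bp=18e6),
        ]
        return SimConfig(populations=small, seed=seed)
    raise ValueError(f"unknown profile {profile!r}")


def make_fixtures(out_dir, profile: str = "tiny", seed: int = 0, force: bool = False):
    """Write a panel (HapMap + metadata CSV + groups CSV + truth JSON).

    Refuses to write into an existing non-empty directory unless ``force``.
    Byte-identical on re-runs with the same seed.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    config = default_config(profile, seed=seed)
    panel = simulate_panel(config)
    write_hapmap(out / "genotypes.hmp.txt", panel.genotypes, panel.marker_map)
    write_metadata(out / "metadata.csv", panel.metadata)
    with open(out / "groups.csv", "w") as fh:
        fh.write("accession_id,scheme,label\n")
        for a, m in panel.metadata.items():
            fh.write(f"{a},population,{m.breeding_program}\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(panel.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return panel
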