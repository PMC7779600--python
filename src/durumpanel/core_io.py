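"""Data model and I/O for inbred SNP genotype panels.

The central container is :class:`GenotypeMatrix` — accessions x biallelic
markers, dosage-coded as the count of the alternate allele (0, 1, 2) with
``MISSING = -1`` as the sentinel. A companion :class:`MarkerMap` carries
physical coordinates (1-based bp on input; every internal interval is
half-open ``[start, end)`` after conversion, the single place where the
convention is fixed). Accession passport data lives in
:class:`AccessionMetadata`; grouping of accessions for population-level
statistics is a :class:`GroupScheme`.

Durum wheat and other selfing crops yield panels of near-fully homozygous
lines; the matrix keeps heterozygous calls as dosage 1 and each statistics
module decides their treatment (the diversity module recodes to one haploid
gene copy per accession).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call
MISSING = -1

#: missing-call tokens accepted in HapMap-style text
_MISSING_TOKENS = {"NN", "N", "--", "-", "NA", "..", "."}

#: decade bins used to classify modern germplasm by year of release
DECADE_LABELS = ("70-80", "81-90", "91-00", "01-10", "11-18")
NOT_MODERN = "not-modern"

GERMPLASM_CLASSES = ("modern", "landrace", "emmer", "wild", "primitive", "EPO")


class FormatError(ValueError):
    """Malformed input file."""


class ClassificationError(ValueError):
    """Passport data insufficient or inconsistent for classification."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Accessions x markers alternate-allele dosage matrix.

    Parameters
    ----------
    accession_ids : ordered unique accession names (rows).
    marker_ids : ordered unique marker names (columns).
    calls : int array, shape (n_accessions, n_markers), values in
        {0, 1, 2, MISSING}.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        if self.calls.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("duplicate accession ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{bad.sum()} calls outside {{0,1,2,{MISSING}}}")

    # -- basic properties ----------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def haploid(self) -> np.ndarray:
        """Haploid recoding for inbred-line statistics.

        Homozygotes map to one gene copy (0 or 1); heterozygous and missing
        calls become NaN. Returns a float array of the same shape.
        """
        h = self.calls.astype(float)
        h[(self.calls == MISSING) | (self.calls == 1)] = np.nan
        h[self.calls == 2] = 1.0
        return h

    # -- subsetting ----------------------------------------------------------
    def accession_indices(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"unknown accession id {e.args[0]!r}") from None

    def subset_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.accession_indices(ids)
        return GenotypeMatrix(list(ids), list(self.marker_ids), self.calls[idx])

    def subset_markers(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            lookup = {m: j for j, m in enumerate(self.marker_ids)}
            idx = np.array([lookup[m] for m in mask_or_ids], dtype=int)
        ids = [self.marker_ids[j] for j in idx]
        return GenotypeMatrix(list(self.accession_ids), ids, self.calls[:, idx])


@dataclass
class MarkerMap:
    """Per-marker genomic coordinates.

    Positions are stored 1-based (bp) as read from HapMap/VCF; interval
    arithmetic elsewhere converts to half-open ``[start, end)``.
    """

    marker_ids: list[str]
    chromosomes: np.ndarray  # array of str labels, e.g. 1A..7B
    positions: np.ndarray  # int64 bp, 1-based
    genetic_positions: np.ndarray | None = None  # optional cM

    def __post_init__(self) -> None:
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n = len(self.marker_ids)
        if len(set(self.marker_ids)) != n:
            raise ValueError("duplicate marker ids in map")
        if len(self.chromosomes) != n or len(self.positions) != n:
            raise ValueError("map column lengths disagree")
        if self.genetic_positions is not None:
            self.genetic_positions = np.asarray(self.genetic_positions, dtype=float)
            if len(self.genetic_positions) != n:
                raise ValueError("map column lengths disagree")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def chromosome_labels(self) -> list[str]:
        """Distinct chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chromosomes:
            seen.setdefault(c, None)
        return list(seen)

    def sorted_order(self) -> np.ndarray:
        """Index array sorting by (chromosome first-appearance, position)."""
        chrom_rank = {c: i for i, c in enumerate(self.chromosome_labels())}
        keys = np.array([chrom_rank[c] for c in self.chromosomes])
        return np.lexsort((self.positions, keys))

    def is_sorted(self) -> bool:
        order = self.sorted_order()
        return bool(np.all(order == np.arange(self.n_markers)))

    def subset(self, keep) -> "MarkerMap":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            lookup = {m: j for j, m in enumerate(self.marker_ids)}
            idx = np.array([lookup[m] for m in keep], dtype=int)
        return MarkerMap(
            [self.marker_ids[j] for j in idx],
            self.chromosomes[idx],
            self.positions[idx],
            None if self.genetic_positions is None else self.genetic_positions[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        d = {
            "marker_id": self.marker_ids,
            "chromosome": self.chromosomes,
            "position": self.positions,
        }
        if self.genetic_positions is not None:
            d["cM"] = self.genetic_positions
        return pd.DataFrame(d)


@dataclass
class AccessionMetadata:
    """Passport record for one accession."""

    accession_id: str
    subspecies: str = "durum"
    germplasm_class: str = "modern"
    country: str = ""
    breeding_program: str = ""
    year_of_release: int | None = None
    cross_year: int | None = None

    def __post_init__(self) -> None:
        if self.germplasm_class not in GERMPLASM_CLASSES:
            raise ClassificationError(
                f"unknown germplasm class {self.germplasm_class!r} "
                f"for {self.accession_id!r}"
            )


@dataclass
class GroupScheme:
    """Named accession -> group-label mapping used by population statistics."""

    name: str
    mapping: dict[str, str]
    min_group_size: int = 1

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty group scheme")

    def groups(self) -> dict[str, list[str]]:
        """Group label -> accession ids, dropping groups below the minimum size."""
        out: dict[str, list[str]] = {}
        for acc, lab in self.mapping.items():
            out.setdefault(str(lab), []).append(acc)
        small = [lab for lab, ids in out.items() if len(ids) < self.min_group_size]
        for lab in small:
            logger.warning("group %r below minimum size %d; dropped", lab, self.min_group_size)
            del out[lab]
        if not out:
            raise ValueError("no group meets the minimum size")
        return out

    def validate_against(self, G: GenotypeMatrix) -> None:
        unknown = set(self.mapping) - set(G.accession_ids)
        if unknown:
            raise ValueError(f"scheme labels {len(unknown)} accessions absent from panel, "
                             f"e.g. {sorted(unknown)[:3]}")

    def restrict(self, ids: Iterable[str]) -> "GroupScheme":
        keep = {a: g for a, g in self.mapping.items() if a in set(ids)}
        return GroupScheme(self.name, keep, self.min_group_size)


# ---------------------------------------------------------------------------
# decade derivation
# ---------------------------------------------------------------------------


def derive_decade(meta: AccessionMetadata) -> str:
    """Decade-of-release label for modern germplasm.

    Uses ``year_of_release`` when present, else ``cross_year + 10`` (elite
    lines without a registration year are dated from the cross). Years before
    1970 are pre-green-revolution material and return ``"not-modern"``.
    """
    if meta.year_of_release is not None:
        year = int(meta.year_of_release)
    elif meta.cross_year is not None:
        year = int(meta.cross_year) + 10
    else:
        raise ClassificationError(
            f"{meta.accession_id!r}: neither year_of_release nor cross_year present"
        )
    if year > 2018:
        raise ClassificationError(f"{meta.accession_id!r}: year {year} beyond panel horizon")
    if year < 1970:
        return NOT_MODERN
    edges = [(1970, 1980), (1981, 1990), (1991, 2000), (2001, 2010), (2011, 2018)]
    for (lo, hi), lab in zip(edges, DECADE_LABELS):
        if lo <= year <= hi:
            return lab
    raise ClassificationError(f"{meta.accession_id!r}: year {year} unclassifiable")


# ---------------------------------------------------------------------------
# HapMap-style text
# ---------------------------------------------------------------------------

_HAPMAP_FIXED = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def _parse_hapmap_token(token: str, alt: str, ref: str) -> int:
    t = token.strip()
    if t == "" or t.upper() in _MISSING_TOKENS:
        return MISSING
    if len(t) == 1:
        t = t + t
    if len(t) != 2:
        return MISSING
    a, b = t[0], t[1]
    if a not in (ref, alt) or b not in (ref, alt):
        return MISSING
    return (a == alt) + (b == alt)


def load_hapmap(path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a HapMap-style tab-separated genotype file.

    One row per marker: 11 fixed columns then one two-letter genotype column
    per accession. Dosage counts the alternate allele; when the ``alleles``
    column declares ``R/A`` the second letter is the alternate, otherwise the
    alphabetically later of the observed alleles is taken as alternate.
    Unknown tokens become missing; heterozygotes are dosage 1.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) <= len(_HAPMAP_FIXED):
            raise FormatError("HapMap header has no accession columns")
        accessions = header[len(_HAPMAP_FIXED):]
        n_acc = len(accessions)
        marker_ids: list[str] = []
        chroms: list[str] = []
        positions: list[int] = []
        rows: list[np.ndarray] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_HAPMAP_FIXED) + n_acc:
                raise FormatError(
                    f"line {lineno}: expected {len(_HAPMAP_FIXED) + n_acc} columns, "
                    f"found {len(parts)}"
                )
            mid = parts[0]
            if mid in seen:
                raise FormatError(f"line {lineno}: duplicated marker id {mid!r}")
            seen.add(mid)
            try:
                pos = int(parts[3])
            except ValueError:
                raise FormatError(f"line {lineno}: non-numeric position {parts[3]!r}") from None
            tokens = parts[len(_HAPMAP_FIXED):]
            allele_field = parts[1]
            letters: list[str] = []
            if "/" in allele_field:
                letters = [x for x in allele_field.split("/") if x and x.upper() != "N"]
            if len(letters) != 2:
                obs = sorted({c for t in tokens for c in t.strip() if c in "ACGT"})
                if len(obs) > 2:
                    raise FormatError(f"line {lineno}: more than two alleles observed {obs}")
                while len(obs) < 2:
                    obs.append("N")  # monomorphic/blank marker: lone allele is ref
                letters = obs
            ref, alt = sorted(letters)  # alphabetically later allele counted as alternate
            row = np.array([_parse_hapmap_token(t, alt, ref) for t in tokens], dtype=np.int8)
            marker_ids.append(mid)
            chroms.append(parts[2])
            positions.append(pos)
            rows.append(row)
    calls = (
        np.stack(rows, axis=1) if rows else np.empty((n_acc, 0), dtype=np.int8)
    )
    G = GenotypeMatrix(accessions, marker_ids, calls)
    M = MarkerMap(marker_ids, np.array(chroms, dtype=object), np.array(positions, dtype=np.int64))
    return G, M


_WRITE_LETTERS = ("A", "G")  # ref 'A' (earlier), alt 'G' (later) — round-trip stable


def write_hapmap(path, G: GenotypeMatrix, M: MarkerMap) -> None:
    """Write the matrix/map pair as HapMap-style text (lossless round trip)."""
    if G.marker_ids != M.marker_ids:
        raise ValueError("matrix and map marker ids disagree")
    ref, alt = _WRITE_LETTERS
    code = {0: ref + ref, 1: ref + alt, 2: alt + alt, MISSING: "NN"}
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_FIXED + G.accession_ids) + "\n")
        for j, mid in enumerate(G.marker_ids):
            fixed = [
                mid, f"{ref}/{alt}", str(M.chromosomes[j]), str(int(M.positions[j])),
                "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            geno = [code[int(x)] for x in G.calls[:, j]]
            fh.write("\t".join(fixed + geno) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def load_vcf(path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read biallelic GT records from a VCF (plain or bgzipped).

    Multiallelic records are skipped (the skip count is logged and stored on
    the returned matrix as ``n_multiallelic_skipped``). ``./.`` becomes
    missing. A record without a GT field raises :class:`FormatError`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    marker_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        if "GT" not in (var.FORMAT or []):
            raise FormatError(f"record {var.CHROM}:{var.POS} has no GT field")
        gts = var.genotypes  # [allele1, allele2, phased] per sample
        row = np.full(len(accessions), MISSING, dtype=np.int8)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                row[i] = a + b
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        rows.append(row)
    vcf.close()
    if skipped:
        logger.info("skipped %d multiallelic records", skipped)
    calls = (
        np.stack(rows, axis=1) if rows else np.empty((len(accessions), 0), dtype=np.int8)
    )
    G = GenotypeMatrix(accessions, marker_ids, calls)
    G.n_multiallelic_skipped = skipped  # type: ignore[attr-defined]
    M = MarkerMap(marker_ids, np.array(chroms, dtype=object), np.array(positions, dtype=np.int64))
    return G, M


# ---------------------------------------------------------------------------
# metadata / groups CSV
# ---------------------------------------------------------------------------


def load_metadata(path) -> dict[str, AccessionMetadata]:
    """Read an accession metadata CSV keyed by ``accession_id``.

    Recognised columns: accession_id, subspecies, germplasm_class, country,
    breeding_program, year_of_release, cross_year.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    if "accession_id" not in df.columns:
        raise FormatError("metadata CSV lacks an accession_id column")
    out: dict[str, AccessionMetadata] = {}
    for rec in df.to_dict("records"):
        def _year(key):
            v = rec.get(key, "")
            return int(float(v)) if v not in ("", None) else None
        acc = str(rec["accession_id"])
        out[acc] = AccessionMetadata(
            accession_id=acc,
            subspecies=rec.get("subspecies", "durum") or "durum",
            germplasm_class=rec.get("germplasm_class", "modern") or "modern",
            country=rec.get("country", ""),
            breeding_program=rec.get("breeding_program", ""),
            year_of_release=_year("year_of_release"),
            cross_year=_year("cross_year"),
        )
    return out


def write_metadata(path, meta: Mapping[str, AccessionMetadata]) -> None:
    cols = ["accession_id", "subspecies", "germplasm_class", "country",
            "breeding_program", "year_of_release", "cross_year"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for m in meta.values():
            w.writerow([
                m.accession_id, m.subspecies, m.germplasm_class, m.country,
                m.breeding_program,
                "" if m.year_of_release is None else m.year_of_release,
                "" if m.cross_year is None else m.cross_year,
            ])


def load_groups(path, scheme: str) -> GroupScheme:
    """Read a groups CSV (accession_id, scheme, label) and extract one scheme."""
    df = pd.read_csv(path, dtype=str)
    need = {"accession_id", "scheme", "label"}
    if not need.issubset(df.columns):
        raise FormatError(f"groups CSV must have columns {sorted(need)}")
    sub = df[df["scheme"] == scheme]
    if sub.empty:
        raise FormatError(f"scheme {scheme!r} absent from {path}")
    return GroupScheme(scheme, dict(zip(sub["accession_id"], sub["label"])))


def scheme_from_metadata(
    meta: Mapping[str, AccessionMetadata],
    by: str,
    restrict_class: str | None = None,
    min_group_size: int = 1,
) -> GroupScheme:
    """Build a GroupScheme from passport data.

    ``by`` is one of ``class``, ``decade``, ``program``, ``country``. With
    ``by='decade'`` only accessions resolving to a modern decade are kept.
    """
    mapping: dict[str, str] = {}
    for acc, m in meta.items():
        if restrict_class and m.germplasm_class != restrict_class:
            continue
        if by == "class":
            mapping[acc] = m.germplasm_class
        elif by == "program":
            if m.breeding_program:
                mapping[acc] = m.breeding_program
        elif by == "country":
            if m.country:
                mapping[acc] = m.country
        elif by == "decade":
            try:
                lab = derive_decade(m)
            except ClassificationError:
                continue
            if lab != NOT_MODERN:
                mapping[acc] = lab
        else:
            raise ValueError(f"unknown scheme key {by!r}")
    return GroupScheme(by, mapping, min_group_size)
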