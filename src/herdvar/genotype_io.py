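"""Genotype data model and PLINK text (PED/MAP) input/output.

The central object is :class:`GenotypeMatrix`: a samples x markers dosage
matrix (counts of ``allele_b``, values 0/1/2, ``MISSING`` sentinel) with
ordered marker and sample metadata.  Every downstream statistic consumes
this object, so validation lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "AUTOSOME_LABELS",
    "MarkerInfo",
    "GenotypeMatrix",
    "PopulationPartition",
    "read_plink_text",
    "write_plink_text",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "subset",
]

#: Sentinel dosage for a missing genotype.  Stored in an int8 matrix, so it
#: must never collide with a valid dosage {0, 1, 2}.
MISSING: int = -9

#: Chromosome labels treated as autosomal for cattle-style data (1..29 by
#: default; any purely numeric label >= 1 counts as an autosome).
AUTOSOME_LABELS = frozenset(str(i) for i in range(1, 100))

_SEX_LABELS = frozenset({"X", "Y", "XY", "MT", "M", "23", "24", "25", "26"})


@dataclass(frozen=True)
class MarkerInfo:
    """Metadata for one biallelic marker.

    ``chromosome`` is a free-form label: an autosome number, a sex label
    ("X", "Y", ...) or "0"/"unmapped" for unplaced markers.  ``quality`` is
    an optional per-marker score in [0, 1] (e.g. a median GC score).
    """

    id: str
    chromosome: str
    position: int
    allele_a: str = "A"
    allele_b: str = "B"
    quality: float | None = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"marker {self.id}: negative position {self.position}")
        if self.quality is not None and not (0.0 <= self.quality <= 1.0):
            raise ValueError(f"marker {self.id}: quality {self.quality} outside [0, 1]")

    @property
    def is_autosomal(self) -> bool:
        c = self.chromosome
        return c not in _SEX_LABELS and c != "0" and c.lower() != "unmapped" and c.isdigit() and int(c) >= 1


class GenotypeMatrix:
    """Samples x markers dosage matrix with aligned metadata.

    Dosages count copies of each marker's ``allele_b``; missing genotypes
    hold :data:`MISSING`.  The matrix is stored as ``int8``.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        markers: Sequence[MarkerInfo],
        sample_ids: Sequence[str],
    ) -> None:
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x markers array")
        n_samples, n_markers = dosages.shape
        if len(sample_ids) != n_samples:
            raise ValueError(
                f"{len(sample_ids)} sample ids for {n_samples} dosage rows"
            )
        if len(markers) != n_markers:
            raise ValueError(f"{len(markers)} markers for {n_markers} dosage columns")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        ids = [m.id for m in markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids")
        valid = (dosages == MISSING) | ((dosages >= 0) & (dosages <= 2))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid dosage {dosages[bad[0], bad[1]]} at sample "
                f"{sample_ids[bad[0]]!r}, marker {ids[bad[1]]!r}"
            )
        qual = [m.quality is not None for m in markers]
        if any(qual) and not all(qual):
            raise ValueError("quality must be present for all markers or none")
        self.dosages = dosages
        self.markers: list[MarkerInfo] = list(markers)
        self.sample_ids: list[str] = list(sample_ids)

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    @property
    def has_quality(self) -> bool:
        return bool(self.markers) and self.markers[0].quality is not None

    def missing_mask(self) -> np.ndarray:
        """Boolean samples x markers mask, True where the genotype is missing."""
        return self.dosages == MISSING

    def canonicalized(self) -> "GenotypeMatrix":
        """Return the matrix in canonical allele orientation.

        Canonical form is what :func:`read_plink_text` produces: dosage
        counts the minor allele, tie-broken to the lexicographically larger
        label.  PED files carry no reference allele, so only canonical
        matrices round-trip bit-identically through write -> read; all
        downstream statistics are invariant to the flip.
        """
        d = self.dosages.copy()
        markers = list(self.markers)
        for j, m in enumerate(markers):
            col = d[:, j]
            called = col != MISSING
            n_b = int(col[called].sum())
            n_a = 2 * int(called.sum()) - n_b
            flip = n_b > n_a or (n_b == n_a and m.allele_b < m.allele_a)
            if flip:
                d[called, j] = 2 - col[called]
                markers[j] = replace(m, allele_a=m.allele_b, allele_b=m.allele_a)
        return GenotypeMatrix(d, markers, self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.markers == other.markers
            and np.array_equal(self.dosages, other.dosages)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_markers} markers)"


class PopulationPartition:
    """Assignment of sample ids to named populations."""

    def __init__(self, mapping: Mapping[str, str]) -> None:
        if not mapping:
            raise ValueError("empty population mapping")
        self.mapping: dict[str, str] = dict(mapping)

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for pop in self.mapping.values():
            seen.setdefault(pop, None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.mapping.items() if p == population]

    def validate_against(self, gm: GenotypeMatrix) -> None:
        unknown = [s for s in self.mapping if s not in set(gm.sample_ids)]
        if unknown:
            raise ValueError(f"samples not in genotype matrix: {unknown[:5]}")

    def indices_by_population(self, gm: GenotypeMatrix) -> dict[str, np.ndarray]:
        """Row indices into ``gm`` per population, in matrix order."""
        pos = {s: i for i, s in enumerate(gm.sample_ids)}
        out: dict[str, list[int]] = {p: [] for p in self.populations}
        for s in gm.sample_ids:
            if s in self.mapping:
                out[self.mapping[s]].append(pos[s])
        return {p: np.asarray(ix, dtype=np.intp) for p, ix in out.items() if ix}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationPartition":
        """Read a two-column (sample, population) TSV, header optional."""
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for i, line in enumerate(fh):
                parts = line.split()
                if not parts:
                    continue
                if i == 0 and parts[0].lower() in {"sample", "sample_id", "id"}:
                    continue
                if len(parts) < 2:
                    raise ValueError(f"{path}: line {i + 1}: need sample and population")
                mapping[parts[0]] = parts[1]
        return cls(mapping)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tpopulation\n")
            for s, p in self.mapping.items():
                fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# PLINK text I/O


def _read_map(map_path: str | Path) -> list[MarkerInfo]:
    markers: list[MarkerInfo] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise ValueError(f"{map_path}: line {lineno}: expected 3 or 4 columns")
            chrom, mid = parts[0], parts[1]
            pos = int(parts[-1])
            markers.append(MarkerInfo(id=mid, chromosome=chrom, position=max(pos, 0)))
    return markers


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read whitespace-delimited PED/MAP into a :class:`GenotypeMatrix`.

    Dosages count copies of ``allele_b``, chosen per marker as the minor
    allele at first read, tie-broken to the lexicographically larger allele
    when counts are equal.  "0 0" genotypes become :data:`MISSING`.
    """
    markers = _read_map(map_path)
    n_markers = len(markers)
    sample_ids: list[str] = []
    rows: list[list[str]] = []  # per sample: 2*n_markers allele codes
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_markers} "
                    f"fields, got {len(parts)}"
                )
            sid = parts[1]
            if sid in sample_ids:
                raise ValueError(f"{ped_path}: line {lineno}: duplicate sample id {sid!r}")
            sample_ids.append(sid)
            rows.append(parts[6:])

    n_samples = len(sample_ids)
    dosages = np.full((n_samples, n_markers), MISSING, dtype=np.int8)
    out_markers: list[MarkerInfo] = []
    for j, m in enumerate(markers):
        counts: dict[str, int] = {}
        for row in rows:
            for a in (row[2 * j], row[2 * j + 1]):
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise ValueError(
                f"{ped_path}: marker {m.id!r} has >2 alleles: {sorted(counts)}"
            )
        if not counts:
            allele_a, allele_b = "0", "0"
        elif len(counts) == 1:
            # monomorphic: the counted (minor) allele is the unobserved one
            (allele_a,) = counts
            allele_b = "0"
        else:
            (a1, c1), (a2, c2) = sorted(counts.items())
            if c1 == c2:
                allele_a, allele_b = a1, a2  # tie: count lexicographically larger
            elif c1 < c2:
                allele_a, allele_b = a2, a1  # a1 is minor
            else:
                allele_a, allele_b = a1, a2
        out_markers.append(replace(m, allele_a=allele_a, allele_b=allele_b))
        for i, row in enumerate(rows):
            a, b = row[2 * j], row[2 * j + 1]
            if a == "0" or b == "0":
                continue
            dosages[i, j] = (a == allele_b) + (b == allele_b)
    return GenotypeMatrix(dosages, out_markers, sample_ids)


def write_plink_text(gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    """Write PED/MAP text re-readable by :func:`read_plink_text`."""
    with open(map_path, "w") as fh:
        for m in gm.markers:
            fh.write(f"{m.chromosome}\t{m.id}\t0\t{m.position}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            fields = ["FAM", sid, "0", "0", "0", "-9"]
            for j, m in enumerate(gm.markers):
                d = gm.dosages[i, j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [m.allele_a, m.allele_a]
                elif d == 1:
                    fields += [m.allele_a, m.allele_b]
                else:
                    fields += [m.allele_b, m.allele_b]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Internal dosage-matrix TSV (fixtures, stage outputs)


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage matrix as TSV: marker-id header row, one row per sample.

    A companion header block of ``#marker`` lines carries chromosome,
    position, alleles and quality so the file round-trips.
    """
    with open(path, "w") as fh:
        for m in gm.markers:
            q = "" if m.quality is None else f"\t{m.quality!r}"
            fh.write(f"#marker\t{m.id}\t{m.chromosome}\t{m.position}\t{m.allele_a}\t{m.allele_b}{q}\n")
        fh.write("sample_id\t" + "\t".join(gm.marker_ids) + "\n")
        for i, sid in enumerate(gm.sample_ids):
            row = "\t".join("NA" if d == MISSING else str(int(d)) for d in gm.dosages[i])
            fh.write(f"{sid}\t{row}\n")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    markers: list[MarkerInfo] = []
    sample_ids: list[str] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#marker":
                quality = float(parts[6]) if len(parts) > 6 else None
                markers.append(
                    MarkerInfo(parts[1], parts[2], int(parts[3]), parts[4], parts[5], quality)
                )
            elif parts[0] == "sample_id":
                continue
            elif parts[0]:
                sample_ids.append(parts[0])
                rows.append([MISSING if v == "NA" else int(v) for v in parts[1:]])
    dosages = np.asarray(rows, dtype=np.int8) if rows else np.empty((0, len(markers)), np.int8)
    return GenotypeMatrix(dosages, markers, sample_ids)


# ---------------------------------------------------------------------------


def subset(
    gm: GenotypeMatrix,
    sample_ids: Iterable[str] | None = None,
    marker_ids: Iterable[str] | None = None,
) -> GenotypeMatrix:
    """Subset to the requested samples and/or markers, preserving matrix order.

    Raises ``KeyError`` listing any unknown id.
    """
    if sample_ids is None:
        row_ix = np.arange(gm.n_samples)
    else:
        wanted = set(sample_ids)
        unknown = wanted - set(gm.sample_ids)
        if unknown:
            raise KeyError(f"unknown sample ids: {sorted(unknown)}")
        row_ix = np.asarray([i for i, s in enumerate(gm.sample_ids) if s in wanted])
    if marker_ids is None:
        col_ix = np.arange(gm.n_markers)
    else:
        wanted_m = set(marker_ids)
        unknown = wanted_m - set(gm.marker_ids)
        if unknown:
            raise KeyError(f"unknown marker ids: {sorted(unknown)}")
        col_ix = np.asarray([j for j, m in enumerate(gm.markers) if m.id in wanted_m])
    dosages = gm.dosages[np.ix_(row_ix, col_ix)] if len(row_ix) and len(col_ix) else np.empty((len(row_ix), len(col_ix)), np.int8)
    return GenotypeMatrix(
        dosages,
        [gm.markers[j] for j in col_ix],
        [gm.sample_ids[i] for i in row_ix],
    )
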