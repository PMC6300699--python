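"""Fragment library I/O: reading, validating, filtering and normalizing.

The atomic unit of an ATAC-STARR-seq experiment is a *fragment*: a genomic
interval (BED convention, 0-based half-open) plus a short random barcode that
disambiguates fragments whose endpoints coincide, together with one
non-negative integer count per sequencing sample (plasmid-DNA input replicates
and RNA output replicates).

Fragment BED dialect
--------------------
Tab-separated, no header by default::

    chrom  start  end  barcode  count_1 ... count_N

with counts ordered as in the sample manifest TSV
(``sample<TAB>condition<TAB>replicate``, condition in {DNA, RNA}).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Fragment",
    "SampleManifest",
    "FragmentParseError",
    "SchemaError",
    "read_fragments",
    "write_fragments",
    "read_bed_intervals",
    "write_bed_intervals",
    "filter_fragments",
    "fragments_to_matrix",
    "rpm_normalize",
]


class FragmentParseError(ValueError):
    """A malformed line in a fragment or interval file."""


class SchemaError(ValueError):
    """Input columns do not match the sample manifest."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(slots=True)
class Fragment:
    """A tested reporter fragment with per-sample counts.

    Identity is the (chrom, start, end, barcode) quadruple: the random 4-nt
    barcode makes fragments with identical alignment positions distinguishable.
    """

    interval: GenomicInterval
    barcode: str
    counts: np.ndarray
    strand: str = "."  # carried through unmodified, never interpreted

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.interval.chrom, self.interval.start, self.interval.end, self.barcode)

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class SampleManifest:
    """Ordered sample sheet: label, condition (DNA or RNA), replicate index."""

    labels: tuple[str, ...]
    conditions: tuple[str, ...]
    replicates: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.conditions):
            raise ValueError("labels and conditions must have equal length")
        if not self.replicates:
            object.__setattr__(self, "replicates", tuple(range(1, len(self.labels) + 1)))
        if len(self.replicates) != len(self.labels):
            raise ValueError("replicates and labels must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("sample labels must be unique")
        bad = set(self.conditions) - {"DNA", "RNA"}
        if bad:
            raise ValueError(f"conditions must be DNA or RNA, got {sorted(bad)}")
        if "DNA" not in self.conditions or "RNA" not in self.conditions:
            raise ValueError("manifest requires at least one DNA and one RNA sample")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def dna_labels(self) -> list[str]:
        return [l for l, c in zip(self.labels, self.conditions) if c == "DNA"]

    @property
    def rna_labels(self) -> list[str]:
        return [l for l, c in zip(self.labels, self.conditions) if c == "RNA"]

    @property
    def is_dna(self) -> np.ndarray:
        return np.array([c == "DNA" for c in self.conditions])

    @classmethod
    def default(cls, n_dna: int = 5, n_rna: int = 5) -> "SampleManifest":
        """Standard five-plasmid / five-RNA replicate design."""
        labels = [f"DNA_{i}" for i in range(1, n_dna + 1)] + [
            f"RNA_{i}" for i in range(1, n_rna + 1)
        ]
        conds = ["DNA"] * n_dna + ["RNA"] * n_rna
        reps = list(range(1, n_dna + 1)) + list(range(1, n_rna + 1))
        return cls(tuple(labels), tuple(conds), tuple(reps))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleManifest":
        labels, conds, reps = [], [], []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FragmentParseError(f"{path}:{i}: expected sample<TAB>condition[<TAB>replicate]")
                labels.append(parts[0])
                conds.append(parts[1])
                reps.append(int(parts[2]) if len(parts) > 2 else len(labels))
        return cls(tuple(labels), tuple(conds), tuple(reps))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for l, c, r in zip(self.labels, self.conditions, self.replicates):
                fh.write(f"{l}\t{c}\t{r}\n")


def read_fragments(path: str | Path, manifest: SampleManifest) -> list[Fragment]:
    """Read a fragment BED file; strict parse, duplicates summed.

    Fragments are returned in file order (first occurrence for duplicated
    identity keys); counts of duplicate (chrom, start, end, barcode) records
    are summed elementwise.
    """
    n = len(manifest)
    frags: list[Fragment] = []
    by_key: dict[tuple, Fragment] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4 + n:
                raise SchemaError(
                    f"{path}:{i}: expected {4 + n} columns "
                    f"(chrom, start, end, barcode, {n} counts), got {len(parts)}"
                )
            chrom, s, e, barcode = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise FragmentParseError(f"{path}:{i}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise FragmentParseError(
                    f"{path}:{i}: invalid interval {chrom}:{start}-{end}"
                )
            try:
                counts = np.array([int(c) for c in parts[4:]], dtype=np.int64)
            except ValueError as exc:
                raise FragmentParseError(f"{path}:{i}: non-integer count") from exc
            if (counts < 0).any():
                raise FragmentParseError(f"{path}:{i}: negative count")
            key = (chrom, start, end, barcode)
            if key in by_key:
                by_key[key].counts = by_key[key].counts + counts
            else:
                frag = Fragment(GenomicInterval(chrom, start, end), barcode, counts)
                by_key[key] = frag
                frags.append(frag)
    return frags


def write_fragments(
    frags: Iterable[Fragment],
    path: str | Path,
    manifest: SampleManifest | None = None,
    header: bool = False,
) -> None:
    """Write fragments in the canonical BED dialect (LF endings, no header)."""
    with open(path, "w", newline="\n") as fh:
        if header and manifest is not None:
            fh.write("#chrom\tstart\tend\tbarcode\t" + "\t".join(manifest.labels) + "\n")
        for f in frags:
            counts = "\t".join(str(int(c)) for c in f.counts)
            fh.write(
                f"{f.interval.chrom}\t{f.interval.start}\t{f.interval.end}\t{f.barcode}\t{counts}\n"
            )


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read plain BED3+ intervals (extra columns ignored)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FragmentParseError(f"{path}:{i}: expected at least 3 BED columns")
            try:
                out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise FragmentParseError(f"{path}:{i}: {exc}") from exc
    return out


def write_bed_intervals(
    intervals: Iterable[GenomicInterval], path: str | Path, names: Sequence[str] | None = None
) -> None:
    with open(path, "w", newline="\n") as fh:
        for i, iv in enumerate(intervals):
            if names is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def filter_fragments(
    frags: Sequence[Fragment],
    min_len: int = 100,
    max_len: int = 600,
    blacklist: Sequence[GenomicInterval] = (),
    drop_chroms: frozenset[str] | set[str] = frozenset({"chrM"}),
    blacklist_mode: str = "any",
) -> list[Fragment]:
    """Apply the standard fragment QC filters.

    Retains fragments with ``min_len <= length <= max_len`` (bounds inclusive),
    not on a dropped chromosome (mitochondrial by default), and with no overlap
    with any blacklist interval. ``blacklist_mode='any'`` removes on >=1 bp of
    overlap (mirroring read-blacklisting practice); ``'full'`` removes only
    fragments fully contained in a blacklist interval. Order is preserved;
    the operation is idempotent.
    """
    if blacklist_mode not in ("any", "full"):
        raise ValueError("blacklist_mode must be 'any' or 'full'")
    # sorted per-chrom arrays for fast blacklist lookup
    bl_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if blacklist:
        tmp: dict[str, list[tuple[int, int]]] = {}
        for iv in blacklist:
            tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, ivs in tmp.items():
            ivs.sort()
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            bl_by_chrom[chrom] = (starts, np.maximum.accumulate(ends))

    def hits_blacklist(f: Fragment) -> bool:
        entry = bl_by_chrom.get(f.interval.chrom)
        if entry is None:
            return False
        starts, cummax_ends = entry
        if blacklist_mode == "any":
            # any interval with start < f.end and end > f.start
            j = np.searchsorted(starts, f.interval.end, side="left")
            return j > 0 and cummax_ends[j - 1] > f.interval.start
        j = np.searchsorted(starts, f.interval.start, side="right")
        # full containment: some interval with start <= f.start and end >= f.end
        return j > 0 and cummax_ends[j - 1] >= f.interval.end

    out = []
    for f in frags:
        if f.interval.chrom in drop_chroms:
            continue
        if not (min_len <= f.length <= max_len):
            continue
        if hits_blacklist(f):
            continue
        out.append(f)
    return out


def fragments_to_matrix(frags: Sequence[Fragment], manifest: SampleManifest) -> pd.DataFrame:
    """Assemble the fragment x sample count matrix (row ids chrom:start-end:barcode)."""
    ids = [f"{f.interval.chrom}:{f.interval.start}-{f.interval.end}:{f.barcode}" for f in frags]
    data = np.vstack([f.counts for f in frags]) if frags else np.empty((0, len(manifest)), int)
    return pd.DataFrame(data, index=ids, columns=list(manifest.labels))


def rpm_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million normalization; each column then sums to 10^6."""
    totals = matrix.sum(axis=0).astype(float)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {', '.join(map(str, zero.index))}")
    return matrix.astype(float).div(totals, axis=1) * 1e6
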