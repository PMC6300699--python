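"""Fragment grouping and tiled-region detection.

Individually tested fragments are often sequenced shallowly; near-identical
fragments (75% reciprocal overlap by default) are clustered into *fragment
groups* whose counts are summed, boosting read coverage for activity testing.
Independently, loci densely covered by partially-overlapping fragments
(*tiled regions*, >=10 unique fragments) are the substrate for per-nucleotide
score inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fragio import Fragment, GenomicInterval, SampleManifest

__all__ = [
    "FragmentGroup",
    "TiledRegion",
    "reciprocal_overlap",
    "group_fragments",
    "tiled_regions",
]


@dataclass(slots=True)
class FragmentGroup:
    """Cluster of near-identical fragments with summed counts.

    ``representative`` is the seed fragment's interval; every member has
    reciprocal overlap >= threshold with it.
    """

    representative: GenomicInterval
    member_keys: list[tuple]
    counts: np.ndarray
    group_id: str = ""

    @property
    def length(self) -> int:
        return self.representative.length

    @property
    def length_bin(self) -> int:
        """100-nt length bin index: floor(length/100), so [100,200) -> bin 1."""
        return self.representative.length // 100


@dataclass(slots=True)
class TiledRegion:
    """Connected component of overlapping fragments with >= min unique members."""

    interval: GenomicInterval
    fragments: list[Fragment] = field(default_factory=list)

    @property
    def fragment_count(self) -> int:
        """Number of distinct (start, end) endpoint patterns (barcode ignored)."""
        return len({(f.interval.start, f.interval.end) for f in self.fragments})


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(ov/len(a), ov/len(b)); 0 for different chromosomes. Symmetric."""
    ov = a.overlap(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def group_fragments(
    frags: Sequence[Fragment],
    threshold: float = 0.75,
    manifest: SampleManifest | None = None,
) -> list[FragmentGroup]:
    """Greedy seeded clustering at a reciprocal-overlap threshold.

    Fragments are ranked by total DNA count descending (total count if no
    manifest is given), ties broken by leftmost start then shortest length.
    The top unassigned fragment seeds a group and absorbs every unassigned
    fragment with reciprocal overlap >= ``threshold`` to the *seed*; the
    procedure repeats until all fragments are assigned. The result is a
    partition: member sets are disjoint, so no two groups can share an
    identical member set (redundant-group removal is implied). Group counts
    are elementwise sums of member counts, conserving totals per sample.
    """
    n = len(frags)
    if n == 0:
        return []
    if manifest is not None:
        dna_mask = manifest.is_dna
        priority = np.array([int(f.counts[dna_mask].sum()) for f in frags])
    else:
        priority = np.array([int(f.counts.sum()) for f in frags])

    order = sorted(
        range(n),
        key=lambda i: (-priority[i], frags[i].interval.chrom, frags[i].interval.start, frags[i].length),
    )

    # per-chromosome sorted coordinate arrays for windowed candidate lookup
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in {f.interval.chrom for f in frags}:
        idx = np.array([i for i in range(n) if frags[i].interval.chrom == chrom])
        starts = np.array([frags[i].interval.start for i in idx])
        o = np.argsort(starts, kind="stable")
        by_chrom[chrom] = idx[o]

    coords = {
        chrom: (
            np.array([frags[i].interval.start for i in idx]),
            np.array([frags[i].interval.end for i in idx]),
        )
        for chrom, idx in by_chrom.items()
    }
    max_len = {chrom: int((e - s).max()) for chrom, (s, e) in coords.items()}

    assigned = np.zeros(n, dtype=bool)
    groups: list[FragmentGroup] = []
    for seed_i in order:
        if assigned[seed_i]:
            continue
        seed = frags[seed_i]
        chrom = seed.interval.chrom
        idx = by_chrom[chrom]
        starts, ends = coords[chrom]
        # overlapping candidates must start before seed.end and within max_len of seed.start
        lo = np.searchsorted(starts, seed.interval.start - max_len[chrom], side="left")
        hi = np.searchsorted(starts, seed.interval.end, side="left")
        window = slice(lo, hi)
        cand = idx[window]
        ov = np.minimum(ends[window], seed.interval.end) - np.maximum(
            starts[window], seed.interval.start
        )
        lens = ends[window] - starts[window]
        ro = np.where(ov > 0, np.minimum(ov / seed.length, ov / lens), 0.0)
        take = cand[(ro >= threshold) & ~assigned[cand]]
        assigned[take] = True
        members = sorted(take, key=lambda i: (frags[i].interval.start, frags[i].interval.end, frags[i].barcode))
        counts = np.sum([frags[i].counts for i in members], axis=0)
        groups.append(
            FragmentGroup(
                representative=seed.interval,
                member_keys=[frags[i].key for i in members],
                counts=np.asarray(counts, dtype=np.int64),
            )
        )
    for g in groups:
        iv = g.representative
        g.group_id = f"{iv.chrom}:{iv.start}-{iv.end}"
    return groups


def tiled_regions(frags: Sequence[Fragment], min_fragments: int = 10) -> list[TiledRegion]:
    """Connected components of fragments under any-overlap (>=1 shared bp).

    A component is reported iff it contains at least ``min_fragments``
    distinct (chrom, start, end) endpoint patterns; its interval is the union
    span [min start, max end] of members. Output intervals are pairwise
    disjoint by construction.
    """
    by_chrom: dict[str, list[Fragment]] = {}
    for f in frags:
        by_chrom.setdefault(f.interval.chrom, []).append(f)

    regions: list[TiledRegion] = []
    for chrom in sorted(by_chrom):
        fl = sorted(by_chrom[chrom], key=lambda f: (f.interval.start, f.interval.end))
        comp: list[Fragment] = []
        comp_end = -1
        for f in fl:
            if comp and f.interval.start >= comp_end:
                _emit(regions, chrom, comp, min_fragments)
                comp = []
            comp.append(f)
            comp_end = max(comp_end, f.interval.end)
        if comp:
            _emit(regions, chrom, comp, min_fragments)
    return regions


def _emit(regions: list[TiledRegion], chrom: str, comp: list[Fragment], min_fragments: int) -> None:
    region = TiledRegion(
        interval=GenomicInterval(chrom, comp[0].interval.start, max(f.interval.end for f in comp)),
        fragments=list(comp),
    )
    if region.fragment_count >= min_fragments:
        regions.append(region)
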