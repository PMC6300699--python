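"""Synthetic ATAC-STARR-seq data with known ground truth.

The generator emulates the statistical fingerprints of a transposase-built
reporter library that the downstream pipeline relies on:

* cut sites cluster in accessible chromatin, modeled per region as a mixture
  of 1-3 Gaussian accessibility peaks, so fragment endpoints densely sample
  the same loci the inference later dissects;
* size selection yields a bimodal fragment-length distribution (two Normal
  components with means 147 nt apart — the nucleosomal spacing — truncated to
  150-500 nt);
* plasmid abundances are negative-binomially dispersed around an
  accessibility-proportional depth, per replicate;
* RNA abundances scale the plasmid mean by 2^(mean latent score over the
  fragment), with short embedded *driver* intervals carrying a nonzero score;
* at heterozygous SNPs, fragments are assigned an allele at random and
  alternate-allele fragments have their RNA mean multiplied by 2^delta.

All outputs are deterministic functions of the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fragio import Fragment, GenomicInterval, SampleManifest

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_fragments",
    "simulate_counts",
    "simulate_allelic",
    "sample_fragment_intervals",
    "write_vcf",
    "write_genotype_map",
    "write_ground_truth",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one synthetic library."""

    n_regions: int = 30
    region_length: int = 2000
    region_gap: int = 10_000
    chrom: str = "chrS"
    # accessibility: 1-3 Gaussian peaks per region
    max_peaks: int = 3
    peak_sd_range: tuple[float, float] = (120.0, 300.0)
    # fragment lengths: two Normal components 147 nt apart, truncated
    frag_len_means: tuple[float, float] = (230.0, 377.0)
    frag_len_sds: tuple[float, float] = (35.0, 45.0)
    frag_len_weights: tuple[float, float] = (0.45, 0.55)
    frag_len_bounds: tuple[int, int] = (150, 500)
    fragments_per_region: int = 100
    # ground-truth drivers (log2 activity score inside the element)
    drivers_per_region: int = 1
    driver_length: int = 50
    driver_effect: float = 2.0
    # sequencing model; dispersion reflects the high replicate concordance of
    # plasmid-library reporter assays (Pearson ~0.95 between RNA replicates)
    depth: float = 200.0  # mean DNA count per fragment per replicate
    dispersion: float = 0.01
    n_dna: int = 5
    n_rna: int = 5
    # allelic model
    snps_per_region: int = 1
    allelic_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_length <= 0 or self.depth <= 0 or self.fragments_per_region <= 0:
            raise ValueError("region length, depth and fragment count must be positive")
        if self.frag_len_bounds[0] >= self.frag_len_bounds[1]:
            raise ValueError("invalid fragment length truncation bounds")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        lo, hi = self.frag_len_bounds
        # infeasible truncation: negligible mixture mass inside the bounds
        from scipy import stats

        mass = sum(
            w * (stats.norm.cdf(hi, m, s) - stats.norm.cdf(lo, m, s))
            for w, m, s in zip(self.frag_len_weights, self.frag_len_means, self.frag_len_sds)
        )
        if mass < 1e-6:
            raise ValueError("fragment-length mixture has ~no mass inside the truncation bounds")

    def manifest(self) -> SampleManifest:
        return SampleManifest.default(self.n_dna, self.n_rna)


@dataclass
class AccessibilityProfile:
    """Per-region mixture of Gaussian peaks over region-local coordinates."""

    centers: np.ndarray
    sds: np.ndarray
    weights: np.ndarray

    def density(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        comp = np.exp(-0.5 * ((x - self.centers) / self.sds) ** 2) / self.sds
        return (comp * self.weights).sum(axis=-1)

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=self.weights)
        return rng.normal(self.centers[comp], self.sds[comp])


@dataclass
class GroundTruth:
    """Latent state of a simulated library."""

    region_intervals: list[GenomicInterval]
    profiles: list[AccessibilityProfile]
    score_tracks: list[np.ndarray]  # per-region latent log2 score per nt
    driver_intervals: list[GenomicInterval]
    snps: list = field(default_factory=list)  # PhasedVariant list after simulate_allelic
    allelic_effect: float = 0.0

    def region_offset(self, r: int) -> int:
        return self.region_intervals[r].start

    def fragment_region(self, frag: Fragment) -> int | None:
        for r, iv in enumerate(self.region_intervals):
            if iv.overlap(frag.interval) > 0:
                return r
        return None


def _sample_profile(cfg: SimConfig, rng: np.random.Generator) -> AccessibilityProfile:
    k = int(rng.integers(1, cfg.max_peaks + 1))
    span = cfg.region_length
    centers = rng.uniform(0.15 * span, 0.85 * span, size=k)
    sds = rng.uniform(*cfg.peak_sd_range, size=k)
    weights = rng.dirichlet(np.ones(k))
    return AccessibilityProfile(centers=centers, sds=sds, weights=weights)


def _sample_length(cfg: SimConfig, rng: np.random.Generator) -> int:
    lo, hi = cfg.frag_len_bounds
    w = np.asarray(cfg.frag_len_weights, float)
    w = w / w.sum()
    for _ in range(10_000):
        comp = int(rng.choice(2, p=w))
        length = rng.normal(cfg.frag_len_means[comp], cfg.frag_len_sds[comp])
        if lo <= length <= hi:
            return int(round(length))
    raise RuntimeError("length rejection sampler failed; check truncation bounds")


def sample_fragment_intervals(
    cfg: SimConfig,
    profile: AccessibilityProfile,
    region: GenomicInterval,
    n: int,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Fragments as pairs of transposase cuts near accessibility peaks.

    One cut is drawn from the accessibility profile; the fragment extends a
    bimodally-distributed length in a random direction. Fragments leaving
    the region are resampled so every fragment lies within region bounds.
    """
    out = []
    span = region.length
    for _ in range(n):
        for _ in range(10_000):
            cut = profile.sample(rng, 1)[0]
            length = _sample_length(cfg, rng)
            left = rng.random() < 0.5
            start = cut - length if left else cut
            end = start + length
            if start >= 0 and end <= span:
                out.append(
                    GenomicInterval(region.chrom, region.start + int(round(start)), region.start + int(round(start)) + length)
                )
                break
        else:
            raise RuntimeError("fragment sampler failed; region too small for length bounds")
    return out


def simulate_fragments(cfg: SimConfig) -> tuple[list[Fragment], GroundTruth]:
    """Sample fragment positions, barcodes, and latent ground truth.

    Counts are left at zero; :func:`simulate_counts` fills them in. Driver
    elements are centered near accessibility peaks (regulatory elements live
    in accessible DNA, and this guarantees fragment coverage of the truth).
    """
    rng = np.random.default_rng(cfg.seed)
    manifest = cfg.manifest()
    regions: list[GenomicInterval] = []
    profiles: list[AccessibilityProfile] = []
    tracks: list[np.ndarray] = []
    drivers: list[GenomicInterval] = []
    frags: list[Fragment] = []
    seen_keys: set[tuple] = set()

    for r in range(cfg.n_regions):
        offset = r * (cfg.region_length + cfg.region_gap)
        region = GenomicInterval(cfg.chrom, offset, offset + cfg.region_length)
        profile = _sample_profile(cfg, rng)
        track = np.zeros(cfg.region_length)
        for _ in range(cfg.drivers_per_region):
            peak = int(rng.choice(len(profile.weights), p=profile.weights))
            center = profile.centers[peak] + rng.normal(0.0, 30.0)
            start = int(np.clip(round(center - cfg.driver_length / 2), 0, cfg.region_length - cfg.driver_length))
            track[start : start + cfg.driver_length] += cfg.driver_effect
            drivers.append(GenomicInterval(cfg.chrom, offset + start, offset + start + cfg.driver_length))
        intervals = sample_fragment_intervals(cfg, profile, region, cfg.fragments_per_region, rng)
        for iv in intervals:
            while True:
                barcode = "".join(rng.choice(_BASES, size=4))
                key = (iv.chrom, iv.start, iv.end, barcode)
                if key not in seen_keys:
                    break
            seen_keys.add(key)
            frags.append(Fragment(iv, barcode, np.zeros(len(manifest), dtype=np.int64)))
        regions.append(region)
        profiles.append(profile)
        tracks.append(track)

    truth = GroundTruth(
        region_intervals=regions,
        profiles=profiles,
        score_tracks=tracks,
        driver_intervals=drivers,
    )
    return frags, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _fragment_means(frags: Sequence[Fragment], truth: GroundTruth, cfg: SimConfig):
    """Per-fragment DNA mean (accessibility-weighted depth) and mean score."""
    dna_mean = np.empty(len(frags))
    score = np.empty(len(frags))
    access = np.empty(len(frags))
    for i, f in enumerate(frags):
        r = truth.fragment_region(f)
        if r is None:
            access[i] = 1.0
            score[i] = 0.0
            continue
        offset = truth.region_offset(r)
        mid = (f.interval.start + f.interval.end) // 2 - offset
        access[i] = truth.profiles[r].density(np.array([mid]))[0]
        s = f.interval.start - offset
        e = f.interval.end - offset
        score[i] = float(truth.score_tracks[r][s:e].mean())
    dna_mean = cfg.depth * access / access.mean()
    return dna_mean, score


def simulate_counts(
    frags: Sequence[Fragment],
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw NB counts per replicate; RNA means scale by 2^(fragment mean score).

    Also writes the counts back into the fragments' ``counts`` arrays and
    returns the fragment x sample matrix.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    manifest = cfg.manifest()
    dna_mean, score = _fragment_means(frags, truth, cfg)
    rna_mean = dna_mean * 2.0**score
    cols = []
    for _ in range(cfg.n_dna):
        cols.append(_nb_draw(rng, dna_mean, cfg.dispersion))
    for _ in range(cfg.n_rna):
        cols.append(_nb_draw(rng, rna_mean, cfg.dispersion))
    counts = np.column_stack(cols).astype(np.int64)
    for f, row in zip(frags, counts):
        f.counts = row.copy()
    ids = [f"{f.interval.chrom}:{f.interval.start}-{f.interval.end}:{f.barcode}" for f in frags]
    return pd.DataFrame(counts, index=ids, columns=list(manifest.labels))


def simulate_allelic(
    frags: Sequence[Fragment],
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list, dict[tuple, list[tuple[str, str]]], pd.DataFrame]:
    """Place het SNPs, assign alleles, and redraw counts with allelic effects.

    One SNP per region is placed at the strongest accessibility peak. Each
    fragment overlapping a SNP carries the reference or alternate allele with
    probability 1/2; alternate fragments have their RNA mean multiplied by
    2^allelic_effect. Returns (variants, genotype_map, count matrix); counts
    are written back into the fragments.
    """
    from .allelic import PhasedVariant

    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    manifest = cfg.manifest()
    variants: list[PhasedVariant] = []
    for r, (region, profile) in enumerate(zip(truth.region_intervals, truth.profiles)):
        for k in range(cfg.snps_per_region):
            peak = int(np.argmax(profile.weights)) if k == 0 else int(rng.integers(len(profile.weights)))
            pos = int(np.clip(round(profile.centers[peak]), 1, region.length - 2))
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            variants.append(
                PhasedVariant(
                    chrom=region.chrom,
                    pos=region.start + pos,
                    ref=str(ref),
                    alt=str(alt),
                    variant_id=f"snp_r{r}_{k}",
                    genotype="0|1",
                )
            )

    genotype_map: dict[tuple, list[tuple[str, str]]] = {}
    alt_mask = np.zeros(len(frags), dtype=bool)
    for i, f in enumerate(frags):
        overlapping = [
            v
            for v in variants
            if v.chrom == f.interval.chrom and f.interval.start <= v.pos < f.interval.end
        ]
        if not overlapping:
            continue
        is_alt = rng.random() < 0.5
        alt_mask[i] = is_alt
        allele = "alt" if is_alt else "ref"
        genotype_map[f.key] = [(v.variant_id, allele) for v in overlapping]

    dna_mean, score = _fragment_means(frags, truth, cfg)
    rna_mean = dna_mean * 2.0**score
    rna_mean = np.where(alt_mask, rna_mean * 2.0**cfg.allelic_effect, rna_mean)
    cols = [_nb_draw(rng, dna_mean, cfg.dispersion) for _ in range(cfg.n_dna)]
    cols += [_nb_draw(rng, rna_mean, cfg.dispersion) for _ in range(cfg.n_rna)]
    counts = np.column_stack(cols).astype(np.int64)
    for f, row in zip(frags, counts):
        f.counts = row.copy()
    ids = [f"{f.interval.chrom}:{f.interval.start}-{f.interval.end}:{f.barcode}" for f in frags]
    matrix = pd.DataFrame(counts, index=ids, columns=list(manifest.labels))
    truth.snps = variants
    truth.allelic_effect = cfg.allelic_effect
    return variants, genotype_map, matrix


def write_vcf(variants: Sequence, path: str | Path, sample: str = "SIM") -> None:
    """Minimal phased single-sample VCF 4.2 writer."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = []
        for v in variants:
            if v.chrom not in chroms:
                chroms.append(v.chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t{v.variant_id or '.'}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{v.genotype}\n"
            )


def write_genotype_map(genotype_map: dict[tuple, list[tuple[str, str]]], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for key in sorted(genotype_map):
            chrom, start, end, barcode = key
            for vid, allele in sorted(genotype_map[key]):
                fh.write(f"{chrom}\t{start}\t{end}\t{barcode}\t{vid}\t{allele}\n")


def write_ground_truth(truth: GroundTruth, cfg: SimConfig, path: str | Path) -> None:
    """JSON bundle with regions, driver intervals, SNPs, and the full config."""
    payload = {
        "config": {k: v for k, v in asdict(cfg).items()},
        "regions": [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end} for iv in truth.region_intervals
        ],
        "drivers": [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end} for iv in truth.driver_intervals
        ],
        "snps": [
            {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt, "id": v.variant_id}
            for v in truth.snps
        ],
        "allelic_effect": truth.allelic_effect,
    }
    with open(path, "w", newline="\n") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
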