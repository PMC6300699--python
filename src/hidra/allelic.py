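"""Allele-specific reporter activity at phased heterozygous SNPs.

Long-read re-sequencing of the plasmid library assigns each fragment identity
key (chrom, start, end, barcode) an allele at the heterozygous SNPs it
overlaps. Comparing RNA read totals between reference- and alternate-carrying
fragments, anchored on the plasmid-DNA allele ratio, tests whether the two
alleles drive different reporter activity.

Because fragments carrying different alleles can also differ in their
endpoints (a positional confounder), only tightly matched fragments are
compared: 90% reciprocal overlap between the two allele sets, fragment ends
at least 25 nt away from any driver element, and more than 20 reads for both
alleles in both libraries.

The test is a beta-binomial: under the null the RNA reference-allele count is
BetaBinomial(n = RNA total, mean = DNA reference proportion, overdispersion
rho), with rho shared across SNPs and estimated by the method of moments.
With rho = 0 the test reduces to an exact binomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fragio import Fragment, SampleManifest
from .grouping import reciprocal_overlap
from .sharprre import DriverElement

__all__ = [
    "PhasedVariant",
    "AllelePair",
    "read_phased_vcf",
    "read_genotype_map",
    "assign_alleles",
    "filter_pairs",
    "betabin_test",
    "estimate_rho",
    "call_allelic",
]


@dataclass(frozen=True)
class PhasedVariant:
    """Heterozygous single-nucleotide variant; ``pos`` is 0-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_id: str = ""
    genotype: str = "0|1"

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide variants are supported")
        if not self.variant_id:
            object.__setattr__(self, "variant_id", f"{self.chrom}:{self.pos + 1}:{self.ref}>{self.alt}")


@dataclass
class AllelePair:
    """Fragments split by allele at one SNP, with library totals per allele."""

    variant: PhasedVariant
    ref_fragments: list[Fragment] = field(default_factory=list)
    alt_fragments: list[Fragment] = field(default_factory=list)

    def totals(self, manifest: SampleManifest) -> dict[str, int]:
        dna = manifest.is_dna

        def tot(frags: list[Fragment], mask: np.ndarray) -> int:
            return int(sum(int(f.counts[mask].sum()) for f in frags))

        return {
            "ref_dna": tot(self.ref_fragments, dna),
            "alt_dna": tot(self.alt_fragments, dna),
            "ref_rna": tot(self.ref_fragments, ~dna),
            "alt_rna": tot(self.alt_fragments, ~dna),
        }


def read_phased_vcf(path: str | Path) -> list[PhasedVariant]:
    """Read phased heterozygous SNVs from a VCF (via cyvcf2).

    Non-SNV and homozygous records are skipped. VCF positions (1-based) are
    converted to 0-based here, the only coordinate-convention boundary in the
    package.
    """
    from cyvcf2 import VCF

    out: list[PhasedVariant] = []
    vcf = VCF(str(path))
    for rec in vcf:
        if not rec.is_snp or len(rec.ALT) != 1:
            continue
        gts = rec.genotypes
        if not gts:
            continue
        a, b = gts[0][0], gts[0][1]
        if a == b:
            continue  # homozygous
        phased = bool(gts[0][2]) if len(gts[0]) > 2 else False
        gt = f"{a}|{b}" if phased else f"{a}/{b}"
        out.append(
            PhasedVariant(
                chrom=rec.CHROM,
                pos=rec.POS - 1,
                ref=rec.REF,
                alt=rec.ALT[0],
                variant_id=rec.ID or "",
                genotype=gt,
            )
        )
    return out


def read_genotype_map(path: str | Path) -> dict[tuple, list[tuple[str, str]]]:
    """Genotype map TSV: chrom, start, end, barcode, variant id, allele."""
    out: dict[tuple, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{i}: expected 6 columns")
            chrom, start, end, barcode, vid, allele = parts
            if allele not in ("ref", "alt"):
                raise ValueError(f"{path}:{i}: allele must be 'ref' or 'alt'")
            out.setdefault((chrom, int(start), int(end), barcode), []).append((vid, allele))
    return out


def assign_alleles(
    frags: Sequence[Fragment],
    variants: Sequence[PhasedVariant],
    genotype_map: dict[tuple, list[tuple[str, str]]],
) -> tuple[list[AllelePair], dict]:
    """Split fragments overlapping each SNP by their genotyped allele.

    Fragments without a genotype record for a SNP they overlap (or with
    conflicting records) are dropped and tallied in the returned summary.
    A genotype record naming a variant whose position the fragment does not
    contain raises a consistency error.
    """
    by_id = {v.variant_id: v for v in variants}
    for key, records in genotype_map.items():
        chrom, start, end, _ = key
        for vid, _allele in records:
            v = by_id.get(vid)
            if v is not None and not (v.chrom == chrom and start <= v.pos < end):
                raise ValueError(
                    f"genotype record for fragment {chrom}:{start}-{end} names variant "
                    f"{vid} at {v.chrom}:{v.pos} outside the fragment"
                )

    pairs = {v.variant_id: AllelePair(variant=v) for v in variants}
    dropped_no_genotype = 0
    dropped_ambiguous = 0
    for f in frags:
        records = genotype_map.get(f.key)
        rec_by_vid = {}
        ambiguous = set()
        if records:
            for vid, allele in records:
                if vid in rec_by_vid and rec_by_vid[vid] != allele:
                    ambiguous.add(vid)
                rec_by_vid[vid] = allele
        for v in variants:
            if v.chrom != f.interval.chrom or not (f.interval.start <= v.pos < f.interval.end):
                continue
            if v.variant_id in ambiguous:
                dropped_ambiguous += 1
                continue
            allele = rec_by_vid.get(v.variant_id)
            if allele is None:
                dropped_no_genotype += 1
                continue
            pair = pairs[v.variant_id]
            (pair.ref_fragments if allele == "ref" else pair.alt_fragments).append(f)
    summary = {
        "dropped_no_genotype": dropped_no_genotype,
        "dropped_ambiguous": dropped_ambiguous,
    }
    return [p for p in pairs.values() if p.ref_fragments or p.alt_fragments], summary


def _end_distance(x: int, drivers: Sequence[DriverElement]) -> float:
    """Distance from coordinate x to the nearest driver-element boundary/interior."""
    best = np.inf
    for d in drivers:
        s, e = d.interval.start, d.interval.end
        if s <= x <= e:
            return 0.0
        best = min(best, abs(x - s), abs(x - e))
    return best


def filter_pairs(
    pairs: Sequence[AllelePair],
    manifest: SampleManifest,
    drivers: Sequence[DriverElement] = (),
    min_overlap: float = 0.90,
    end_margin: int = 25,
    min_reads: int = 20,
) -> list[AllelePair]:
    """Enforce the positional-confounder and coverage filters.

    1. Fragments whose either end lies within ``end_margin`` nt of a driver
       element (strictly closer than the margin) are removed.
    2. Within each SNP, fragments are greedily retained (highest total count
       first) so that every kept ref fragment has reciprocal overlap
       >= ``min_overlap`` with every kept alt fragment.
    3. Pairs are kept only if both alleles exceed ``min_reads`` total reads
       (strict >) in both the DNA and the RNA libraries.
    """
    out: list[AllelePair] = []
    for pair in pairs:
        def end_ok(f: Fragment) -> bool:
            return (
                _end_distance(f.interval.start, drivers) >= end_margin
                and _end_distance(f.interval.end, drivers) >= end_margin
            )

        cands = [(f, "ref") for f in pair.ref_fragments if end_ok(f)] + [
            (f, "alt") for f in pair.alt_fragments if end_ok(f)
        ]
        # greedy mutual-overlap clique: highest-coverage fragments first
        cands.sort(key=lambda t: (-int(t[0].counts.sum()), t[0].key))
        kept: list[tuple[Fragment, str]] = []
        for f, allele in cands:
            if all(
                reciprocal_overlap(f.interval, g.interval) >= min_overlap for g, _ in kept
            ):
                kept.append((f, allele))
        filtered = AllelePair(
            variant=pair.variant,
            ref_fragments=[f for f, a in kept if a == "ref"],
            alt_fragments=[f for f, a in kept if a == "alt"],
        )
        t = filtered.totals(manifest)
        if (
            t["ref_dna"] > min_reads
            and t["alt_dna"] > min_reads
            and t["ref_rna"] > min_reads
            and t["alt_rna"] > min_reads
        ):
            out.append(filtered)
    return out


def _betabinom_logpmf(k: np.ndarray, n: int, mean: float, rho: float) -> np.ndarray:
    if rho <= 0:
        return stats.binom.logpmf(k, n, mean)
    conc = 1.0 / rho - 1.0
    return stats.betabinom.logpmf(k, n, mean * conc, (1.0 - mean) * conc)


def betabin_test(
    pair_or_counts,
    manifest: SampleManifest | None = None,
    rho: float = 0.0,
) -> dict:
    """Two-sided beta-binomial test of allelic imbalance for one SNP.

    The null distribution of the RNA reference count is
    BetaBinomial(n = RNA total, mean = DNA reference proportion, rho); the
    two-sided p-value sums the probabilities of all outcomes no more likely
    than the observed one (minimum-likelihood ordering, exact). Accepts
    either an :class:`AllelePair` (with ``manifest``) or a dict of totals.
    A DNA proportion of exactly 0 or 1 is untestable.
    """
    if isinstance(pair_or_counts, AllelePair):
        if manifest is None:
            raise ValueError("manifest required with an AllelePair")
        t = pair_or_counts.totals(manifest)
        variant = pair_or_counts.variant
    else:
        t = dict(pair_or_counts)
        variant = t.get("variant")
    ref_rna, alt_rna = int(t["ref_rna"]), int(t["alt_rna"])
    ref_dna, alt_dna = int(t["ref_dna"]), int(t["alt_dna"])
    n_rna = ref_rna + alt_rna
    n_dna = ref_dna + alt_dna
    result = {
        "variant": variant,
        "ref_rna": ref_rna,
        "alt_rna": alt_rna,
        "ref_dna": ref_dna,
        "alt_dna": alt_dna,
        "rna_ref_prop": ref_rna / n_rna if n_rna else np.nan,
        "dna_ref_prop": ref_dna / n_dna if n_dna else np.nan,
        "rho": rho,
    }
    p0 = result["dna_ref_prop"]
    if n_rna == 0 or n_dna == 0 or p0 in (0.0, 1.0) or np.isnan(p0):
        result.update(p=1.0, untestable=True)
        return result
    k = np.arange(n_rna + 1)
    logpmf = _betabinom_logpmf(k, n_rna, p0, rho)
    obs = logpmf[ref_rna]
    # sum over outcomes with density <= observed (small tolerance for ties)
    mask = logpmf <= obs + 1e-12
    from scipy.special import logsumexp

    p = float(np.exp(logsumexp(logpmf[mask])))
    result.update(p=min(p, 1.0), untestable=False)
    return result


def estimate_rho(
    pairs: Sequence[AllelePair] | pd.DataFrame,
    manifest: SampleManifest | None = None,
    min_pairs: int = 20,
) -> float:
    """Shared beta-binomial overdispersion by the method of moments.

    The squared deviation of the RNA reference proportion from the DNA
    proportion, in excess of both libraries' binomial sampling variance, is
    attributed to overdispersion: summing over SNPs,

        rho = sum[(pR-pD)^2 - pD(1-pD)(1/nR + 1/nD)] / sum[pD(1-pD)(nR-1)/nR]

    clipped to [0, 0.5]. Requires at least ``min_pairs`` testable SNPs.
    """
    if isinstance(pairs, pd.DataFrame):
        df = pairs
    else:
        if manifest is None:
            raise ValueError("manifest required with AllelePair input")
        rows = [p.totals(manifest) for p in pairs]
        df = pd.DataFrame(rows)
    n_rna = (df["ref_rna"] + df["alt_rna"]).to_numpy(dtype=float)
    n_dna = (df["ref_dna"] + df["alt_dna"]).to_numpy(dtype=float)
    ok = (n_rna > 0) & (n_dna > 0)
    df, n_rna, n_dna = df[ok], n_rna[ok], n_dna[ok]
    if len(df) < min_pairs:
        raise ValueError(f"rho estimation requires >= {min_pairs} pairs, got {len(df)}")
    p_rna = df["ref_rna"].to_numpy(dtype=float) / n_rna
    p_dna = df["ref_dna"].to_numpy(dtype=float) / n_dna
    keep = (p_dna > 0) & (p_dna < 1)
    p_rna, p_dna, n_rna, n_dna = p_rna[keep], p_dna[keep], n_rna[keep], n_dna[keep]
    pq = p_dna * (1.0 - p_dna)
    num = np.sum((p_rna - p_dna) ** 2 - pq * (1.0 / n_rna + 1.0 / n_dna))
    den = np.sum(pq * (n_rna - 1.0) / n_rna)
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 0.5))


def call_allelic(
    results: Iterable[dict] | pd.DataFrame,
    alpha_nominal: float = 0.05,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """BH correction across tested SNPs with nominal and FDR significance tiers."""
    from .activity import bh_adjust

    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(list(results))
    if len(df) == 0:
        df["fdr"] = []
        df["nominal"] = []
        df["significant_fdr"] = []
        return df
    testable = ~df.get("untestable", pd.Series(False, index=df.index)).astype(bool)
    fdr = np.ones(len(df))
    fdr[testable.to_numpy()] = bh_adjust(df.loc[testable, "p"].to_numpy())
    df = df.copy()
    df["fdr"] = fdr
    df["nominal"] = (df["p"] < alpha_nominal) & testable
    df["significant_fdr"] = (df["fdr"] < fdr_threshold) & testable
    return df
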