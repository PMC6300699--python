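"""Calling transcriptionally active fragment groups.

A fragment group is *active* when its RNA abundance significantly exceeds its
plasmid-DNA abundance. The test is a negative-binomial GLM Wald test of the
condition effect (RNA vs DNA) with a log link and size-factor offsets:

    K_gj ~ NB(mean = s_j * exp(eta_g,cond(j)), dispersion = alpha_g)

where s_j are median-of-ratios size factors and alpha_g is a per-group
method-of-moments dispersion shrunk toward a mean-dependent trend. Because
transfection efficiency can depend on fragment length, Benjamini-Hochberg
correction is applied separately within 100-nt length bins, and a group is
called active iff fdr < alpha AND log2 fold-change > 0 (up-regulated only).

The two-condition-with-offsets design admits a closed-form score equation per
condition, solved by a vectorized Newton iteration; no general GLM machinery
is needed, which keeps 10^4-group simulations fast.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fragio import GenomicInterval, SampleManifest, rpm_normalize
from .grouping import FragmentGroup

__all__ = [
    "size_factors",
    "estimate_dispersion",
    "nb_wald",
    "nb_test_group",
    "bh_adjust",
    "call_active",
    "merge_active_regions",
    "signal_track",
]

_LN2 = np.log(2.0)


def size_factors(matrix: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    The reference is the per-row geometric mean over rows with no zero count;
    factor_j is the median over those rows of count_rj / geomean_r. With
    ``pseudo_reference=True`` the geometric mean is computed over positive
    entries only, rescuing matrices where every row contains a zero.
    """
    counts = matrix.to_numpy(dtype=float)
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(counts), np.nan)
        npos = np.sum(counts > 0, axis=1)
        usable = npos > 0
        loggeo = np.nanmean(logc[usable], axis=1)
        rows = counts[usable]
    else:
        usable = (counts > 0).all(axis=1)
        if not usable.any():
            raise ValueError(
                "no row is free of zeros; re-run with pseudo_reference=True "
                "to use a positive-entry pseudo-reference"
            )
        rows = counts[usable]
        loggeo = np.log(rows).mean(axis=1)
    with np.errstate(divide="ignore"):
        logratios = np.where(rows > 0, np.log(rows), np.nan) - loggeo[:, None]
    logsf = np.nanmedian(logratios, axis=0)
    logsf = logsf - np.mean(logsf)  # geometric mean 1
    return pd.Series(np.exp(logsf), index=matrix.columns)


def _moments_dispersion(counts: np.ndarray, sf: np.ndarray, is_dna: np.ndarray) -> np.ndarray:
    """Raw per-group method-of-moments NB dispersion from within-condition variance."""
    q = counts / sf  # normalized counts
    disp = np.zeros(counts.shape[0])
    wsum = np.zeros(counts.shape[0])
    for mask in (is_dna, ~is_dna):
        nc = int(mask.sum())
        if nc < 2:
            continue
        m = q[:, mask].mean(axis=1)
        v = q[:, mask].var(axis=1, ddof=1)
        inv_s = np.mean(1.0 / sf[mask])
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m * inv_s) / m**2, 0.0)
        w = nc - 1
        disp += w * np.maximum(a, 0.0)
        wsum += w
    return disp / np.maximum(wsum, 1)


def estimate_dispersion(
    matrix: pd.DataFrame | np.ndarray,
    manifest: SampleManifest,
    factors: pd.Series | np.ndarray,
    n_slices: int = 20,
    shrink: float = 0.5,
    floor: float = 1e-8,
) -> np.ndarray:
    """Trend-shrunk method-of-moments dispersions for one matrix (e.g. one bin).

    Per-group raw dispersions are computed from within-condition variance,
    then shrunk ``shrink``/(1-``shrink``) toward the bin trend: the median raw
    dispersion in ``n_slices`` baseMean quantile slices, linearly interpolated
    at each group's baseMean. Requires >=2 replicates in at least one
    condition; the result is floored at ``floor``.
    """
    counts = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    sf = np.asarray(factors, dtype=float)
    is_dna = manifest.is_dna
    if int(is_dna.sum()) < 2 and int((~is_dna).sum()) < 2:
        raise ValueError("dispersion estimation requires >=2 replicates in a condition")
    raw = _moments_dispersion(counts, sf, is_dna)
    base_mean = (counts / sf).mean(axis=1)

    n = len(raw)
    if n >= 2 * n_slices:
        order = np.argsort(base_mean)
        slices = np.array_split(order, n_slices)
        centers = np.array([np.median(base_mean[s]) for s in slices])
        medians = np.array([np.median(raw[s]) for s in slices])
        uniq, first = np.unique(centers, return_index=True)
        trend = np.interp(base_mean, uniq, medians[first])
    else:
        trend = np.full(n, np.median(raw))
    return np.maximum(shrink * raw + (1.0 - shrink) * trend, floor)


def _nb_condition_mle(
    counts: np.ndarray, sf: np.ndarray, disp: np.ndarray, n_iter: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """MLE mean and Var(log mean) per group for one condition, vectorized.

    Score equation for the NB log-mean with offsets s_j and fixed dispersion:
    sum_j (K_j - s_j*mu) / (1 + a*s_j*mu) = 0. Newton in log mu; with a=0
    this is the Poisson MLE sum(K)/sum(s) exactly. Groups with zero total are
    returned with mu=0 and infinite variance.
    """
    K = counts  # (G, S)
    total = K.sum(axis=1)
    ssum = sf.sum()
    mu = np.maximum(total / ssum, 1e-300)
    a = disp
    active = total > 0
    for _ in range(n_iter):
        den = 1.0 + a[:, None] * sf[None, :] * mu[:, None]
        f = ((K - sf[None, :] * mu[:, None]) / den).sum(axis=1)
        # d f / d log mu = mu * f'(mu); f'(mu) = -sum s_j (1 + a K_j) / den^2
        fp = -(sf[None, :] * (1.0 + a[:, None] * K) / den**2).sum(axis=1)
        step = np.where(active, f / (fp * mu + 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        mu = np.where(active, mu * np.exp(-step), mu)
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = np.where(active, mu, 0.0)
    m = sf[None, :] * mu[:, None]
    info = (m / (1.0 + a[:, None] * m)).sum(axis=1)
    var_log = np.where(info > 0, 1.0 / np.maximum(info, 1e-300), np.inf)
    return mu, var_log


def nb_wald(
    counts: np.ndarray,
    manifest: SampleManifest,
    factors: np.ndarray | pd.Series,
    dispersions: np.ndarray | float,
) -> pd.DataFrame:
    """Vectorized NB Wald test (RNA vs DNA) for a stack of groups.

    Returns a DataFrame with columns baseMean, log2fc, se, p, untestable.
    Groups with zero total counts in either condition are flagged untestable
    (p=1, log2fc=0): the fold-change is unidentified on the log scale.
    With dispersion 0 the fit reduces exactly to a Poisson GLM.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    sf = np.asarray(factors, dtype=float)
    disp = np.broadcast_to(np.asarray(dispersions, dtype=float), (counts.shape[0],)).copy()
    is_dna = manifest.is_dna

    mu_d, var_d = _nb_condition_mle(counts[:, is_dna], sf[is_dna], disp)
    mu_r, var_r = _nb_condition_mle(counts[:, ~is_dna], sf[~is_dna], disp)

    untestable = (mu_d <= 0) | (mu_r <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.log(mu_r) - np.log(mu_d)
    beta = np.where(untestable, 0.0, beta)
    se = np.sqrt(var_d + var_r)
    se = np.where(untestable, np.inf, se)
    z = np.where(untestable, 0.0, beta / se)
    p = np.where(untestable, 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    base_mean = (counts / sf).mean(axis=1)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": beta / _LN2,
            "se": se / _LN2,
            "p": np.clip(p, 0.0, 1.0),
            "untestable": untestable,
        }
    )


def nb_test_group(
    counts: Sequence[int] | np.ndarray,
    manifest: SampleManifest,
    factors: np.ndarray | pd.Series,
    dispersion: float,
) -> pd.Series:
    """Single-group convenience wrapper around :func:`nb_wald`."""
    return nb_wald(np.asarray(counts, float)[None, :], manifest, factors, dispersion).iloc[0]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_active(
    groups: Sequence[FragmentGroup],
    manifest: SampleManifest,
    alpha: float = 0.05,
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Full activity-calling pass over fragment groups.

    Size factors are estimated from the group count matrix; dispersion trends
    and Benjamini-Hochberg correction are computed strictly within 100-nt
    length bins (no cross-bin correction). A group is active iff its in-bin
    fdr < ``alpha`` and log2fc > 0.
    """
    if not groups:
        return pd.DataFrame(
            columns=["group_id", "length_bin", "baseMean", "log2fc", "se", "p", "fdr", "active"]
        )
    counts = np.vstack([g.counts for g in groups]).astype(float)
    matrix = pd.DataFrame(counts, columns=list(manifest.labels))
    sf = size_factors(matrix, pseudo_reference=pseudo_reference).to_numpy()

    bins = np.array([g.length_bin for g in groups])
    res = pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "length_bin": bins,
            "baseMean": 0.0,
            "log2fc": 0.0,
            "se": 0.0,
            "p": 1.0,
            "fdr": 1.0,
            "active": False,
        }
    )
    for b in np.unique(bins):
        sel = np.flatnonzero(bins == b)
        sub = counts[sel]
        disp = estimate_dispersion(sub, manifest, sf)
        stats_df = nb_wald(sub, manifest, sf, disp)
        fdr = bh_adjust(stats_df["p"].to_numpy())
        res.loc[sel, ["baseMean", "log2fc", "se", "p"]] = stats_df[
            ["baseMean", "log2fc", "se", "p"]
        ].to_numpy()
        res.loc[sel, "fdr"] = fdr
        res.loc[sel, "active"] = (fdr < alpha) & (stats_df["log2fc"].to_numpy() > 0)
    return res


def merge_active_regions(
    results: pd.DataFrame, groups: Sequence[FragmentGroup]
) -> list[GenomicInterval]:
    """Union-merge the representative intervals of active groups (any-overlap)."""
    by_id = {g.group_id: g for g in groups}
    active = [
        by_id[gid].representative
        for gid, act in zip(results["group_id"], results["active"])
        if act and gid in by_id
    ]
    if not active:
        return []
    active.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur = active[0]
    for iv in active[1:]:
        if iv.chrom == cur.chrom and iv.start < cur.end:
            cur = GenomicInterval(cur.chrom, cur.start, max(cur.end, iv.end))
        else:
            merged.append(cur)
            cur = iv
    merged.append(cur)
    return merged


def fragment_activity(
    matrix: pd.DataFrame, manifest: SampleManifest, pseudocount: float = 0.1
) -> pd.Series:
    """Per-row regulatory activity a = (RNA-DNA)/DNA on RPM scale + pseudocount.

    RNA and DNA are the mean RPM over the respective replicates; the
    pseudocount is added to both so rows with equal abundance score exactly 0.
    """
    rpm = rpm_normalize(matrix)
    dna = rpm[manifest.dna_labels].mean(axis=1) + pseudocount
    rna = rpm[manifest.rna_labels].mean(axis=1) + pseudocount
    return (rna - dna) / dna


def signal_track(
    frags,
    matrix: pd.DataFrame,
    manifest: SampleManifest,
    pseudocount: float = 0.1,
    reduce: str = "mean",
    decimals: int = 4,
) -> dict[str, list[tuple[int, int, float]]]:
    """Per-base activity track as bedGraph-style runs per chromosome.

    Each covered base gets the mean (or max) activity of fragments covering
    it; uncovered bases are absent. Matrix rows must align with ``frags``.
    """
    if reduce not in ("mean", "max"):
        raise ValueError("reduce must be 'mean' or 'max'")
    act = fragment_activity(matrix, manifest, pseudocount).to_numpy()
    by_chrom: dict[str, list[int]] = {}
    for i, f in enumerate(frags):
        by_chrom.setdefault(f.interval.chrom, []).append(i)

    out: dict[str, list[tuple[int, int, float]]] = {}
    for chrom in sorted(by_chrom):
        idx = by_chrom[chrom]
        lo = min(frags[i].interval.start for i in idx)
        hi = max(frags[i].interval.end for i in idx)
        n = hi - lo
        if reduce == "mean":
            val = np.zeros(n + 1)
            cov = np.zeros(n + 1)
            for i in idx:
                s, e = frags[i].interval.start - lo, frags[i].interval.end - lo
                val[s] += act[i]
                val[e] -= act[i]
                cov[s] += 1
                cov[e] -= 1
            val = np.cumsum(val)[:-1]
            cov = np.cumsum(cov)[:-1]
            with np.errstate(invalid="ignore", divide="ignore"):
                per_base = np.where(cov > 0, val / cov, np.nan)
        else:
            per_base = np.full(n, -np.inf)
            for i in idx:
                s, e = frags[i].interval.start - lo, frags[i].interval.end - lo
                np.maximum.at(per_base, np.arange(s, e), act[i])
            per_base[per_base == -np.inf] = np.nan
            cov = ~np.isnan(per_base)

        per_base = np.round(per_base, decimals)
        runs: list[tuple[int, int, float]] = []
        start = None
        for pos in range(n + 1):
            v = per_base[pos] if pos < n else np.nan
            if start is not None:
                prev = per_base[start]
                if pos == n or np.isnan(v) or v != prev:
                    runs.append((lo + start, lo + pos, float(prev)))
                    start = None
            if pos < n and not np.isnan(v) and start is None:
                start = pos
        out[chrom] = runs
    return out


def write_bedgraph(track: dict[str, list[tuple[int, int, float]]], path) -> None:
    with open(path, "w", newline="\n") as fh:
        for chrom in sorted(track):
            for s, e, v in track[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
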