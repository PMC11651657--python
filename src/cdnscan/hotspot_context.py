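"""Mutational-hotspot diagnostics for high-recurrence sites.

Three questions about whether recurrence could be mutational rather than
selective: (1) how much does mutability vary across k-mer motifs (the
max/mean spread alpha); (2) do the local sequences around recurrent sites
look more alike than random sequence (consensus-length comparison against a
Poisson(W/4) null for match counts); (3) is a group of sites shifted toward
high mutability relative to the pool (one-sided K-S with a resampling-
adjusted significance).
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .opportunity import MotifOpportunity, _encode

logger = logging.getLogger(__name__)

RATE_SCALE = 1e5  # rates reported per 1e5 motif sites


@dataclass
class MotifRateTable:
    """Per-motif mutation rates and the max/mean spread statistic.

    ``table`` has columns motif / count / site_number / rate (the rate is
    scaled per 1e5 motif sites; motifs with zero site number are reported
    with an undefined rate and excluded from alpha_stat).
    """

    k: int
    table: pd.DataFrame
    alpha_stat: float


def motif_rate_table(counts: Mapping[str, float], sites: Mapping[str, float],
                     k: int) -> MotifRateTable:
    """Assemble a rate table from per-motif numerators and site numbers."""
    motifs = sorted(set(counts) | set(sites))
    for m in motifs:
        if len(m) != k or any(b not in "ACGT" for b in m):
            raise ValueError(f"motif {m!r} is not a length-{k} ACGT string")
    rows = []
    for m in motifs:
        c, s = counts.get(m, 0.0), sites.get(m, 0.0)
        rate = c / s * RATE_SCALE if s > 0 else np.nan
        rows.append({"motif": m, "count": c, "site_number": s, "rate": rate})
    df = pd.DataFrame(rows, columns=["motif", "count", "site_number", "rate"])
    defined = df["rate"].dropna()
    if len(defined) and defined.mean() > 0:
        alpha = float(defined.max() / defined.mean())
    else:
        alpha = np.nan
    return MotifRateTable(k=k, table=df, alpha_stat=alpha)


def motif_rates(records: Iterable, cds_set: Mapping[str, str],
                motif_opportunity: MotifOpportunity) -> MotifRateTable:
    """Per-motif mutation rates from a cohort (Fig-4A-style table).

    For k in {3, 5} the numerators count synonymous mutations only; for
    k = 7 they count all singleton mutations (keys hit in exactly one
    patient) of either missense or synonymous class.  Each record's motif is
    the reference context centered on its position; records too close to a
    CDS edge are skipped.
    """
    k = motif_opportunity.k
    h = k // 2
    records = list(records)

    if k == 7:
        patients = defaultdict(set)
        for r in records:
            patients[r.key].add(r.patient_id)
        records = [r for r in records if len(patients[r.key]) == 1
                   and r.consequence in ("missense", "synonymous")]
        # singletons contribute once even if a patient's call is duplicated
        seen = set()
        uniq = []
        for r in records:
            if r.key not in seen:
                seen.add(r.key)
                uniq.append(r)
        records = uniq
    else:
        records = [r for r in records if r.consequence == "synonymous"]

    counts: dict[str, float] = defaultdict(float)
    n_edge = 0
    for r in records:
        if r.chrom not in cds_set:
            raise KeyError(f"record chromosome {r.chrom!r} not in the CDS set")
        seq = cds_set[r.chrom]
        i0 = r.pos - 1
        if i0 < h or i0 + h >= len(seq):
            n_edge += 1
            continue
        if seq[i0] != r.ref:
            raise ValueError(
                f"record ref {r.ref} at {r.chrom}:{r.pos} does not match CDS base {seq[i0]}")
        counts[seq[i0 - h:i0 + h + 1]] += 1
    if n_edge:
        logger.info("motif_rates: skipped %d records without full %d-mer context", n_edge, k)
    return motif_rate_table(counts, motif_opportunity.table, k)


@dataclass
class ConsensusResult:
    """Consensus-length distribution for one window size, with its Poisson test.

    Consensus length is the match count, window minus Hamming distance;
    under random sequence it is close to Poisson(lambda = W/4).  The K-S
    test is one-sided for a heavy right tail (consensus stochastically
    greater than the null).
    """

    window: int
    consensus: np.ndarray
    ks_stat: float
    p_value: float

    def __post_init__(self):
        w = self.window
        if len(self.consensus) and (self.consensus.min() < 0 or self.consensus.max() > w):
            raise ValueError("consensus lengths must lie in [0, window]")


def windows_from_reference(reference: Mapping[str, str],
                           sites: Sequence[tuple[str, int, str]],
                           half_width: int) -> list[tuple[str, str]]:
    """Extract (gene, window) pairs of width 2*half_width+1 around 1-based sites.

    ``sites`` are (chrom, pos, gene) triples; sites too close to a contig
    edge are skipped with a log message.
    """
    out = []
    skipped = 0
    for chrom, pos, gene in sites:
        seq = reference[chrom]
        i0 = pos - 1
        if i0 - half_width < 0 or i0 + half_width >= len(seq):
            skipped += 1
            continue
        out.append((gene, seq[i0 - half_width:i0 + half_width + 1].upper()))
    if skipped:
        logger.info("windows_from_reference: skipped %d edge sites", skipped)
    return out


def consensus_compare(site_windows: Sequence[tuple[str, str]],
                      window_sizes: Sequence[int] = (21, 41, 61, 81, 101),
                      stride: int = 10,
                      homology_exclusions: Iterable[tuple[str, str]] | None = None,
                      ) -> list[ConsensusResult]:
    """Pairwise consensus lengths around recurrence sites vs the Poisson null.

    ``site_windows`` are (gene, sequence) pairs, each sequence odd-length and
    centered on its site.  For every window size W each site contributes the
    W-wide slices at offsets in ``stride`` steps that fit its sequence;
    slices of different sites at the same offset are compared.  Pairs of
    sites from the same gene, or from gene pairs in ``homology_exclusions``,
    are skipped (homology would mimic a mutational motif).
    """
    excl = {frozenset(pair) for pair in (homology_exclusions or [])}
    genes = [g for g, _ in site_windows]
    seqs = []
    for g, s in site_windows:
        if len(s) % 2 == 0:
            raise ValueError(f"window for gene {g!r} has even length {len(s)}; "
                             "windows must be odd and centered on the site")
        seqs.append(_encode(s, g))

    results = []
    for W in window_sizes:
        if W % 2 == 0:
            raise ValueError(f"window size {W} is not odd")
        half = W // 2
        slices: list[dict[int, np.ndarray]] = []
        for s in seqs:
            center = len(s) // 2
            max_o = center - half
            offs = range(-(max_o // stride) * stride, max_o + 1, stride)
            slices.append({o: s[center + o - half:center + o + half + 1] for o in offs})
        consensus = []
        for ia, ib in combinations(range(len(seqs)), 2):
            if genes[ia] == genes[ib] or frozenset((genes[ia], genes[ib])) in excl:
                continue
            common = slices[ia].keys() & slices[ib].keys()
            for o in common:
                consensus.append(W - int((slices[ia][o] != slices[ib][o]).sum()))
        consensus = np.array(consensus, dtype=int)
        if len(consensus):
            stat, p = _discrete_ks_greater(consensus, W, stats.poisson(W / 4))
        else:
            stat, p = np.nan, np.nan
        results.append(ConsensusResult(window=W, consensus=consensus,
                                       ks_stat=stat, p_value=p))
    return results


def _discrete_ks_greater(sample: np.ndarray, support_max: int,
                         null) -> tuple[float, float]:
    """One-sided K-S of integer data vs a discrete null (sample greater).

    Both CDFs are evaluated right-continuously on the integer support, which
    is what makes the statistic meaningful for heavily tied count data (a
    continuous-data K-S routine overstates the discrepancy at ties).  The
    p-value is the one-sided Smirnov tail exp(-2 n D^2), conservative for
    discrete distributions.
    """
    n = len(sample)
    xs = np.arange(0, support_max + 1)
    ecdf = np.searchsorted(np.sort(sample), xs, side="right") / n
    d = max(0.0, float((null.cdf(xs) - ecdf).max()))
    p = min(1.0, float(np.exp(-2.0 * n * d * d)))
    return d, p


def _d_greater(sub_sorted: np.ndarray, pool_sorted: np.ndarray) -> float:
    """One-sided two-sample K-S statistic for 'subset stochastically greater'.

    D = sup_x [F_pool(x) - F_subset(x)], the statistic scipy's ks_2samp
    reports for alternative='less' with the subset as first sample.
    """
    g, P = len(sub_sorted), len(pool_sorted)
    fs = np.arange(1, g + 1) / g
    left = np.searchsorted(pool_sorted, sub_sorted, side="left") / P
    right = np.searchsorted(pool_sorted, sub_sorted, side="right") / P
    cand = np.maximum(left - np.arange(g) / g, right - fs)
    return max(0.0, float(cand.max()))


def resampled_ks(group_values: Sequence[float], pool_values: Sequence[float],
                 n_resample: int = 100_000, seed: int | None = None,
                 literal: bool = False) -> tuple[float, float]:
    """One-sided K-S of group vs pool with a resampling-adjusted significance.

    The raw p0 tests whether the group is stochastically greater than the
    pool.  ``n_resample`` same-size subsets drawn from the pool (without
    replacement) each yield a significance p_j; the adjusted p is the
    fraction of resamples with p_j <= p0 (the standard permutation
    convention).  With equal subset sizes p_j is a monotone decreasing
    function of the K-S statistic, so statistics are compared directly.
    ``literal=True`` instead returns the fraction with p0 < p_j.
    Deterministic under a fixed seed.
    """
    group = np.sort(np.asarray(group_values, dtype=float))
    pool = np.asarray(pool_values, dtype=float)
    g = len(group)
    if g < 1:
        raise ValueError("group must contain at least one value")
    if g > len(pool):
        raise ValueError(f"group size {g} exceeds pool size {len(pool)}")
    p0 = float(stats.ks_2samp(group, pool, alternative="less").pvalue)
    pool_sorted = np.sort(pool)
    d0 = _d_greater(group, pool_sorted)

    rng = np.random.default_rng(seed)
    d = np.empty(n_resample)
    for j in range(n_resample):
        sub = np.sort(rng.choice(pool, size=g, replace=False))
        d[j] = _d_greater(sub, pool_sorted)
    if literal:
        adjusted = float((d < d0 - 1e-12).mean())
    else:
        adjusted = float((d >= d0 - 1e-12).mean())
    return p0, adjusted
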