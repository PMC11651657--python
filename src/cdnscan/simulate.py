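"""Synthetic cohorts with the statistical structure the theory assumes.

Sites draw per-site mutation rates from a gamma distribution with mean E(u)
and shape k, constant across patients.  A CpG stratum (default 6.5% of
sites) is elevated sevenfold, an optional outlier stratum (fraction p) is
elevated alpha-fold, and rates are then renormalized so the grand mean is
exactly E(u) — the strata shift relative, not absolute, mutation mass, so
the closed-form expectations anchored to E(u) remain valid.  Planted CDN
sites multiply their rate by the scaled selective advantage w at cohort
simulation time.

Per patient and site, a mutation is a Bernoulli event with probability
u(l); above ~1e8 Bernoulli trials a per-site Poisson(n*u) draw assigned to
distinct random patients is used instead (a draw exceeding n is redrawn and
logged, keeping i <= n).  Defaults are exome-cohort scale: n = 1000,
L_S = 0.9e7, L_A = 2.07e7, E(u) = 3e-6, k = 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import MutationRecord
from .opportunity import BASES, SiteOpportunity

logger = logging.getLogger(__name__)

CLASS_NAMES = ("bulk", "cpg", "outlier", "cdn")
BULK, CPG, OUTLIER, CDN = range(4)

_FAST_MODE_TRIALS = 10 ** 8


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort; the seed is mandatory."""

    seed: int
    n: int = 1000
    L_S: int = 9_000_000
    L_A: int = 20_700_000
    E_u: float = 3e-6
    k: float = 1.0
    cpg_fraction: float = 0.065
    cpg_fold: float = 7.0
    outlier_p: float = 0.0
    outlier_alpha: float = 1.0
    cdn_sites: tuple[tuple[int, float], ...] = ()
    mode: str = "auto"

    def __post_init__(self):
        if self.n < 1 or self.L_S < 0 or self.L_A < 0 or self.L_S + self.L_A < 1:
            raise ValueError("need n >= 1 and at least one site")
        if not 0 <= self.cpg_fraction <= 1 or not 0 <= self.outlier_p < 1:
            raise ValueError("fractions must be in [0, 1]")
        if self.cpg_fold < 1 or self.outlier_alpha < 1:
            raise ValueError("rate multipliers must be >= 1")
        if self.E_u <= 0 or self.k <= 0:
            raise ValueError("E_u and k must be positive")
        if self.outlier_p * self.outlier_alpha * self.E_u * self.n >= 1:
            raise ValueError("outlier stratum saturates per-site hit probability "
                             "(p * alpha * n * E_u >= 1)")
        if self.mode not in ("auto", "bernoulli", "poisson"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for site, w in self.cdn_sites:
            if not self.L_S <= site < self.L_S + self.L_A:
                raise ValueError(f"planted CDN site {site} is not a missense site "
                                 f"(valid range [{self.L_S}, {self.L_S + self.L_A}))")
            if w < 1:
                raise ValueError("planted CDN advantage w must be >= 1")

    @property
    def L(self) -> int:
        return self.L_S + self.L_A


@dataclass
class SimTruth:
    """Ground truth: per-site rates, classes, alleles, and the planted CDN map."""

    rates: np.ndarray
    cls: np.ndarray                      # codes into CLASS_NAMES
    is_syn: np.ndarray
    cpg: np.ndarray
    ref: np.ndarray                      # base indices into BASES
    alt: np.ndarray
    cdn_w: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        idx = np.arange(len(self.rates))
        return pd.DataFrame({
            "chrom": "SIM1",
            "pos": idx + 1,
            "rate": self.rates,
            "class": np.array(CLASS_NAMES)[self.cls],
            "consequence": np.where(self.is_syn, "synonymous", "missense"),
            "cpg": self.cpg,
            "ref": np.array(list(BASES))[self.ref],
            "alt": np.array(list(BASES))[self.alt],
            "w": [self.cdn_w.get(int(i), 1.0) for i in idx],
        })


def _rngs(seed: int) -> tuple[np.random.Generator, ...]:
    ss = np.random.SeedSequence(seed)
    return tuple(np.random.default_rng(child) for child in ss.spawn(3))


def draw_site_rates(config: SimConfig) -> SimTruth:
    """Draw per-site rates and classes; deterministic per seed."""
    rng, _, _ = _rngs(config.seed)
    L = config.L
    rates = rng.gamma(shape=config.k, scale=config.E_u / config.k, size=L)
    cpg = rng.random(L) < config.cpg_fraction
    rates[cpg] *= config.cpg_fold
    cls = np.full(L, BULK, dtype=np.int8)
    cls[cpg] = CPG
    if config.outlier_p > 0:
        n_out = int(round(config.outlier_p * L))
        out_idx = rng.choice(L, size=n_out, replace=False)
        rates[out_idx] *= config.outlier_alpha
        cls[out_idx] = OUTLIER
    rates *= config.E_u / rates.mean()

    cdn_w = {int(site): float(w) for site, w in config.cdn_sites}
    for site in cdn_w:
        cls[site] = CDN
    is_syn = np.arange(L) < config.L_S
    ref = rng.integers(0, 4, size=L, dtype=np.int8)
    alt = ((ref + rng.integers(1, 4, size=L)) % 4).astype(np.int8)
    return SimTruth(rates=rates, cls=cls, is_syn=is_syn, cpg=cpg,
                    ref=ref, alt=alt, cdn_w=cdn_w)


def site_hit_counts(config: SimConfig, truth: SimTruth | None = None
                    ) -> tuple[np.ndarray, SimTruth]:
    """Number of patients hit per site (the spectrum-level view of a cohort)."""
    if truth is None:
        truth = draw_site_rates(config)
    _, rng, _ = _rngs(config.seed)
    u = truth.rates
    if truth.cdn_w:
        u = u.copy()
        for site, w in truth.cdn_w.items():
            u[site] *= w
    mode = config.mode
    if mode == "auto":
        mode = "poisson" if config.n * config.L > _FAST_MODE_TRIALS else "bernoulli"
    if mode == "bernoulli":
        counts = rng.binomial(config.n, np.clip(u, 0.0, 1.0))
    else:
        counts = rng.poisson(config.n * u)
        over = counts > config.n
        n_redraws = 0
        while over.any():
            n_redraws += int(over.sum())
            counts[over] = rng.poisson(config.n * u[over])
            over = counts > config.n
        if n_redraws:
            logger.info("site_hit_counts: redrew %d Poisson counts exceeding n", n_redraws)
    return counts.astype(np.int64), truth


def simulate_cohort(config: SimConfig) -> tuple[list[MutationRecord], SimTruth]:
    """Emit MAF-dialect records for one synthetic cohort, plus the truth table."""
    counts, truth = site_hit_counts(config)
    _, _, rng = _rngs(config.seed)
    records: list[MutationRecord] = []
    for site in np.flatnonzero(counts):
        c = int(counts[site])
        patients = rng.choice(config.n, size=c, replace=False)
        csq = "synonymous" if truth.is_syn[site] else "missense"
        for p in patients:
            records.append(MutationRecord(
                patient_id=f"P{int(p):06d}",
                chrom="SIM1",
                pos=int(site) + 1,
                ref=BASES[truth.ref[site]],
                alt=BASES[truth.alt[site]],
                gene=f"G{int(site) // 3000:05d}",
                consequence=csq,
            ))
    return records, truth


def tally_spectrum(counts: np.ndarray, is_syn: np.ndarray
                   ) -> tuple[dict[int, int], dict[int, int]]:
    """(A_i, S_i) maps from per-site hit counts (i >= 1 keys only)."""
    def spec(sel):
        binc = np.bincount(counts[sel])
        return {i: int(c) for i, c in enumerate(binc) if i >= 1 and c > 0}
    return spec(~is_syn), spec(is_syn)


def opportunity_from_truth(truth: SimTruth) -> SiteOpportunity:
    """Integer site opportunities matching a simulated cohort's design.

    Each simulated site counts as one site of its designated class, so
    spectrum closure is exact against the simulated coding space.
    """
    strata = {}
    for name, sel in (
        ("all", np.ones(len(truth.rates), dtype=bool)),
        ("cpg_removed", ~truth.cpg),
        ("cpg_only", truth.cpg),
    ):
        strata[name] = {
            "L": float(sel.sum()),
            "L_S": float((sel & truth.is_syn).sum()),
            "L_A": float((sel & ~truth.is_syn).sum()),
            "L_N": 0.0,
        }
    t = strata["all"]
    return SiteOpportunity(L=t["L"], L_S=t["L_S"], L_A=t["L_A"], L_N=0.0,
                           strata=strata, cpg_mask={"SIM1": truth.cpg},
                           analyzed={"SIM1": np.ones(len(truth.rates), dtype=bool)})


def write_truth(truth: SimTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)
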