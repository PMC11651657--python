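"""Mutation-path probabilities and site-opportunity counting.

The number of "synonymous sites" (L_S) or "missense sites" (L_A) in a coding
region is not a count of physical positions: each position has three possible
single-base changes, and each change is weighted by the relative probability
that an occurring mutation follows that base-to-base path.  The twelve path
probabilities R_{m>v} are calibrated on fourfold-degenerate third codon
positions, where every change is synonymous and therefore (to first order)
neutral.  For a coding region of length L,

    L_S = sum over positions l, alt bases v of  delta_syn(l, m>v) * R_{m>v}

and likewise for L_A (missense) and L_N (nonsense), so that
L_S + L_A + L_N = L exactly.

Classification is always codon-resolved: the same m>v change can be
synonymous in one codon and missense in another, so the delta is evaluated
per position against the standard genetic code (taken from Biopython's codon
table; the table is data, so alternate codes could be substituted).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

BASES = "ACGT"
_A, _C, _G, _T = 0, 1, 2, 3
#: the 12 ordered mutation paths m>v
PATHS: list[tuple[str, str]] = [(m, v) for m in BASES for v in BASES if m != v]

SYN, MIS, NON, _SKIP = 0, 1, 2, 3
STRATA = ("all", "cpg_removed", "cpg_only")


def _codon_aa() -> dict[str, str]:
    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


CODON_TO_AA = _codon_aa()


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-codon lookup tables.

    cls[c, p, a]  : class of changing position p of codon index c to base a
                    (SYN/MIS/NON; _SKIP when a is the reference base or the
                    reference codon is a stop).
    is_stop[c]    : reference codon is a stop codon.
    fourfold[c]   : third position of codon c is fourfold degenerate.
    """
    cls = np.full((64, 3, 4), _SKIP, dtype=np.int8)
    is_stop = np.zeros(64, dtype=bool)
    fourfold = np.zeros(64, dtype=bool)
    for c in range(64):
        codon = BASES[(c >> 4) & 3] + BASES[(c >> 2) & 3] + BASES[c & 3]
        aa = CODON_TO_AA[codon]
        if aa == "*":
            is_stop[c] = True
            continue
        for p in range(3):
            for a, base in enumerate(BASES):
                if base == codon[p]:
                    continue
                alt_aa = CODON_TO_AA[codon[:p] + base + codon[p + 1:]]
                if alt_aa == aa:
                    cls[c, p, a] = SYN
                elif alt_aa == "*":
                    cls[c, p, a] = NON
                else:
                    cls[c, p, a] = MIS
        fourfold[c] = all(
            cls[c, 2, a] in (SYN, _SKIP) for a in range(4)
        )
    return cls, is_stop, fourfold


_CLS, _IS_STOP, _FOURFOLD = _build_tables()

_DECODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _DECODE[ord(_b)] = _i
    _DECODE[ord(_b.lower())] = _i


def _encode(seq: str, name: str = "") -> np.ndarray:
    b = _DECODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (b == 255).any():
        bad = seq[int(np.argmax(b == 255))]
        raise ValueError(f"non-ACGT base {bad!r} in sequence {name!r}")
    return b


def read_cds_fasta(path) -> dict[str, str]:
    """Read framed coding sequences (frame starts at position 1 of each record)."""
    cds = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS {rec.id!r} length {len(seq)} is not a multiple of 3")
        cds[rec.id] = seq
    if not cds:
        raise ValueError(f"no FASTA records in {path}")
    return cds


@dataclass(frozen=True)
class PathProbabilities:
    """Normalized probabilities of the 12 single-base mutation paths.

    R sums to one over the 12 ordered paths; N holds the fourfold-site counts
    per reference base and n_obs the observed fourfold-site mutation tallies
    used for calibration.
    """

    R: dict[tuple[str, str], float]
    N: dict[str, int] = field(default_factory=dict)
    n_obs: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.R.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"path probabilities sum to {total!r}, expected 1")
        if any(v < 0 for v in self.R.values()):
            raise ValueError("negative path probability")

    @classmethod
    def uniform(cls) -> "PathProbabilities":
        return cls(R={p: 1.0 / 12 for p in PATHS})

    @property
    def matrix(self) -> np.ndarray:
        """4x4 matrix R[m, v] indexed by A,C,G,T; zero on the diagonal."""
        mat = np.zeros((4, 4))
        for (m, v), r in self.R.items():
            mat[BASES.index(m), BASES.index(v)] = r
        return mat


def fourfold_sites(cds_set: Mapping[str, str]) -> dict[str, np.ndarray]:
    """1-based positions of fourfold-degenerate third codon positions."""
    out = {}
    for name, seq in cds_set.items():
        b = _encode(seq, name)
        cidx = b[0::3].astype(np.int32) * 16 + b[1::3] * 4 + b[2::3]
        ff = _FOURFOLD[cidx]
        out[name] = (np.flatnonzero(ff) * 3 + 3).astype(np.int64)
    return out


def fourfold_path_probs(cds_set: Mapping[str, str], records: Iterable) -> PathProbabilities:
    """Calibrate R_{m>v} from mutations observed at fourfold-degenerate sites.

    ``records`` carry CDS-relative 1-based coordinates (``chrom`` names a CDS
    in ``cds_set``).  Records outside fourfold positions are ignored with a
    logged count; a record whose ref allele disagrees with the sequence is an
    error.
    """
    ff = fourfold_sites(cds_set)
    ff_lookup = {name: set(pos.tolist()) for name, pos in ff.items()}
    N = dict.fromkeys(BASES, 0)
    for name, positions in ff.items():
        seq = cds_set[name]
        for p in positions:
            N[seq[p - 1]] += 1
    if sum(N.values()) == 0:
        raise ValueError("no fourfold-degenerate sites in the CDS set; cannot calibrate")

    n_obs = dict.fromkeys(PATHS, 0)
    n_ignored = 0
    for rec in records:
        sites = ff_lookup.get(rec.chrom)
        if sites is None or rec.pos not in sites:
            n_ignored += 1
            continue
        ref_here = cds_set[rec.chrom][rec.pos - 1]
        if ref_here != rec.ref:
            raise ValueError(
                f"record ref {rec.ref} at {rec.chrom}:{rec.pos} does not match CDS base {ref_here}"
            )
        n_obs[(rec.ref, rec.alt)] += 1
    if n_ignored:
        logger.info("fourfold_path_probs: ignored %d records off fourfold sites", n_ignored)
    if sum(n_obs.values()) == 0:
        raise ValueError("no mutations at fourfold-degenerate sites; cannot calibrate")

    r = {}
    for (m, v) in PATHS:
        if N[m] == 0:
            if n_obs[(m, v)]:
                logger.warning("path %s>%s observed but no fourfold sites with ref %s", m, v, m)
            r[(m, v)] = 0.0
        else:
            r[(m, v)] = n_obs[(m, v)] / N[m]
    total = sum(r.values())
    R = {p: val / total for p, val in r.items()}
    return PathProbabilities(R=R, N=N, n_obs=n_obs)


@dataclass
class SiteOpportunity:
    """Weighted site numbers for a coding region, stratified by CpG context.

    ``strata`` maps each of all / cpg_removed / cpg_only to a dict with keys
    L, L_S, L_A, L_N.  ``cpg_mask`` and ``analyzed`` are per-CDS boolean
    arrays (0-based positions); positions in stop codons are not analyzed.
    """

    L: float
    L_S: float
    L_A: float
    L_N: float
    strata: dict[str, dict[str, float]]
    cpg_mask: dict[str, np.ndarray] = field(default_factory=dict)
    analyzed: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.L > 0 and abs(self.L_S + self.L_A + self.L_N - self.L) > 1e-6 * self.L:
            raise ValueError("L_S + L_A + L_N does not equal L")

    @classmethod
    def from_totals(cls, L_S: float, L_A: float, L_N: float = 0.0,
                    strata: dict | None = None) -> "SiteOpportunity":
        L = L_S + L_A + L_N
        if strata is None:
            strata = {"all": {"L": L, "L_S": L_S, "L_A": L_A, "L_N": L_N}}
        return cls(L=L, L_S=L_S, L_A=L_A, L_N=L_N, strata=strata)

    def for_stratum(self, stratum: str = "all") -> tuple[float, float]:
        """(L_S, L_A) for one CpG stratum."""
        if stratum not in self.strata:
            raise KeyError(f"stratum {stratum!r} not available (have {sorted(self.strata)})")
        s = self.strata[stratum]
        return s["L_S"], s["L_A"]

    def is_cpg(self, chrom: str, pos: int) -> bool:
        """CpG flag for a 1-based CDS position."""
        mask = self.cpg_mask.get(chrom)
        if mask is None:
            raise KeyError(f"no CpG mask for {chrom!r}")
        return bool(mask[pos - 1])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stratum": name, **vals} for name, vals in self.strata.items()
        ]
        return pd.DataFrame(rows, columns=["stratum", "L", "L_S", "L_A", "L_N"])


def _position_masses(cds_set: Mapping[str, str], R: PathProbabilities):
    """Per-CDS arrays: base index, class-specific path mass, analyzed and CpG flags.

    Path mass is conditioned on the position's reference base (each row of R
    renormalized to 1), the standard single-base site-counting convention:
    every analyzed position then distributes exactly one site among the
    synonymous/missense/nonsense classes, so L_S + L_A + L_N = L.  Positions
    whose reference base has zero total path probability cannot be
    apportioned and are dropped from the analysis with a warning.
    """
    Rmat = R.matrix
    row_sums = Rmat.sum(axis=1)
    ok_rows = row_sums > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        Rcond = np.where(ok_rows[:, None], Rmat / np.where(ok_rows, row_sums, 1.0)[:, None], 0.0)
    if not ok_rows.all():
        missing = [BASES[i] for i in np.flatnonzero(~ok_rows)]
        logger.warning(
            "_position_masses: reference base(s) %s have zero path probability; "
            "their positions are excluded", ",".join(missing))
    for name, seq in cds_set.items():
        b = _encode(seq, name)
        L = len(b)
        cidx = b[0::3].astype(np.int32) * 16 + b[1::3] * 4 + b[2::3]
        stop = _IS_STOP[cidx]
        if stop[:-1].any():
            logger.warning(
                "CDS %r: %d internal stop codon(s) skipped", name, int(stop[:-1].sum())
            )
        analyzed_codon = ~stop
        analyzed = np.repeat(analyzed_codon, 3) & ok_rows[b]

        mass = {SYN: np.zeros(L), MIS: np.zeros(L), NON: np.zeros(L)}
        for p in range(3):
            cls_p = _CLS[cidx, p, :]            # (ncodon, 4)
            w = Rcond[b[p::3], :]               # (ncodon, 4)
            for klass in (SYN, MIS, NON):
                mass[klass][p::3] = ((cls_p == klass) * w).sum(axis=1)
        for klass in mass:
            mass[klass][~analyzed] = 0.0

        cpg = np.zeros(L, dtype=bool)
        cpg[:-1] |= (b[:-1] == _C) & (b[1:] == _G)
        cpg[1:] |= (b[1:] == _G) & (b[:-1] == _C)
        yield name, b, mass, analyzed, cpg


def count_sites(cds_set: Mapping[str, str], R: PathProbabilities) -> SiteOpportunity:
    """Compute L_S / L_A / L_N by weighting every possible codon change with R.

    A position's reference dinucleotide context sets its CpG flag (the C or
    the G of a CG dinucleotide, covering both strands).  Stop-codon positions
    (including the terminal stop) are excluded from L; an internal stop is
    additionally warned about.
    """
    totals = {name: {"L": 0.0, "L_S": 0.0, "L_A": 0.0, "L_N": 0.0} for name in STRATA}
    cpg_masks: dict[str, np.ndarray] = {}
    analyzed_masks: dict[str, np.ndarray] = {}
    for name, b, mass, analyzed, cpg in _position_masses(cds_set, R):
        cpg_masks[name] = cpg
        analyzed_masks[name] = analyzed
        for stratum, sel in (
            ("all", analyzed),
            ("cpg_removed", analyzed & ~cpg),
            ("cpg_only", analyzed & cpg),
        ):
            totals[stratum]["L"] += float(sel.sum())
            totals[stratum]["L_S"] += float(mass[SYN][sel].sum())
            totals[stratum]["L_A"] += float(mass[MIS][sel].sum())
            totals[stratum]["L_N"] += float(mass[NON][sel].sum())
    t = totals["all"]
    return SiteOpportunity(
        L=t["L"], L_S=t["L_S"], L_A=t["L_A"], L_N=t["L_N"],
        strata=totals, cpg_mask=cpg_masks, analyzed=analyzed_masks,
    )


@dataclass
class MotifOpportunity:
    """Per-motif site numbers for k-mer contexts centered on the mutated base.

    For k in {3, 5} the basis is synonymous path mass only (L_{c,S}); for
    k = 7 it is the combined synonymous + missense mass (L_c), matching the
    use of all singleton mutations as the rate reference at that length.
    Positions within k//2 of a CDS edge carry no full context and are
    excluded here (but retained in L_S / L_A).
    """

    k: int
    table: dict[str, float]
    basis: str

    def site_number(self, motif: str) -> float:
        return self.table.get(motif, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.table.items()), columns=["motif", "site_number"]
        )


def motif_site_counts(cds_set: Mapping[str, str], R: PathProbabilities, k: int) -> MotifOpportunity:
    if k not in (3, 5, 7):
        raise ValueError(f"motif length k must be 3, 5 or 7, got {k}")
    h = k // 2
    nmotif = 4 ** k
    acc = np.zeros(nmotif)
    for name, b, mass, analyzed, _cpg in _position_masses(cds_set, R):
        L = len(b)
        if L < k:
            continue
        if k == 7:
            w = mass[SYN] + mass[MIS]
            basis = "all-singleton"
        else:
            w = mass[SYN]
            basis = "synonymous"
        ids = np.zeros(L - 2 * h, dtype=np.int64)
        for j in range(k):
            ids = ids * 4 + b[j:L - 2 * h + j]
        valid = analyzed[h:L - h]
        acc += np.bincount(ids[valid], weights=w[h:L - h][valid], minlength=nmotif)
    table = {}
    nz = np.flatnonzero(acc)
    digits = np.array(list(BASES))
    for idx in nz:
        motif = ""
        v = int(idx)
        for _ in range(k):
            motif = digits[v & 3] + motif
            v >>= 2
        table[motif] = float(acc[idx])
    basis = "all-singleton" if k == 7 else "synonymous"
    return MotifOpportunity(k=k, table=table, basis=basis)


def write_opportunity_tsv(op: SiteOpportunity, path) -> None:
    op.to_frame().to_csv(path, sep="\t", index=False)


def read_opportunity_tsv(path) -> SiteOpportunity:
    df = pd.read_csv(path, sep="\t")
    strata = {
        row["stratum"]: {k: float(row[k]) for k in ("L", "L_S", "L_A", "L_N")}
        for _, row in df.iterrows()
    }
    t = strata["all"]
    return SiteOpportunity(
        L=t["L"], L_S=t["L_S"], L_A=t["L_A"], L_N=t["L_N"], strata=strata
    )
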