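"""Somatic mutation cohorts: ingestion, filtering, and recurrence spectra.

The central summary is the recurrence spectrum: A_i counts missense sites at
which the identical nucleotide change (same position, same ref>alt) is seen
in exactly i distinct patients, S_i the synonymous analogue.  The recurrence
key is (chrom, pos, ref, alt) — two different alt alleles at one position
are two sites.  Each patient contributes at most once per key, so i <= n
always holds.  A_0 and S_0 close the spectrum against the site opportunity:
A_0 = L_A - sum_{i>=1} A_i.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .opportunity import SiteOpportunity

logger = logging.getLogger(__name__)

CONSEQUENCES = ("synonymous", "missense", "nonsense")

#: canonical MAF-subset column roles
CANONICAL_DIALECT = {
    "patient": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "gene": "Hugo_Symbol",
    "consequence": "Variant_Classification",
}

_CONSEQUENCE_ALIASES = {
    "missense_mutation": "missense",
    "missense": "missense",
    "missense_variant": "missense",
    "silent": "synonymous",
    "synonymous": "synonymous",
    "synonymous_variant": "synonymous",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "stop_gained": "nonsense",
}


@dataclass(frozen=True)
class MutationRecord:
    """One somatic substitution observed in one patient.

    Coordinates are 1-based forward strand; the reader never
    reverse-complements.  ``pop_freq`` is the germline population frequency
    annotation (maximum over sub-populations when several are supplied).
    """

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "missense"
    pop_freq: float | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in "ACGT" or len(self.ref) != 1:
            raise ValueError(f"ref must be a single A/C/G/T, got {self.ref!r}")
        if self.alt not in "ACGT" or len(self.alt) != 1:
            raise ValueError(f"alt must be a single A/C/G/T, got {self.alt!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"consequence must be one of {CONSEQUENCES}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PatientLoad:
    """Coding mutation load (missense + nonsense + synonymous) of one patient."""

    patient_id: str
    load: int
    scaled_load: float | None = None
    zscore: float | None = None


def read_mutations(path, dialect: Mapping[str, object] | None = None,
                   rejects: list | None = None) -> list[MutationRecord]:
    """Read a MAF-subset TSV into records.

    ``dialect`` maps the roles patient/chrom/pos/ref/alt/gene/consequence
    (and optionally pop_freq, a column name or list of column names) onto the
    file's headers; unmapped roles use the canonical MAF names.  Rows whose
    consequence is outside the three-value set are skipped with a logged
    count; rows with non-ACGT alleles are collected into ``rejects`` when a
    list is given.
    """
    roles = dict(CANONICAL_DIALECT)
    if dialect:
        roles.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for role in ("patient", "chrom", "pos", "ref", "alt", "consequence"):
        col = roles[role]
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} (role {role!r})")
    freq_cols = roles.get("pop_freq")
    if isinstance(freq_cols, str):
        freq_cols = [freq_cols]
    if freq_cols:
        for col in freq_cols:
            if col not in df.columns:
                raise ValueError(f"missing population-frequency column {col!r}")

    records: list[MutationRecord] = []
    n_skipped_consequence = 0
    n_rejected = 0
    gene_col = roles.get("gene")
    has_gene = gene_col in df.columns
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        csq = _CONSEQUENCE_ALIASES.get(str(row[roles["consequence"]]).strip().lower())
        if csq is None:
            n_skipped_consequence += 1
            continue
        pop_freq = None
        if freq_cols:
            vals = [float(row[c]) for c in freq_cols if pd.notna(row[c]) and str(row[c]) != ""]
            if vals:
                pop_freq = max(vals)
        try:
            records.append(MutationRecord(
                patient_id=str(row[roles["patient"]]),
                chrom=str(row[roles["chrom"]]),
                pos=int(row[roles["pos"]]),
                ref=str(row[roles["ref"]]).upper(),
                alt=str(row[roles["alt"]]).upper(),
                gene=str(row[gene_col]) if has_gene and pd.notna(row.get(gene_col)) else "",
                consequence=csq,
                pop_freq=pop_freq,
            ))
        except ValueError as err:
            n_rejected += 1
            if rejects is not None:
                rejects.append({**row, "reason": str(err)})
    if n_skipped_consequence:
        logger.info("read_mutations: skipped %d rows with out-of-scope consequence",
                    n_skipped_consequence)
    if n_rejected:
        logger.warning("read_mutations: rejected %d malformed rows", n_rejected)
    return records


def write_rejects(rejects: Sequence[Mapping], path) -> None:
    pd.DataFrame(list(rejects)).to_csv(path, sep="\t", index=False)


def write_cohort_tsv(records: Iterable[MutationRecord], path) -> None:
    rows = [{
        "Tumor_Sample_Barcode": r.patient_id, "Chromosome": r.chrom,
        "Start_Position": r.pos, "Reference_Allele": r.ref,
        "Tumor_Seq_Allele2": r.alt, "Hugo_Symbol": r.gene,
        "Variant_Classification": r.consequence,
    } for r in records]
    pd.DataFrame(rows, columns=list(CANONICAL_DIALECT.values())).to_csv(
        path, sep="\t", index=False)


def filter_cohort(records: Sequence[MutationRecord],
                  max_pop_freq: float = 0.001,
                  max_load: float = 3000,
                  ) -> tuple[list[MutationRecord], list[PatientLoad], list[str]]:
    """Germline filter then hypermutator exclusion.

    Records with pop_freq above ``max_pop_freq`` are removed first (records
    without an annotation pass).  Patient loads are computed on the survivors
    and patients whose load exceeds ``max_load`` (the mutator-phenotype
    cutoff, default 3000 coding mutations) are excluded entirely.
    """
    somatic = [r for r in records if r.pop_freq is None or r.pop_freq <= max_pop_freq]
    load_by_patient = Counter(r.patient_id for r in somatic)
    excluded = sorted(p for p, n in load_by_patient.items() if n > max_load)
    excluded_set = set(excluded)
    kept = [r for r in somatic if r.patient_id not in excluded_set]
    loads = [PatientLoad(patient_id=p, load=n)
             for p, n in sorted(load_by_patient.items()) if p not in excluded_set]
    return kept, loads, excluded


def scale_panel_load(n_l: float, l: float, L: float) -> float:
    """Scale a targeted-panel mutation load to whole-exome scale: n_l * L / l."""
    if l <= 0:
        raise ValueError(f"covered length l must be positive, got {l}")
    if L < l:
        raise ValueError(f"whole-coding length L ({L}) must be >= covered length l ({l})")
    return n_l * L / l


def load_zscores(loads: Sequence[PatientLoad],
                 grouping: Mapping[str, str] | None = None) -> list[PatientLoad]:
    """Standardize loads within cohorts: z = (load - group mean) / group SD.

    The SD convention is the sample SD (ddof=1).  Groups with fewer than two
    patients or zero SD are flagged in the log and get z = 0.
    """
    groups: dict[str, list[PatientLoad]] = defaultdict(list)
    for pl in loads:
        label = grouping[pl.patient_id] if grouping else "all"
        groups[label].append(pl)
    for label, members in groups.items():
        vals = np.array([m.load for m in members], dtype=float)
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        if sd == 0.0:
            logger.warning("load_zscores: group %r has zero SD; z-scores set to 0", label)
            for m in members:
                m.zscore = 0.0
        else:
            mean = vals.mean()
            for m in members:
                m.zscore = (m.load - mean) / sd
    return list(loads)


def recurrence_counts(records: Iterable[MutationRecord], per_site: bool = False
                      ) -> dict[tuple, tuple[int, str]]:
    """Map each recurrence key to (number of distinct patients, consequence).

    Duplicated calls from one patient count once.  ``per_site=True`` keys by
    (chrom, pos) irrespective of the alt allele (non-default diagnostic mode).
    """
    patients: dict[tuple, set] = defaultdict(set)
    consequences: dict[tuple, Counter] = defaultdict(Counter)
    for r in records:
        key = (r.chrom, r.pos) if per_site else r.key
        patients[key].add(r.patient_id)
        consequences[key][r.consequence] += 1
    out = {}
    for key, pats in patients.items():
        csq_counter = consequences[key]
        if len(csq_counter) > 1:
            logger.warning("recurrence_counts: conflicting consequences at %s: %s",
                           key, dict(csq_counter))
        # majority vote with a deterministic (alphabetical) tie-break
        winner = max(sorted(csq_counter), key=lambda c: csq_counter[c])
        out[key] = (len(pats), winner)
    return out


@dataclass
class RecurrenceSpectrum:
    """Counts of sites hit in exactly i patients, split by consequence.

    ``a`` maps i -> A_i (missense), ``s`` maps i -> S_i (synonymous);
    nonsense sites are tallied in a parallel map and excluded from A_i unless
    the spectrum was built with ``merge_nonsense=True``.  a0/s0 close the
    spectrum against the opportunity used to build it.
    """

    n: int
    a: dict[int, int]
    s: dict[int, int]
    a0: float
    s0: float
    stratum: str = "all"
    nonsense: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        for d in (self.a, self.s, self.nonsense):
            for i, c in d.items():
                if i < 1 or c < 0:
                    raise ValueError("spectrum counts must have i >= 1 and count >= 0")
                if i > self.n:
                    raise ValueError(f"recurrence {i} exceeds cohort size {self.n}")
        if self.a0 < 0 or self.s0 < 0:
            raise ValueError("closure produced a negative A_0 or S_0")

    @classmethod
    def from_counts(cls, n: int, a: Mapping[int, int], s: Mapping[int, int],
                    L_A: float, L_S: float, stratum: str = "all",
                    nonsense: Mapping[int, int] | None = None) -> "RecurrenceSpectrum":
        return cls(n=n, a=dict(a), s=dict(s),
                   a0=L_A - sum(a.values()), s0=L_S - sum(s.values()),
                   stratum=stratum, nonsense=dict(nonsense or {}))

    @property
    def max_i(self) -> int:
        keys = list(self.a) + list(self.s) + list(self.nonsense)
        return max(keys) if keys else 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"i": 0, "A_i": self.a0, "S_i": self.s0,
                 "ratio": self.a0 / self.s0 if self.s0 else np.nan}]
        for i in range(1, self.max_i + 1):
            ai, si = self.a.get(i, 0), self.s.get(i, 0)
            rows.append({"i": i, "A_i": ai, "S_i": si,
                         "ratio": ai / si if si else np.nan})
        df = pd.DataFrame(rows)
        df.insert(0, "stratum", self.stratum)
        return df


def build_spectrum(records: Iterable[MutationRecord],
                   opportunity: SiteOpportunity,
                   stratum: str = "all",
                   *,
                   n: int | None = None,
                   merge_nonsense: bool = False,
                   per_site: bool = False) -> RecurrenceSpectrum:
    """Build the recurrence spectrum of a filtered cohort.

    ``stratum`` selects all sites, CpG sites only, or CpG sites removed
    (the latter two need a CpG mask on the opportunity).  ``merge_nonsense``
    folds nonsense sites into A_i for a combined "nonsynonymous" reading.
    """
    records = list(records)
    counts = recurrence_counts(records, per_site=per_site)
    if stratum not in ("all", "cpg_removed", "cpg_only"):
        raise ValueError(f"unknown stratum {stratum!r}")
    if n is None:
        n = len({r.patient_id for r in records})
        if n == 0:
            raise ValueError("empty cohort: pass n explicitly to build an empty spectrum")

    a: Counter = Counter()
    s: Counter = Counter()
    x: Counter = Counter()
    for key, (i, csq) in counts.items():
        if stratum != "all":
            chrom, pos = key[0], key[1]
            cpg = opportunity.is_cpg(chrom, pos)
            if stratum == "cpg_removed" and cpg:
                continue
            if stratum == "cpg_only" and not cpg:
                continue
        if csq == "synonymous":
            s[i] += 1
        elif csq == "missense":
            a[i] += 1
        else:
            x[i] += 1
            if merge_nonsense:
                a[i] += 1
    L_S, L_A = opportunity.for_stratum(stratum)
    if sum(a.values()) > L_A:
        raise ValueError(
            f"sum A_i = {sum(a.values())} exceeds L_A = {L_A}: opportunity does not "
            "match the cohort's coding space")
    if sum(s.values()) > L_S:
        raise ValueError(
            f"sum S_i = {sum(s.values())} exceeds L_S = {L_S}: opportunity does not "
            "match the cohort's coding space")
    return RecurrenceSpectrum.from_counts(
        n=n, a=dict(a), s=dict(s), L_A=L_A, L_S=L_S, stratum=stratum,
        nonsense=dict(x))


@dataclass(frozen=True)
class RatioResult:
    """An A/S ratio over one recurrence bin; undefined when S = 0."""

    A: float
    S: float

    @property
    def undefined(self) -> bool:
        return self.S == 0

    @property
    def ratio(self) -> float | None:
        return None if self.undefined else self.A / self.S


def as_ratio(spectrum: RecurrenceSpectrum,
             bins: Sequence[tuple[int, int | None]]) -> dict[tuple, RatioResult]:
    """A/S ratios over i-bins; a bin is (lo, hi) inclusive, hi=None meaning >= lo.

    The ratio measures selection strength; when the synonymous denominator is
    empty the pair (A, 0) is returned flagged as undefined rather than a
    number.
    """
    seen: set = set()
    open_lo: int | None = None
    out = {}
    for lo, hi in bins:
        if lo < 0 or (hi is not None and hi < lo):
            raise ValueError(f"bad bin ({lo}, {hi})")
        top = max(spectrum.max_i, lo) if hi is None else hi
        span = set(range(lo, top + 1))
        overlap = span & seen or (open_lo is not None and top >= open_lo)
        if overlap:
            raise ValueError("bins must be disjoint")
        seen |= span
        if hi is None:
            open_lo = lo if open_lo is None else min(open_lo, lo)
        A = S = 0.0
        for i in range(lo, top + 1):
            if i == 0:
                A += spectrum.a0
                S += spectrum.s0
            else:
                A += spectrum.a.get(i, 0)
                S += spectrum.s.get(i, 0)
        out[(lo, hi)] = RatioResult(A=A, S=S)
    return out


def spectrum_table(spectra: Sequence[RecurrenceSpectrum]) -> pd.DataFrame:
    """Stack spectra (one per stratum) into one table for TSV output."""
    return pd.concat([sp.to_frame() for sp in spectra], ignore_index=True)
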