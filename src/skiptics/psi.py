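"""Percent-spliced-in (PSI) quantification from splice-junction read counts.

For an exon, the 3'PSI (acceptor-side) and 5'PSI (donor-side) inclusion
fractions are

    psi3 = I3 / (I3 + E)        psi5 = I5 / (I5 + E)

where ``I3`` is the read total of junctions splicing directly into the exon's
acceptor splice site, ``I5`` the total splicing out of its donor site, and
``E`` the total of junctions that skip the exon entirely (start strictly
before the exon start and end strictly after the exon end, on the same
strand). Junctions touching an exon boundary are inclusion evidence, never
exclusion. The combined ``psi`` is the arithmetic mean of the defined
per-site values; both per-site values are always retained.

Strand convention: on '+', the acceptor is the exon's lower-coordinate
boundary; on '-', the acceptor is the higher-coordinate boundary, so a
junction whose genomic *start* equals the exon *end* splices into a
'-'-strand exon's acceptor.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError
from .junction_io import ExonRecord, SpliceJunction

#: Default coverage gate: informative reads required at each splice site.
DEFAULT_MIN_READS = 10

Aggregator = Literal["pooled", "mean"]


@dataclass(frozen=True, slots=True)
class PsiEstimate:
    """Per-exon, per-sample inclusion estimate with coverage gating.

    ``psi3``/``psi5``/``psi`` are ``None`` when their denominator is zero.
    ``covered`` is True when both sites reach the informative-read threshold,
    i.e. ``I3 + E >= min_reads`` and ``I5 + E >= min_reads``.
    """

    exon_id: str
    sample_id: str
    inclusion_reads_3ss: int
    inclusion_reads_5ss: int
    exclusion_reads: int
    psi3: float | None
    psi5: float | None
    psi: float | None
    covered: bool


@dataclass(frozen=True, slots=True)
class DeltaPsiRecord:
    """Treated-minus-control PSI difference for one exon.

    ``delta_psi`` is defined only when both conditions are covered and have a
    defined PSI; otherwise it is ``None`` and ``covered_both`` is False.
    """

    exon_id: str
    psi_control: float | None
    psi_treated: float | None
    delta_psi: float | None
    covered_both: bool


class JunctionIndex:
    """Constant-time junction lookups for one sample.

    Supports (a) total reads of junctions ending at an acceptor coordinate,
    (b) total reads of junctions starting at a donor coordinate, and (c) total
    reads of junctions strictly spanning an interval; all strand-aware.
    Duplicate identical intervals are merged by summing reads, with a warning.
    """

    def __init__(self, junctions: Iterable[SpliceJunction]):
        junctions = list(junctions)
        sample_ids = {j.sample_id for j in junctions}
        if len(sample_ids) > 1:
            raise DataError(
                f"JunctionIndex expects junctions from one sample, got "
                f"{sorted(sample_ids)}"
            )
        self.sample_id = next(iter(sample_ids)) if sample_ids else ""

        merged: dict[tuple[str, int, int, str], int] = {}
        duplicates = 0
        for j in junctions:
            if j.interval in merged:
                duplicates += 1
            merged[j.interval] = merged.get(j.interval, 0) + j.reads
        if duplicates:
            warnings.warn(
                f"{duplicates} duplicate junction interval(s) merged by "
                f"summing read counts",
                stacklevel=2,
            )

        self._by_end: dict[tuple[str, str, int], int] = defaultdict(int)
        self._by_start: dict[tuple[str, str, int], int] = defaultdict(int)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for (chrom, start, end, strand), reads in merged.items():
            self._by_end[(chrom, strand, end)] += reads
            self._by_start[(chrom, strand, start)] += reads
            self._trees[chrom].addi(start, end, (strand, reads))
        self.n_junctions = len(merged)

    def reads_ending_at(
        self, chrom: str, pos: int, strand: str, include_unstranded: bool = False
    ) -> int:
        total = self._by_end.get((chrom, strand, pos), 0)
        if include_unstranded and strand != ".":
            total += self._by_end.get((chrom, ".", pos), 0)
        return total

    def reads_starting_at(
        self, chrom: str, pos: int, strand: str, include_unstranded: bool = False
    ) -> int:
        total = self._by_start.get((chrom, strand, pos), 0)
        if include_unstranded and strand != ".":
            total += self._by_start.get((chrom, ".", pos), 0)
        return total

    def reads_spanning(
        self,
        chrom: str,
        start: int,
        end: int,
        strand: str,
        include_unstranded: bool = False,
    ) -> int:
        """Total reads of junctions with begin < start and end > end."""
        tree = self._trees.get(chrom)
        if tree is None:
            return 0
        total = 0
        for iv in tree.overlap(start, end):
            if iv.begin < start and iv.end > end:
                j_strand, reads = iv.data
                if j_strand == strand or (include_unstranded and j_strand == "."):
                    total += reads
        return total


def index_junctions(junctions: Iterable[SpliceJunction]) -> JunctionIndex:
    """Build a :class:`JunctionIndex` over one sample's junctions."""
    return JunctionIndex(junctions)


def compute_psi(
    exon: ExonRecord,
    index: JunctionIndex,
    min_reads: int = DEFAULT_MIN_READS,
    include_unstranded: bool = False,
) -> PsiEstimate:
    """Compute the 3'/5'/combined PSI of one exon in one sample.

    With ``include_unstranded=True``, junctions with '.' strand also count
    toward an exon on either strand; by default they are excluded.
    """
    if exon.strand == "+":
        i3 = index.reads_ending_at(exon.chrom, exon.start, "+", include_unstranded)
        i5 = index.reads_starting_at(exon.chrom, exon.end, "+", include_unstranded)
    else:
        i3 = index.reads_starting_at(exon.chrom, exon.end, "-", include_unstranded)
        i5 = index.reads_ending_at(exon.chrom, exon.start, "-", include_unstranded)
    excl = index.reads_spanning(
        exon.chrom, exon.start, exon.end, exon.strand, include_unstranded
    )
    psi3 = i3 / (i3 + excl) if (i3 + excl) > 0 else None
    psi5 = i5 / (i5 + excl) if (i5 + excl) > 0 else None
    defined = [v for v in (psi3, psi5) if v is not None]
    psi = sum(defined) / len(defined) if defined else None
    covered = (i3 + excl) >= min_reads and (i5 + excl) >= min_reads
    return PsiEstimate(
        exon_id=exon.exon_id,
        sample_id=index.sample_id,
        inclusion_reads_3ss=i3,
        inclusion_reads_5ss=i5,
        exclusion_reads=excl,
        psi3=psi3,
        psi5=psi5,
        psi=psi,
        covered=covered,
    )


def psi_matrix(
    exons: Iterable[ExonRecord],
    samples: Mapping[str, JunctionIndex],
    min_reads: int = DEFAULT_MIN_READS,
    include_unstranded: bool = False,
) -> list[PsiEstimate]:
    """One PsiEstimate per (exon, sample), in deterministic row order.

    Rows are ordered by (chrom, start, exon_id, sample_id). Exons on contigs
    absent from a sample's junctions get undefined PSI with covered=False.
    """
    ordered_exons = sorted(exons, key=lambda e: (e.chrom, e.start, e.exon_id))
    estimates: list[PsiEstimate] = []
    for exon in ordered_exons:
        for sample_id in sorted(samples):
            index = samples[sample_id]
            est = compute_psi(exon, index, min_reads, include_unstranded)
            if est.sample_id != sample_id:
                # empty index carries no sample label of its own
                est = PsiEstimate(
                    exon_id=est.exon_id,
                    sample_id=sample_id,
                    inclusion_reads_3ss=est.inclusion_reads_3ss,
                    inclusion_reads_5ss=est.inclusion_reads_5ss,
                    exclusion_reads=est.exclusion_reads,
                    psi3=est.psi3,
                    psi5=est.psi5,
                    psi=est.psi,
                    covered=est.covered,
                )
            estimates.append(est)
    return estimates


@dataclass(frozen=True, slots=True)
class _Aggregate:
    psi: float | None
    covered: bool
    i3: int
    i5: int
    excl: int


def _aggregate(
    estimates: Iterable[PsiEstimate],
    method: Aggregator,
    min_reads: int,
) -> dict[str, _Aggregate]:
    by_exon: dict[str, list[PsiEstimate]] = defaultdict(list)
    for est in estimates:
        by_exon[est.exon_id].append(est)
    out: dict[str, _Aggregate] = {}
    for exon_id, ests in by_exon.items():
        i3 = sum(e.inclusion_reads_3ss for e in ests)
        i5 = sum(e.inclusion_reads_5ss for e in ests)
        excl = sum(e.exclusion_reads for e in ests)
        if method == "pooled":
            psi3 = i3 / (i3 + excl) if (i3 + excl) > 0 else None
            psi5 = i5 / (i5 + excl) if (i5 + excl) > 0 else None
            defined = [v for v in (psi3, psi5) if v is not None]
            psi = sum(defined) / len(defined) if defined else None
            covered = (i3 + excl) >= min_reads and (i5 + excl) >= min_reads
        elif method == "mean":
            defined = [e.psi for e in ests if e.psi is not None]
            psi = sum(defined) / len(defined) if defined else None
            covered = any(e.covered for e in ests)
        else:
            raise ValueError(f"unknown aggregator {method!r}")
        out[exon_id] = _Aggregate(psi=psi, covered=covered, i3=i3, i5=i5, excl=excl)
    return out


def delta_psi(
    psi_control: Iterable[PsiEstimate],
    psi_treated: Iterable[PsiEstimate],
    aggregator: Aggregator = "pooled",
    min_reads: int = DEFAULT_MIN_READS,
) -> list[DeltaPsiRecord]:
    """Per-exon treated-minus-control PSI from replicate-level estimates.

    With the default ``pooled`` aggregator, read counts are summed across
    replicates within a condition before the ratio is taken (stable for
    low-coverage exons); ``mean`` averages per-sample PSI values instead.
    Both condition groups must cover the same exon set.
    """
    control = _aggregate(psi_control, aggregator, min_reads)
    treated = _aggregate(psi_treated, aggregator, min_reads)
    missing = sorted(set(control) ^ set(treated))
    if missing:
        raise DataError(
            "control and treated groups quantify different exon sets; "
            f"unmatched exon_ids: {missing}"
        )
    records: list[DeltaPsiRecord] = []
    for exon_id in sorted(control):
        c, t = control[exon_id], treated[exon_id]
        covered_both = (
            c.covered and t.covered and c.psi is not None and t.psi is not None
        )
        delta = t.psi - c.psi if covered_both else None
        records.append(
            DeltaPsiRecord(
                exon_id=exon_id,
                psi_control=c.psi,
                psi_treated=t.psi,
                delta_psi=delta,
                covered_both=covered_both,
            )
        )
    return records


def psi_to_frame(estimates: Iterable[PsiEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "exon_id": e.exon_id,
                "sample_id": e.sample_id,
                "inclusion_reads_3ss": e.inclusion_reads_3ss,
                "inclusion_reads_5ss": e.inclusion_reads_5ss,
                "exclusion_reads": e.exclusion_reads,
                "psi3": e.psi3,
                "psi5": e.psi5,
                "psi": e.psi,
                "covered": e.covered,
            }
            for e in estimates
        ]
    )


def delta_to_frame(records: Iterable[DeltaPsiRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "exon_id": r.exon_id,
                "psi_control": r.psi_control,
                "psi_treated": r.psi_treated,
                "delta_psi": r.delta_psi,
                "covered_both": r.covered_both,
            }
            for r in records
        ]
    )
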