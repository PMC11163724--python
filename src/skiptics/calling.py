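"""Skiptic-exon calling from condition-wise PSI comparisons.

An exon is *constitutive* when its steady-state (control) PSI exceeds the
constitutive threshold (default 0.90, i.e. PSI > 90%); a constitutive exon is
called *skiptic* when its PSI drops under treatment by at least the skip
threshold (default 0.20 in delta-PSI units). Exons failing the coverage gate
in either condition are labelled ``low_coverage``; covered exons that are not
constitutive at baseline are ``alternative``. The four labels partition the
input: every exon receives exactly one.

Calls are threshold-based point estimates by design — no multiple-testing
machinery — matching a descriptive, junction-count-based analysis.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError
from .junction_io import ExonRecord
from .psi import DeltaPsiRecord

logger = logging.getLogger(__name__)

LABELS = ("constitutive_unchanged", "skiptic", "alternative", "low_coverage")

DEFAULT_CONSTITUTIVE_THRESHOLD = 0.90
DEFAULT_SKIP_THRESHOLD = 0.20


@dataclass(frozen=True, slots=True)
class SkipticCall:
    """Classification of one exon from control vs. treated PSI."""

    exon_id: str
    gene_id: str
    psi_control: float | None
    psi_treated: float | None
    delta_psi: float | None
    label: str


def classify_exon(
    record: DeltaPsiRecord,
    constitutive_threshold: float = DEFAULT_CONSTITUTIVE_THRESHOLD,
    skip_threshold: float = DEFAULT_SKIP_THRESHOLD,
    gene_id: str = "",
) -> SkipticCall:
    """Assign one of the four labels to a delta-PSI record."""
    for name, value in (
        ("constitutive_threshold", constitutive_threshold),
        ("skip_threshold", skip_threshold),
    ):
        if not 0.0 < value < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {value}")

    if not record.covered_both or record.psi_control is None:
        label = "low_coverage"
    elif record.psi_control <= constitutive_threshold:
        label = "alternative"
    elif record.delta_psi is not None and record.delta_psi <= -skip_threshold:
        label = "skiptic"
    else:
        label = "constitutive_unchanged"
    return SkipticCall(
        exon_id=record.exon_id,
        gene_id=gene_id,
        psi_control=record.psi_control,
        psi_treated=record.psi_treated,
        delta_psi=record.delta_psi,
        label=label,
    )


def call_skiptics(
    delta_table: Iterable[DeltaPsiRecord],
    constitutive_threshold: float = DEFAULT_CONSTITUTIVE_THRESHOLD,
    skip_threshold: float = DEFAULT_SKIP_THRESHOLD,
    gene_ids: Mapping[str, str] | None = None,
) -> list[SkipticCall]:
    """Classify every exon; output sorted by delta-PSI ascending.

    ``gene_ids`` optionally maps exon_id to gene_id for reporting. Per-label
    counts are logged.
    """
    records = list(delta_table)
    if not records:
        warnings.warn("empty delta-PSI table: no calls made", stacklevel=2)
        return []
    gene_ids = gene_ids or {}
    calls = [
        classify_exon(
            r,
            constitutive_threshold,
            skip_threshold,
            gene_id=gene_ids.get(r.exon_id, ""),
        )
        for r in records
    ]
    calls.sort(
        key=lambda c: (c.delta_psi is None, c.delta_psi or 0.0, c.exon_id)
    )
    counts = Counter(c.label for c in calls)
    logger.info(
        "skiptic calls: %s",
        ", ".join(f"{label}={counts.get(label, 0)}" for label in LABELS),
    )
    return calls


def summarize_calls(calls: Iterable[SkipticCall]) -> dict[str, int]:
    """Per-label call counts (all four labels always present)."""
    counts = Counter(c.label for c in calls)
    return {label: counts.get(label, 0) for label in LABELS}


@dataclass(frozen=True, slots=True)
class SpeciesOverlap:
    """Cross-species skiptic overlap through an ortholog exon map.

    ``shared`` counts mapped pairs skiptic in both species; ``a_only`` and
    ``b_only`` count skiptic exons of each species not shared (whether their
    partner is non-skiptic or they have no mapped partner at all).
    """

    shared: int
    a_only: int
    b_only: int
    unmapped_a: int
    unmapped_b: int
    pair_table: pd.DataFrame


def compare_species(
    calls_a: Iterable[SkipticCall],
    calls_b: Iterable[SkipticCall],
    ortholog_map: Sequence[tuple[str, str]],
) -> SpeciesOverlap:
    """Summarize skiptic-call overlap between two species.

    ``ortholog_map`` lists (exon_id_A, exon_id_B) pairs asserted equivalent;
    pairs referencing exon IDs absent from either call set raise an error.
    """
    calls_a = list(calls_a)
    calls_b = list(calls_b)
    known_a = {c.exon_id for c in calls_a}
    known_b = {c.exon_id for c in calls_b}
    unknown = [f"A:{a}" for a, _ in ortholog_map if a not in known_a]
    unknown += [f"B:{b}" for _, b in ortholog_map if b not in known_b]
    if unknown:
        raise DataError(f"ortholog map references unknown exon IDs: {unknown}")

    skiptic_a = {c.exon_id for c in calls_a if c.label == "skiptic"}
    skiptic_b = {c.exon_id for c in calls_b if c.label == "skiptic"}
    mapped_a = {a for a, _ in ortholog_map}
    mapped_b = {b for _, b in ortholog_map}

    rows = []
    shared = 0
    for a, b in ortholog_map:
        in_a, in_b = a in skiptic_a, b in skiptic_b
        shared += in_a and in_b
        rows.append(
            {"exon_a": a, "exon_b": b, "skiptic_a": in_a, "skiptic_b": in_b}
        )
    return SpeciesOverlap(
        shared=shared,
        a_only=len(skiptic_a) - shared,
        b_only=len(skiptic_b) - shared,
        unmapped_a=len(skiptic_a - mapped_a),
        unmapped_b=len(skiptic_b - mapped_b),
        pair_table=pd.DataFrame(
            rows, columns=["exon_a", "exon_b", "skiptic_a", "skiptic_b"]
        ),
    )


def calls_to_frame(calls: Iterable[SkipticCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "exon_id": c.exon_id,
                "gene_id": c.gene_id,
                "psi_control": c.psi_control,
                "psi_treated": c.psi_treated,
                "delta_psi": c.delta_psi,
                "label": c.label,
            }
            for c in calls
        ]
    )


def write_skiptic_bed(
    calls: Iterable[SkipticCall],
    exons: Iterable[ExonRecord],
    path: str | Path,
) -> None:
    """Write skiptic exons as BED6 for genome-browser display.

    Name is ``gene:exon``; score is ``round(1000 * |delta_psi|)``.
    """
    by_id = {e.exon_id: e for e in exons}
    with open(path, "w") as handle:
        for call in calls:
            if call.label != "skiptic":
                continue
            exon = by_id.get(call.exon_id)
            if exon is None:
                continue
            score = round(1000 * abs(call.delta_psi or 0.0))
            name = f"{call.gene_id or exon.gene_id}:{call.exon_id}"
            handle.write(
                f"{exon.chrom}\t{exon.start}\t{exon.end}\t{name}\t{score}\t"
                f"{exon.strand}\n"
            )
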