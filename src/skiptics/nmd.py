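"""Nonsense-mediated decay (NMD) prediction for skipped exons.

Two rules are exposed:

* ``frame_only`` (default): skipping an internal exon whose length is not a
  multiple of 3 shifts the downstream reading frame, which almost always
  creates a premature termination codon (PTC); the prediction depends only on
  exon length.
* ``full_ptc_rule``: the transcript is re-spliced without the exon and
  re-translated from the annotated coding start; the classical 50-nt rule then
  predicts NMD when a PTC appears more than 50 nt upstream of the final
  exon–exon junction.

The frame rule needs no transcript model and is robust to annotation errors;
the full rule is provided for users with complete coding transcript models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .junction_io import ExonRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Classical boundary: a PTC more than this many nt upstream of the last
#: exon-exon junction triggers NMD.
LAST_JUNCTION_DISTANCE = 50


@dataclass(frozen=True, slots=True)
class NmdCall:
    """Prediction for one skipped exon.

    ``ptc_detected`` and ``last_junction_rule_passed`` are ``None`` under the
    frame-only rule (not evaluated).
    """

    exon_id: str
    exon_length: int
    frame_preserving: bool
    ptc_detected: bool | None
    last_junction_rule_passed: bool | None
    nmd_predicted: bool
    rule_used: str  # "frame_only" | "full_ptc_rule"


def frame_call(exon_id: str, exon_length: int) -> NmdCall:
    """Frame-rule NMD call from an exon length alone."""
    if exon_length <= 0:
        raise ValueError(f"exon length must be positive, got {exon_length}")
    frame_preserving = exon_length % 3 == 0
    return NmdCall(
        exon_id=exon_id,
        exon_length=exon_length,
        frame_preserving=frame_preserving,
        ptc_detected=None,
        last_junction_rule_passed=None,
        nmd_predicted=not frame_preserving,
        rule_used="frame_only",
    )


def predict_nmd_frame(exon: ExonRecord) -> NmdCall:
    """Frame-rule NMD prediction for skipping one annotated exon."""
    return frame_call(exon.exon_id, exon.length)


@dataclass(frozen=True, slots=True)
class TranscriptModel:
    """Ordered exon sequences of one transcript with its coding start.

    ``exons`` lists (exon_id, sequence) pairs in transcription (5'→3') order;
    ``cds_start`` is the 0-based offset of the start codon's first base within
    the spliced mRNA, or ``None`` for a non-coding model.
    """

    transcript_id: str
    exons: tuple[tuple[str, str], ...]
    cds_start: int | None = None

    @property
    def spliced(self) -> str:
        return "".join(seq for _, seq in self.exons).upper().replace("U", "T")

    @property
    def coding_length(self) -> int:
        return len(self.spliced) - (self.cds_start or 0)

    def exon_span(self, exon_id: str) -> tuple[int, int]:
        """Half-open span of an exon within the spliced mRNA."""
        pos = 0
        for eid, seq in self.exons:
            if eid == exon_id:
                return pos, pos + len(seq)
            pos += len(seq)
        raise ValueError(
            f"exon {exon_id!r} not in transcript {self.transcript_id!r}"
        )


def _first_stop(seq: str, start: int) -> int | None:
    """Position of the first in-frame stop codon at or after ``start``."""
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i
    return None


def predict_nmd_full(exon_id: str, transcript: TranscriptModel) -> NmdCall:
    """Full PTC/50-nt-rule NMD prediction for skipping one exon.

    The exon is removed from the spliced mRNA and translation is re-run from
    the annotated coding start. ``ptc_detected`` is True when a stop codon
    appears upstream of where the annotated stop lands in the re-spliced
    transcript; the 50-nt rule then requires that PTC to sit more than 50 nt
    upstream of the final exon–exon junction of the re-spliced transcript.
    """
    if transcript.cds_start is None:
        raise ValueError(
            "transcript has no annotated coding start; use the frame-only "
            "rule (predict_nmd_frame) instead"
        )
    a, b = transcript.exon_span(exon_id)  # raises if exon absent
    exon_length = b - a
    full = transcript.spliced
    cds_start = transcript.cds_start

    if a <= cds_start < b:
        raise ValueError(
            f"coding start lies inside skipped exon {exon_id!r}; "
            "cannot evaluate the PTC rule"
        )
    modified = full[:a] + full[b:]
    new_cds_start = cds_start - exon_length if b <= cds_start else cds_start

    annotated_stop = _first_stop(full, cds_start)
    if annotated_stop is not None:
        if annotated_stop >= b:
            expected_stop = annotated_stop - exon_length
        elif annotated_stop < a:
            expected_stop = annotated_stop
        else:
            expected_stop = None  # annotated stop removed with the exon
    else:
        expected_stop = None

    new_stop = _first_stop(modified, new_cds_start)
    ptc_detected = new_stop is not None and (
        expected_stop is None or new_stop < expected_stop
    )

    remaining = [(eid, seq) for eid, seq in transcript.exons if eid != exon_id]
    if len(remaining) >= 2:
        last_junction = sum(len(seq) for _, seq in remaining[:-1])
    else:
        last_junction = None  # single-exon transcript: rule not applicable

    rule_passed: bool | None
    if ptc_detected and last_junction is not None:
        rule_passed = (last_junction - new_stop) > LAST_JUNCTION_DISTANCE
    elif ptc_detected:
        rule_passed = False
    else:
        rule_passed = None

    return NmdCall(
        exon_id=exon_id,
        exon_length=exon_length,
        frame_preserving=exon_length % 3 == 0,
        ptc_detected=ptc_detected,
        last_junction_rule_passed=rule_passed,
        nmd_predicted=bool(ptc_detected and rule_passed),
        rule_used="full_ptc_rule",
    )


def choose_transcript(
    exon_id: str, transcripts: Sequence[TranscriptModel]
) -> TranscriptModel:
    """Pick the transcript used for a multi-transcript exon.

    The longest annotated coding transcript containing the exon wins; ties
    break on the lexicographically smallest transcript_id, so the choice is
    deterministic.
    """
    containing = [
        t
        for t in transcripts
        if t.cds_start is not None and any(eid == exon_id for eid, _ in t.exons)
    ]
    if not containing:
        raise ValueError(
            f"no coding transcript containing exon {exon_id!r} was supplied"
        )
    return min(containing, key=lambda t: (-t.coding_length, t.transcript_id))


@dataclass(frozen=True, slots=True)
class NmdSummary:
    n_nmd: int
    n_total: int
    fraction: float


def summarize_nmd(calls: Iterable[NmdCall]) -> NmdSummary:
    """Counts and fraction of NMD-positive calls (order-invariant)."""
    calls = list(calls)
    if not calls:
        raise ValueError("summarize_nmd requires at least one call")
    n_nmd = sum(c.nmd_predicted for c in calls)
    return NmdSummary(n_nmd=n_nmd, n_total=len(calls), fraction=n_nmd / len(calls))


def calls_to_frame(calls: Iterable[NmdCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "exon_id": c.exon_id,
                "exon_length": c.exon_length,
                "frame_preserving": c.frame_preserving,
                "rule_used": c.rule_used,
                "nmd_predicted": c.nmd_predicted,
            }
            for c in calls
        ]
    )


def write_nmd_tsv(calls: Iterable[NmdCall], path: str | Path) -> None:
    calls = list(calls)
    summary = summarize_nmd(calls)
    with open(path, "w") as handle:
        handle.write(
            f"# NMD predicted for {summary.n_nmd}/{summary.n_total} exons "
            f"({100 * summary.fraction:.1f}%)\n"
        )
        calls_to_frame(calls).to_csv(handle, sep="\t", index=False)
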