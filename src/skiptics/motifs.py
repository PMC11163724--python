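"""UG/GU dinucleotide repeat profiling around splice sites.

TDP-43 binds UG-repeat RNA; this module measures how often qualifying UG
repeat runs occur at each position of a window centered on an exon's acceptor
(3'SS) or donor (5'SS) splice site, averaged over a set of exons.

The per-sequence indicator is computed in five stages:

1. every position participating in at least one UG or GU dinucleotide
   (overlaps allowed, T and U equivalent) is masked 'Y', all others 'N';
2. (part of stage 1 — non-UG bases, including ambiguity codes, become 'N');
3. repeat *runs* are segments containing at least ``min_len`` Y characters and
   at most ``max_inner_n`` N characters, where any N must be interior to the
   run (flanked by Y on both sides), e.g. YYYYY, YNYYYY, YYNYYY, ...;
4. Y positions inside qualifying runs score 1, everything else (including the
   interior N itself) scores 0;
5. the indicator vectors of all windows, aligned on the splice site, are
   summed vertically and divided by the number of sequences.

Window convention: offset 0 is the first exonic base for the 3'SS anchor and
the last exonic base for the 5'SS anchor; negative offsets are upstream in
transcript (sense) orientation. Windows for '-'-strand exons are
reverse-complemented so positions always read 5'→3' on the sense strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .errors import DataError
from .junction_io import ExonRecord

Anchor = Literal["3SS", "5SS"]

DEFAULT_FLANK = 400
DEFAULT_MIN_LEN = 5
DEFAULT_MAX_INNER_N = 1

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class MaskedSequence:
    """A sequence with its UG/GU mask and (optionally) its run indicator."""

    raw: str
    mask: str
    qualifying: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.raw) != len(self.mask):
            raise ValueError("mask length must equal sequence length")
        if self.qualifying is not None and len(self.qualifying) != len(self.raw):
            raise ValueError("qualifying vector length must equal sequence length")


def mask_ug(sequence: str) -> MaskedSequence:
    """Mask every position inside a UG or GU dinucleotide as 'Y'.

    Overlapping dinucleotides all mask, so "TGT" becomes "YYY". T and U are
    treated identically; ambiguity codes and assembly N's cannot support a UG
    dinucleotide and become 'N'.
    """
    s = sequence.upper().replace("U", "T")
    n = len(s)
    mask = bytearray(b"N" * n)
    for i in range(n - 1):
        pair = s[i : i + 2]
        if pair == "TG" or pair == "GT":
            mask[i] = mask[i + 1] = ord("Y")
    return MaskedSequence(raw=sequence, mask=mask.decode())


def find_repeat_runs(
    mask: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_inner_n: int = DEFAULT_MAX_INNER_N,
) -> np.ndarray:
    """Binary indicator of Y positions inside qualifying repeat runs.

    A run qualifies when it contains >= ``min_len`` Y characters and at most
    ``max_inner_n`` N characters, none of them terminal. Y positions in
    qualifying runs get 1; interior N positions and everything else get 0.
    """
    n = len(mask)
    qual = np.zeros(n, dtype=np.uint8)
    # maximal Y-runs as (start, end) half-open
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if mask[i] == "Y":
            j = i
            while j < n and mask[j] == "Y":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    # A chain of consecutive Y-runs whose inter-run gaps total <= max_inner_n
    # spans a candidate run (terminal chars are Y by construction). Marking the
    # maximal chain from each start run covers every qualifying sub-chain.
    for a in range(len(runs)):
        y_total = runs[a][1] - runs[a][0]
        gap_total = 0
        b = a
        while b + 1 < len(runs):
            gap = runs[b + 1][0] - runs[b][1]
            if gap_total + gap > max_inner_n:
                break
            gap_total += gap
            b += 1
            y_total += runs[b][1] - runs[b][0]
        if y_total >= min_len:
            for k in range(a, b + 1):
                qual[runs[k][0] : runs[k][1]] = 1
    return qual


def repeat_indicator(
    sequence: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_inner_n: int = DEFAULT_MAX_INNER_N,
) -> MaskedSequence:
    """Mask a sequence and attach its qualifying-run indicator."""
    masked = mask_ug(sequence)
    return MaskedSequence(
        raw=masked.raw,
        mask=masked.mask,
        qualifying=find_repeat_runs(masked.mask, min_len, max_inner_n),
    )


@dataclass(frozen=True, slots=True)
class WindowSequence:
    """A sense-strand window around one splice site."""

    exon_id: str
    anchor: str
    seq: str
    truncated: bool  # True when padded with N at a contig edge


def _contig_sequence(genome, chrom: str) -> str | None:
    """Fetch a full contig from a pyfaidx.Fasta or a plain mapping."""
    try:
        entry = genome[chrom]
    except KeyError:
        return None
    if isinstance(entry, str):
        return entry
    return str(entry[:])  # pyfaidx FastaRecord


def extract_window(
    genome: Mapping[str, str],
    exon: ExonRecord,
    anchor: Anchor,
    flank: int = DEFAULT_FLANK,
) -> WindowSequence:
    """Extract the +/- ``flank`` window around one splice site of an exon.

    ``genome`` may be a ``pyfaidx.Fasta`` or any mapping of contig name to
    sequence. The returned sequence has length ``2 * flank + 1`` and reads
    5'→3' on the exon's sense strand; windows truncated at contig ends are
    padded with 'N' and flagged.
    """
    if anchor not in ("3SS", "5SS"):
        raise ValueError(f"anchor must be '3SS' or '5SS', got {anchor!r}")
    contig = _contig_sequence(genome, exon.chrom)
    if contig is None:
        raise DataError(f"contig {exon.chrom!r} not found in genome FASTA")
    if (anchor == "3SS") == (exon.strand == "+"):
        center = exon.start  # first exonic base on '+' / last on '-'
    else:
        center = exon.end - 1
    lo, hi = center - flank, center + flank + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(contig))
    seq = contig[max(lo, 0) : min(hi, len(contig))]
    seq = "N" * left_pad + seq + "N" * right_pad
    if exon.strand == "-":
        seq = reverse_complement(seq)
    return WindowSequence(
        exon_id=exon.exon_id,
        anchor=anchor,
        seq=seq,
        truncated=bool(left_pad or right_pad),
    )


@dataclass(frozen=True, slots=True)
class RepeatProfile:
    """Per-offset UG-repeat-run frequency aligned on a splice site."""

    anchor: str
    offsets: np.ndarray  # relative positions, offset 0 = anchored exonic base
    frequency: np.ndarray  # fraction of sequences with a qualifying run
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "anchor": self.anchor,
                "offset": self.offsets,
                "frequency": self.frequency,
                "n_sequences": self.n_sequences,
            }
        )


def splice_site_profile(
    exons: Iterable[ExonRecord],
    genome: Mapping[str, str],
    anchor: Anchor,
    flank: int = DEFAULT_FLANK,
    min_len: int = DEFAULT_MIN_LEN,
    max_inner_n: int = DEFAULT_MAX_INNER_N,
) -> RepeatProfile:
    """Average the qualifying-run indicator over splice-site-aligned windows."""
    exons = list(exons)
    if not exons:
        raise DataError("splice_site_profile requires at least one exon")
    total = np.zeros(2 * flank + 1, dtype=np.int64)
    for exon in exons:
        window = extract_window(genome, exon, anchor, flank)
        total += repeat_indicator(window.seq, min_len, max_inner_n).qualifying
    return RepeatProfile(
        anchor=anchor,
        offsets=np.arange(-flank, flank + 1),
        frequency=total / len(exons),
        n_sequences=len(exons),
    )


def write_profile_tsv(profile: RepeatProfile, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "# offset 0 = first exonic base (3SS anchor) or last exonic base "
            "(5SS anchor); offsets read 5'->3' on the sense strand\n"
        )
        profile.to_frame().to_csv(handle, sep="\t", index=False)
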