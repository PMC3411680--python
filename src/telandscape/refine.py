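"""Post-annotation cleanup: fragment joining, simple-repeat filtering, and
full-length classification.

A TE copy interrupted by younger insertions is reported by homology search
as several fragments. Consecutive same-family fragments are rejoined when
the genomic gap between them consists mostly (>80% by default) of other TE
annotations — i.e. the interruption is explained by nesting. Annotations
whose length outside simple-repeat regions falls below a minimum (20 bp by
default) are spurious hits and are eliminated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import groupby

from telandscape.model import (
    SimpleRepeatTrack,
    TECopy,
    TEFamily,
    merge_intervals,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class JoinPolicy:
    """Controls fragment joining.

    min_other_te_fraction: minimum fraction of the genomic gap that must be
        covered by other TE annotations for two fragments to be joined.
    require_same_family / require_colinear: join only fragments of the same
        family whose consensus spans are colinear (second fragment starts at
        or after the first's consensus end, minus ``colinear_tolerance_bp``
        to absorb slight overlap of alignment ends).
    """

    min_other_te_fraction: float = 0.80
    require_same_family: bool = True
    require_colinear: bool = True
    colinear_tolerance_bp: int = 50

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_other_te_fraction <= 1.0):
            raise ValueError("min_other_te_fraction must be in [0,1]")


@dataclass(frozen=True)
class FilterPolicy:
    """Minimum residual length (bp) outside simple repeats."""

    min_length_bp: int = 20

    def __post_init__(self) -> None:
        if self.min_length_bp < 1:
            raise ValueError("min_length_bp must be >= 1")


def _covered_fraction(
    gap_start: int,
    gap_end: int,
    intervals: list[tuple[int, int]],
    exclude: tuple[tuple[int, int], ...],
) -> float:
    """Fraction of [gap_start, gap_end) covered by intervals not in exclude.

    An empty gap is defined as fully covered (fraction 1).
    """
    if gap_end <= gap_start:
        return 1.0
    keep = [iv for iv in intervals if iv not in exclude]
    if not keep:
        return 0.0
    covered = 0
    for s, e in merge_intervals(keep):
        if s >= gap_end:
            break
        covered += max(0, min(e, gap_end) - max(s, gap_start))
    return covered / (gap_end - gap_start)


def _merge_pair(a: TECopy, b: TECopy) -> TECopy:
    """Merge two colinear fragments into one copy spanning both."""
    cons_start = cons_end = None
    if a.cons_start is not None and b.cons_start is not None:
        cons_start = min(a.cons_start, b.cons_start)
        cons_end = max(a.cons_end, b.cons_end)
    identity = None
    if a.identity_pct is not None and b.identity_pct is not None:
        identity = (
            a.identity_pct * a.length + b.identity_pct * b.length
        ) / (a.length + b.length)
    joined = (a.joined_from or (a.copy_id,)) + (b.joined_from or (b.copy_id,))
    return replace(
        a,
        end=max(a.end, b.end),
        cons_start=cons_start,
        cons_end=cons_end,
        identity_pct=identity,
        joined_from=joined,
    )


def join_fragments(
    copies: list[TECopy], policy: JoinPolicy = JoinPolicy()
) -> list[TECopy]:
    """Join consecutive fragments of interrupted TE copies.

    Two consecutive same-family, same-strand fragments, colinear on the
    consensus, merge whenever the genomic gap between them is more than
    ``policy.min_other_te_fraction`` covered by other TE annotations.
    Merging is applied transitively left to right. Overlapping same-family
    fragments (gap <= 0) merge unconditionally.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in copies:
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end))

    out: list[TECopy] = []

    def group_key(c: TECopy):
        if policy.require_same_family:
            return (c.chrom, c.family_id, c.strand)
        return (c.chrom, c.strand)

    for _key, group in groupby(
        sorted(copies, key=lambda c: (group_key(c), c.start, c.end)), group_key
    ):
        current: TECopy | None = None
        for nxt in group:
            if current is None:
                current = nxt
                continue
            colinear = True
            if policy.require_colinear and (
                current.cons_end is not None and nxt.cons_start is not None
            ):
                colinear = (
                    nxt.cons_start
                    >= current.cons_end - policy.colinear_tolerance_bp
                )
            gap_start, gap_end = current.end, nxt.start
            if gap_end <= gap_start:
                if colinear:
                    logger.debug(
                        "overlapping fragments %s/%s merged unconditionally",
                        current.copy_id,
                        nxt.copy_id,
                    )
                    current = _merge_pair(current, nxt)
                    continue
            elif colinear:
                frac = _covered_fraction(
                    gap_start,
                    gap_end,
                    by_chrom[current.chrom],
                    exclude=(
                        (current.start, current.end),
                        (nxt.start, nxt.end),
                    ),
                )
                if frac > policy.min_other_te_fraction:
                    current = _merge_pair(current, nxt)
                    continue
            out.append(current)
            current = nxt
        if current is not None:
            out.append(current)
    out.sort(key=lambda c: (c.chrom, c.start, c.end, c.copy_id))
    return out


def subtract_and_filter(
    copies: list[TECopy],
    simple_repeats: SimpleRepeatTrack,
    policy: FilterPolicy = FilterPolicy(),
) -> list[TECopy]:
    """Drop copies whose length outside simple repeats is below the minimum.

    The subtraction is a filter criterion, not a trim: surviving copies
    keep their original coordinates.
    """
    kept: list[TECopy] = []
    for c in copies:
        residual = c.length - simple_repeats.overlap_bp(c.chrom, c.start, c.end)
        if residual >= policy.min_length_bp:
            kept.append(c)
    return kept


def flag_full_length(
    copies: list[TECopy],
    families: list[TEFamily],
    min_coverage: float = 0.95,
    end_tolerance_bp: int = 10,
) -> list[TECopy]:
    """Set ``full_length`` on copies covering essentially the whole consensus.

    A copy is full-length iff its consensus span covers at least
    ``min_coverage`` of the family consensus AND both termini lie within
    ``end_tolerance_bp`` of the consensus ends. Copies without a consensus
    span are incomplete (logged).
    """
    fam_len = {f.family_id: f.consensus_length for f in families}
    out: list[TECopy] = []
    for c in copies:
        if c.cons_start is None or c.cons_end is None:
            logger.debug("copy %s lacks consensus span; incomplete", c.copy_id)
            out.append(replace(c, full_length=False))
            continue
        length = fam_len.get(c.family_id)
        if length is None:
            logger.warning(
                "copy %s: unknown family %s; incomplete", c.copy_id, c.family_id
            )
            out.append(replace(c, full_length=False))
            continue
        full = (
            c.cons_span >= min_coverage * length
            and c.cons_start <= end_tolerance_bp
            and c.cons_end >= length - end_tolerance_bp
        )
        out.append(replace(c, full_length=full))
    return out
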