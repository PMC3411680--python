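"""LTR-retrotransposon insertion dating.

The two long terminal repeats of an LTR element are identical at the
moment of insertion and diverge thereafter, each accumulating substitutions
at the neutral rate r. Aligning the 5' and 3' LTRs of one full-length copy,
counting transitions (P) and transversions (Q), correcting with the Kimura
two-parameter distance

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

and dividing by twice the per-site per-year rate gives the insertion age

    T = K / (2 r).

The factor 2 reflects that the observed divergence accrues on both LTR
copies. The default clock r = 1.3e-8 substitutions/site/year is the
grass-retrotransposon rate commonly borrowed for fungal LTR elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align

DEFAULT_RATE = 1.3e-8

# Age bins (years) bounding the three expansion periods reported for
# L. bicolor: 57-10 Mya, 5-1 Mya, and <0.5 Mya.
DEFAULT_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 0.5e6),
    (1.0e6, 5.0e6),
    (10.0e6, 57.0e6),
)

MIN_LTR_LEN = 30


@dataclass(frozen=True)
class ClockParams:
    """Molecular-clock rate and expansion-period age bins."""

    rate_r: float = DEFAULT_RATE
    bins: tuple[tuple[float, float], ...] = DEFAULT_BINS

    def __post_init__(self) -> None:
        if self.rate_r <= 0:
            raise ValueError("rate_r must be > 0")
        prev_hi = -1.0
        for lo, hi in self.bins:
            if not (lo < hi) or lo < prev_hi:
                raise ValueError("bins must be non-overlapping and ascending")
            prev_hi = hi


@dataclass(frozen=True)
class ActivityPolicy:
    """Identity threshold (strict >) for flagging potentially active
    families."""

    identity_threshold_pct: float = 95.0

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold_pct < 100.0):
            raise ValueError("identity_threshold_pct must be in (0,100)")


@dataclass
class LTRPair:
    """Dated 5'/3' LTR pair of one full-length element."""

    copy_id: str
    family_id: str
    aligned_cols: int
    p_transitions: float
    q_transversions: float
    k2p: float | None
    age_years: float | None
    saturated: bool = False


class SaturationError(ValueError):
    """Divergence too high for the K2P correction to be defined."""


class UndatablePairError(ValueError):
    """No comparable columns between the two LTRs."""


def make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Align.PairwiseAligner:
    """Global affine-gap pairwise aligner (penalties given as positive)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_ltrs(
    ltr5: str, ltr3: str, aligner: Align.PairwiseAligner | None = None
) -> tuple[str, str]:
    """Globally align the two LTRs; returns the gapped sequence pair.

    Sequences shorter than 30 bp are refused — too short to date and
    usually a sign of a degenerate LTR call. The caller must orient the
    sequences (both on the element's strand) before calling. Among
    co-optimal alignments the first in the aligner's deterministic
    enumeration order is taken.
    """
    ltr5, ltr3 = ltr5.upper(), ltr3.upper()
    if len(ltr5) < MIN_LTR_LEN or len(ltr3) < MIN_LTR_LEN:
        raise ValueError(
            f"LTR shorter than {MIN_LTR_LEN} bp cannot be dated reliably"
        )
    if aligner is None:
        aligner = make_aligner()
    alignment = aligner.align(ltr5, ltr3)[0]
    return str(alignment[0]), str(alignment[1])


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


def is_transition(a: str, b: str) -> bool:
    return a != b and (
        (a in _PURINES and b in _PURINES)
        or (a in _PYRIMIDINES and b in _PYRIMIDINES)
    )


def count_pq(aligned5: str, aligned3: str) -> tuple[float, float, int]:
    """Count transition and transversion fractions over comparable columns.

    Comparable columns are those where both symbols are in {A,C,G,T};
    gap and N columns are excluded. Returns (P, Q, n).
    """
    if len(aligned5) != len(aligned3):
        raise ValueError("aligned sequences differ in length")
    n = ts = tv = 0
    for a, b in zip(aligned5.upper(), aligned3.upper()):
        if a not in _VALID or b not in _VALID:
            continue
        n += 1
        if a == b:
            continue
        if is_transition(a, b):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise UndatablePairError("no comparable columns between LTRs")
    return ts / n, tv / n, n


def kimura2p(p: float, q: float) -> tuple[float, bool]:
    """Kimura two-parameter distance; returns (K, saturated).

    Saturation (1 - 2P - Q <= 0 or 1 - 2Q <= 0) leaves K undefined;
    saturated pairs are excluded from age histograms but reported.
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise ValueError("P and Q must be in [0,1]")
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan, True
    return -0.5 * math.log(w1) - 0.25 * math.log(w2), False


def age_from_k(k: float, clock: ClockParams = ClockParams()) -> float:
    """Insertion age in years: T = K / (2 r)."""
    if not (k >= 0.0) or math.isnan(k):
        raise SaturationError("K undefined or negative; cannot date")
    return k / (2.0 * clock.rate_r)


def date_ltr_pair(
    copy_id: str,
    family_id: str,
    ltr5: str,
    ltr3: str,
    clock: ClockParams = ClockParams(),
    aligner: Align.PairwiseAligner | None = None,
) -> LTRPair:
    """Align, count, correct and convert: the full dating pipeline for one
    element."""
    a5, a3 = align_ltrs(ltr5, ltr3, aligner=aligner)
    p, q, n = count_pq(a5, a3)
    k, saturated = kimura2p(p, q)
    return LTRPair(
        copy_id=copy_id,
        family_id=family_id,
        aligned_cols=n,
        p_transitions=p,
        q_transversions=q,
        k2p=None if saturated else k,
        age_years=None if saturated else age_from_k(k, clock),
        saturated=saturated,
    )


@dataclass
class ExpansionHistogram:
    """Per-bin family counts plus out-of-bin and saturated tallies."""

    bins: tuple[tuple[float, float], ...]
    family_counts: list[int] = field(default_factory=list)
    other_families: int = 0
    saturated_copies: int = 0


def bin_expansions(
    pairs: list[LTRPair], clock: ClockParams = ClockParams()
) -> ExpansionHistogram:
    """Count families per expansion-period age bin.

    A family is counted once in every bin (closed-lower, open-upper) that
    contains at least one of its dated copies; families whose dated copies
    all fall outside every bin are tallied under ``other_families``;
    saturated copies are counted separately and never binned.
    """
    in_bin: list[set[str]] = [set() for _ in clock.bins]
    outside: set[str] = set()
    dated_families: set[str] = set()
    saturated = 0
    for pair in pairs:
        if pair.saturated or pair.age_years is None:
            saturated += 1
            continue
        dated_families.add(pair.family_id)
        hit = False
        for i, (lo, hi) in enumerate(clock.bins):
            if lo <= pair.age_years < hi:
                in_bin[i].add(pair.family_id)
                hit = True
                break
        if not hit:
            outside.add(pair.family_id)
    binned = set().union(*in_bin) if in_bin else set()
    return ExpansionHistogram(
        bins=clock.bins,
        family_counts=[len(s) for s in in_bin],
        other_families=len(outside - binned),
        saturated_copies=saturated,
    )


def flag_active(
    families: list,
    copies: list,
    policy: ActivityPolicy = ActivityPolicy(),
) -> dict[str, bool]:
    """Flag families with >=2 full-length, nearly identical copies.

    A family whose members are still nearly identical to the consensus
    (identity strictly above the threshold) has transposed recently enough
    that it is potentially still active.
    """
    counts: dict[str, int] = {}
    for c in copies:
        if (
            c.full_length
            and c.identity_pct is not None
            and c.identity_pct > policy.identity_threshold_pct
        ):
            counts[c.family_id] = counts.get(c.family_id, 0) + 1
    return {f.family_id: counts.get(f.family_id, 0) >= 2 for f in families}
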