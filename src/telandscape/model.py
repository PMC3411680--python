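"""Shared domain types for the TE landscape pipeline.

Coordinate convention: all internal intervals are 0-based, half-open
``[start, end)``. The GFF3 and RepeatMasker ``.out`` converters in
:mod:`telandscape.io` own the +/-1 arithmetic against the 1-based
inclusive conventions of those formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Fixed order -> class mapping. LTR and non-LTR retroelement orders are
# class I (RNA intermediate), DNA-transposon orders class II, and anything
# unclassified is bookkept as "fragment".
CLASS_I_LTR_ORDERS = ("ERV", "Copia", "Gypsy", "LARD", "DIRS")
CLASS_I_NONLTR_ORDERS = ("Tad", "Deceiver", "L1", "LINE")
CLASS_II_ORDERS = ("TIR", "Helitron", "MITE")

ORDER_TO_CLASS: dict[str, str] = {
    **{o: "I" for o in CLASS_I_LTR_ORDERS},
    **{o: "I" for o in CLASS_I_NONLTR_ORDERS},
    **{o: "II" for o in CLASS_II_ORDERS},
    "unclassified": "fragment",
}

KNOWN_ORDERS = tuple(ORDER_TO_CLASS)


@dataclass(frozen=True)
class TEClass:
    """TE classification: class I (retroelements), II (DNA transposons),
    or fragment (unclassified)."""

    order_label: str

    def __post_init__(self) -> None:
        if self.order_label not in ORDER_TO_CLASS:
            raise ValueError(f"unknown TE order: {self.order_label!r}")

    @property
    def class_label(self) -> str:
        return ORDER_TO_CLASS[self.order_label]

    @property
    def has_ltr(self) -> bool:
        """True for orders flanked by long terminal repeats."""
        return self.order_label in CLASS_I_LTR_ORDERS


@dataclass
class TEFamily:
    """A named TE family with its classification and consensus length."""

    family_id: str
    te_class: TEClass
    consensus_length: int

    def __post_init__(self) -> None:
        if self.consensus_length <= 0:
            raise ValueError(
                f"family {self.family_id}: consensus_length must be > 0"
            )

    @property
    def has_ltr(self) -> bool:
        return self.te_class.has_ltr


@dataclass
class TECopy:
    """One annotated TE interval on the genome.

    ``start``/``end`` are genomic (0-based half-open); ``cons_start``/
    ``cons_end`` locate the copy on the family consensus in the same
    convention (``None`` when the annotation does not provide them).
    Minus-strand copies keep unflipped genomic coordinates; sequence
    extraction reverse-complements on demand.
    """

    copy_id: str
    family_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    cons_start: int | None = None
    cons_end: int | None = None
    identity_pct: float | None = None
    full_length: bool = False
    joined_from: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"copy {self.copy_id}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"copy {self.copy_id}: bad strand {self.strand!r}")
        if self.cons_start is not None and self.cons_end is not None:
            if not (0 <= self.cons_start < self.cons_end):
                raise ValueError(
                    f"copy {self.copy_id}: invalid consensus span "
                    f"[{self.cons_start}, {self.cons_end})"
                )
        if self.identity_pct is not None and not (
            0.0 <= self.identity_pct <= 100.0
        ):
            raise ValueError(
                f"copy {self.copy_id}: identity_pct out of [0,100]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cons_span(self) -> int | None:
        if self.cons_start is None or self.cons_end is None:
            return None
        return self.cons_end - self.cons_start


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeAssembly:
    """A genome as a map of chromosome name -> uppercase A/C/G/T/N string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for name, seq in self.sequences.items():
            s = seq.upper()
            bad = set(s) - set("ACGTN")
            if bad:
                # ambiguity codes collapse to N; anything else is rejected
                iupac = set("RYSWKMBDHV")
                if bad - iupac:
                    raise ValueError(
                        f"{name}: non-nucleotide symbols {sorted(bad - iupac)}"
                    )
                s = "".join(c if c in "ACGTN" else "N" for c in s)
            clean[name] = s
        self.sequences = clean

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Extract [start, end); reverse-complemented for minus strand."""
        seq = self.sequences[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"{chrom}:[{start},{end}) outside chromosome of {len(seq)} bp"
            )
        sub = seq[start:end]
        return revcomp(sub) if strand == "-" else sub


@dataclass
class SimpleRepeatTrack:
    """Per-chromosome simple-repeat intervals, stored merged and sorted.

    Consumed from an external tandem-repeat finder as BED; never computed
    here.
    """

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = {
            chrom: merge_intervals(ivs) for chrom, ivs in self.intervals.items()
        }

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Total bp of [start, end) covered by simple repeats."""
        total = 0
        for s, e in self.intervals.get(chrom, ()):
            if s >= end:
                break
            total += max(0, min(e, end) - max(s, start))
        return total


def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/touching half-open intervals."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if s >= e:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def validate_copies(copies: list[TECopy], assembly: GenomeAssembly) -> None:
    """Assert every copy lies within its chromosome bounds."""
    lengths = assembly.lengths
    for c in copies:
        if c.chrom not in lengths:
            raise ValueError(f"copy {c.copy_id}: unknown chromosome {c.chrom}")
        if c.end > lengths[c.chrom]:
            raise ValueError(
                f"copy {c.copy_id}: end {c.end} beyond {c.chrom} "
                f"({lengths[c.chrom]} bp)"
            )
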