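"""Genome TE summary table: per-order family/copy counts, full-length vs
incomplete split, DNA amount and percent genome composition, with class
subtotals and a grand total.

DNA amount counts each copy's genomic span once per copy even where copies
overlap through nesting, so per-row megabases sum exactly to the total; a
deduplicated ``masked_mb`` column (union of copy intervals per row) is
emitted alongside for transparency. Genome size is a parameter rather than
being inferred from the FASTA, so summaries of annotation subsets remain
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from telandscape.model import (
    CLASS_I_LTR_ORDERS,
    CLASS_I_NONLTR_ORDERS,
    CLASS_II_ORDERS,
    TECopy,
    TEFamily,
    merge_intervals,
)

# Presentation order of the leaf rows in the summary table.
ORDER_ROWS: tuple[str, ...] = (
    CLASS_I_LTR_ORDERS + CLASS_I_NONLTR_ORDERS + CLASS_II_ORDERS
)


@dataclass
class SummaryRow:
    """One row of the summary table.

    ``n_full_length``/``n_incomplete`` are ``None`` for fragment rows,
    which carry no consensus and hence no full/incomplete split.
    """

    label: str
    n_families: int
    n_copies: int
    n_full_length: int | None
    n_incomplete: int | None
    dna_mb: float
    composition_pct: float
    masked_mb: float | None = None

    def __post_init__(self) -> None:
        # full + incomplete equals copies for pure order rows; rows that
        # also include fragment copies (which carry no split) may exceed
        # the split sum, never the reverse
        if self.n_full_length is not None and self.n_incomplete is not None:
            if self.n_full_length + self.n_incomplete > self.n_copies:
                raise ValueError(
                    f"{self.label}: full ({self.n_full_length}) + incomplete "
                    f"({self.n_incomplete}) > copies ({self.n_copies})"
                )


def _row_from_counts(
    label: str,
    n_families: int,
    n_copies: int,
    n_full: int | None,
    n_inc: int | None,
    dna_bp: float,
    genome_size_bp: int,
    masked_bp: float | None = None,
) -> SummaryRow:
    dna_mb = dna_bp / 1e6
    return SummaryRow(
        label=label,
        n_families=n_families,
        n_copies=n_copies,
        n_full_length=n_full,
        n_incomplete=n_inc,
        dna_mb=dna_mb,
        composition_pct=100.0 * dna_bp / genome_size_bp,
        masked_mb=None if masked_bp is None else masked_bp / 1e6,
    )


def subtotal_row(
    label: str, rows: list[SummaryRow], genome_size_bp: int
) -> SummaryRow:
    """Sum a list of rows into a subtotal row.

    The full/incomplete split is summed over rows that carry one
    (fragment rows contribute copies but no split, mirroring the
    bookkeeping of the genome summary table).
    """
    with_split = [r for r in rows if r.n_full_length is not None]
    dna_mb = sum(r.dna_mb for r in rows)
    masked = [r.masked_mb for r in rows if r.masked_mb is not None]
    return SummaryRow(
        label=label,
        n_families=sum(r.n_families for r in rows),
        n_copies=sum(r.n_copies for r in rows),
        n_full_length=(
            sum(r.n_full_length for r in with_split) if with_split else None
        ),
        n_incomplete=(
            sum(
                r.n_copies - r.n_full_length
                for r in with_split
            )
            if with_split
            else None
        ),
        dna_mb=dna_mb,
        composition_pct=100.0 * dna_mb / (genome_size_bp / 1e6),
        masked_mb=sum(masked) if masked else None,
    )


def build_summary(
    leaf_rows: dict[str, SummaryRow],
    fragment_row: SummaryRow | None,
    genome_size_bp: int,
) -> list[SummaryRow]:
    """Assemble leaf rows + class subtotals + grand total.

    ``leaf_rows`` maps order label -> row; orders absent from the map are
    skipped. Emits, in order: class I leaves, Total Class I, class II
    leaves, Total Class II, the fragment row, Total TE.
    """
    if genome_size_bp <= 0:
        raise ValueError("genome size must be > 0")
    class1 = [
        leaf_rows[o]
        for o in CLASS_I_LTR_ORDERS + CLASS_I_NONLTR_ORDERS
        if o in leaf_rows
    ]
    class2 = [leaf_rows[o] for o in CLASS_II_ORDERS if o in leaf_rows]
    out: list[SummaryRow] = []
    out.extend(class1)
    out.append(subtotal_row("Total Class I", class1, genome_size_bp))
    out.extend(class2)
    out.append(subtotal_row("Total Class II", class2, genome_size_bp))
    totals = [out[len(class1)], out[-1]]
    if fragment_row is not None:
        out.append(fragment_row)
        totals.append(fragment_row)
    out.append(subtotal_row("Total TE", totals, genome_size_bp))
    return out


def summarize(
    copies: list[TECopy],
    families: list[TEFamily],
    genome_size_bp: int,
) -> list[SummaryRow]:
    """Per-order summary of refined, full-length-flagged copies.

    Family count per order counts families with at least one copy. Copies
    of unclassified families land in the fragment row, which carries no
    full/incomplete split.
    """
    if genome_size_bp <= 0:
        raise ValueError("genome size must be > 0")
    order_of = {f.family_id: f.te_class.order_label for f in families}
    per_order: dict[str, list[TECopy]] = {}
    for c in copies:
        per_order.setdefault(order_of.get(c.family_id, "unclassified"), []).append(c)

    def leaf(label: str, group: list[TECopy], split: bool) -> SummaryRow:
        n_full = sum(1 for c in group if c.full_length)
        ivs: dict[str, list[tuple[int, int]]] = {}
        for c in group:
            ivs.setdefault(c.chrom, []).append((c.start, c.end))
        masked_bp = sum(
            e - s
            for chrom_ivs in ivs.values()
            for s, e in merge_intervals(chrom_ivs)
        )
        return _row_from_counts(
            label,
            n_families=len({c.family_id for c in group}),
            n_copies=len(group),
            n_full=n_full if split else None,
            n_inc=len(group) - n_full if split else None,
            dna_bp=sum(c.length for c in group),
            genome_size_bp=genome_size_bp,
            masked_bp=masked_bp,
        )

    leaves = {
        o: leaf(o, per_order[o], split=True)
        for o in ORDER_ROWS
        if o in per_order
    }
    fragment = (
        leaf("TE fragments", per_order["unclassified"], split=False)
        if "unclassified" in per_order
        else None
    )
    return build_summary(leaves, fragment, genome_size_bp)


def density_summary(n_copies: int, genome_size_bp: int) -> int:
    """Average TE density, copies per Mb, rounded to nearest integer."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be > 0")
    return round(n_copies / (genome_size_bp / 1e6))


def to_dataframe(rows: list[SummaryRow]) -> pd.DataFrame:
    """Six-column table (+ masked Mb) mirroring the genome summary layout."""
    return pd.DataFrame(
        {
            "TE type": [r.label for r in rows],
            "Family": [r.n_families for r in rows],
            "Copy number": [r.n_copies for r in rows],
            "Full length/incomplete": [
                "-"
                if r.n_full_length is None
                else f"{r.n_full_length}/{r.n_incomplete}"
                for r in rows
            ],
            "DNA amount (Mb)": [r.dna_mb for r in rows],
            "TE composition in genome (%)": [r.composition_pct for r in rows],
            "Masked (Mb)": [
                float("nan") if r.masked_mb is None else r.masked_mb
                for r in rows
            ],
        }
    )
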