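"""Published TE-annotation bookkeeping for the 60 Mb *Laccaria bicolor*
assembly.

These are the per-order rows of the published genome TE summary (family
count, copy number, full-length/incomplete split, DNA amount in Mb), used
as *inputs*: the summarize module's subtotal/total/percentage arithmetic
recomputes every derived figure (class subtotals, grand total, percent
composition, average density) from them at run time.

Leaf rows carry the superfamily-level counts. The published LTR and
non-LTR group rows are also recorded: the published leaf Mb values for
the LTR group do not sum exactly to the published group figure (4.03 vs
3.99 Mb — a rounding artifact of the source table), so Mb/% arithmetic is
checked from the group rows, whose sums are self-consistent at every
level, while family/copy/full-length arithmetic is checked from the
leaves, where the sums are exact.
"""

from __future__ import annotations

GENOME_SIZE_BP = 60_000_000

# label -> (n_families, n_copies, n_full_length, n_incomplete, dna_mb)
LEAF_ROWS: dict[str, tuple[int, int, int, int, float]] = {
    "ERV": (1, 7, 4, 3, 0.03),
    "Copia": (46, 3382, 57, 3325, 2.23),
    "Gypsy": (27, 3085, 47, 3038, 1.71),
    "LARD": (3, 118, 1, 117, 0.05),
    "DIRS": (1, 19, 1, 18, 0.01),
    "Tad": (2, 22, 17, 5, 1.60),
    "Deceiver": (1, 1, 1, 0, 0.02),
    "L1": (1, 1, 0, 1, 0.01),
    "LINE": (5, 1249, 5, 1244, 0.58),
    "TIR": (23, 6369, 692, 5677, 2.85),
    "Helitron": (1, 215, 2, 213, 0.08),
    "MITE": (4, 249, 103, 146, 0.06),
}

# published group-level rows (same tuple layout); the fragment row has no
# full/incomplete split
GROUP_ROWS: dict[str, tuple[int, int, int | None, int | None, float]] = {
    "LTR": (78, 6611, 110, 6501, 3.99),
    "NonLTR": (9, 1273, 23, 1250, 2.21),
    "TIR": (23, 6369, 692, 5677, 2.85),
    "Helitron": (1, 215, 2, 213, 0.08),
    "MITE": (4, 249, 103, 146, 0.06),
    "Fragments": (56, 11070, None, None, 5.33),
}

LTR_ORDERS = ("ERV", "Copia", "Gypsy", "LARD", "DIRS")
NONLTR_ORDERS = ("Tad", "Deceiver", "L1", "LINE")
CLASS_II_GROUPS = ("TIR", "Helitron", "MITE")

# published derived figures the arithmetic must reproduce
PUBLISHED = {
    "class_i": (87, 7884, 133, 7751, 6.20, 10.33),
    "class_ii": (28, 6833, 797, 6036, 2.99, 4.98),
    "total_copies": 25787,
    "total_full_length": 930,
    "total_incomplete": 13787,
    "total_dna_mb": 14.52,
    "total_composition_pct": 24.2,
    "density_per_mb": 430,
    "copia_composition_pct": 3.72,
}
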