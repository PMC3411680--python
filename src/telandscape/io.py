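"""Readers and writers for the standard formats the pipeline touches.

RepeatMasker ``.out`` and GFF3 use 1-based inclusive coordinates; both
converters translate to the internal 0-based half-open convention on read
and back on write. The GFF3 writer emits attributes in a fixed order so
read -> write -> read is the identity on coordinates and attributes.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from telandscape.model import (
    GenomeAssembly,
    KNOWN_ORDERS,
    SimpleRepeatTrack,
    TEClass,
    TECopy,
    TEFamily,
)

logger = logging.getLogger(__name__)

# RepeatMasker class/family strings -> internal order label. Matching is
# case-insensitive on the part after the last "/" and on the whole string.
_ORDER_ALIASES = {
    "copia": "Copia",
    "gypsy": "Gypsy",
    "erv": "ERV",
    "lard": "LARD",
    "dirs": "DIRS",
    "tad": "Tad",
    "tad1": "Tad",
    "deceiver": "Deceiver",
    "l1": "L1",
    "line": "LINE",
    "tir": "TIR",
    "helitron": "Helitron",
    "mite": "MITE",
}


def parse_order_label(class_family: str) -> str:
    """Map a RepeatMasker class/family string to an order label.

    Unknown strings map to ``unclassified`` (class: fragment).
    """
    for token in reversed(class_family.split("/")):
        key = token.strip().lower()
        if key in _ORDER_ALIASES:
            return _ORDER_ALIASES[key]
        # exact order name, e.g. "LINE" appearing before the slash
        for order in KNOWN_ORDERS:
            if key == order.lower():
                return order
    logger.warning("unknown TE class string %r -> unclassified", class_family)
    return "unclassified"


class MalformedRecordError(ValueError):
    """A format row that cannot be parsed, reported with its line number."""


def _strip_parens(tok: str) -> int:
    return int(tok.strip("()"))


def read_repeatmasker_out(
    path: str | Path,
) -> tuple[list[TECopy], list[TEFamily]]:
    """Parse a RepeatMasker ``.out`` file into copies and families.

    Layout: 3 header lines, then whitespace-separated columns
    score, div%, del%, ins%, query, qbegin, qend, (qleft), strand,
    repeat, class/family, rbegin, rend, (rleft), ID. On the ``C``
    (complement) strand the repeat coordinates are printed
    ``(left) end begin``; either orientation is accepted.

    Returns one :class:`TECopy` per alignment row (1-based inclusive query
    coordinates converted to 0-based half-open, ``C`` mapped to ``-``,
    ``identity_pct = 100 - div%``) and families deduplicated by repeat
    name with the consensus length inferred as ``rend + rleft``.
    """
    copies: list[TECopy] = []
    fam_len: dict[str, int] = {}
    fam_order: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno <= 3 or not line.strip():
            continue
        toks = line.split()
        if len(toks) < 14:
            raise MalformedRecordError(
                f"{path}:{lineno}: expected >=14 columns, got {len(toks)}"
            )
        try:
            div = float(toks[1])
            query = toks[4]
            qbegin, qend = int(toks[5]), int(toks[6])
            strand = "-" if toks[8] in ("C", "-") else "+"
            repeat = toks[9]
            class_family = toks[10]
            r1, r2, r3 = toks[11], toks[12], toks[13]
            if r1.startswith("("):  # C orientation: (left) end begin
                rleft, rend, rbegin = _strip_parens(r1), int(r2), int(r3)
            else:  # + orientation: begin end (left)
                rbegin, rend, rleft = int(r1), int(r2), _strip_parens(r3)
        except (ValueError, IndexError) as exc:
            raise MalformedRecordError(f"{path}:{lineno}: {exc}") from exc
        if qbegin > qend:
            raise MalformedRecordError(
                f"{path}:{lineno}: query begin {qbegin} > end {qend}"
            )
        order = parse_order_label(class_family)
        copy_id = toks[14] if len(toks) > 14 else f"rm{lineno}"
        copies.append(
            TECopy(
                copy_id=f"{repeat}.{copy_id}.{lineno}",
                family_id=repeat,
                chrom=query,
                start=qbegin - 1,
                end=qend,
                strand=strand,
                cons_start=min(rbegin, rend) - 1,
                cons_end=max(rbegin, rend),
                identity_pct=100.0 - div,
            )
        )
        length = max(rbegin, rend) + rleft
        fam_len[repeat] = max(fam_len.get(repeat, 0), length)
        fam_order.setdefault(repeat, order)
    families = [
        TEFamily(
            family_id=name,
            te_class=TEClass(fam_order[name]),
            consensus_length=fam_len[name],
        )
        for name in fam_len
    ]
    return copies, families


# ---------------------------------------------------------------------------
# GFF3

_GFF_SOURCE = "telandscape"
_GFF_TYPE = "dispersed_repeat"


def read_gff3(path: str | Path) -> list[TECopy]:
    """Read TE copies from GFF3 (one feature per copy).

    Attributes must carry ``Family``; ``Identity``, ``ConsStart``/
    ``ConsEnd`` (1-based inclusive), ``FullLength`` and ``JoinedFrom``
    are optional. Records lacking a family attribute are rejected and
    logged. Strand ``.`` is stored as ``+`` and logged.
    """
    copies: list[TECopy] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise MalformedRecordError(
                    f"{path}:{lineno}: expected 9 tab-separated columns"
                )
            chrom, _src, _type, start1, end1, _score, strand, _phase, attrs = (
                fields
            )
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if "Family" not in attr:
                logger.warning(
                    "%s:%d: record lacks Family attribute; skipped",
                    path,
                    lineno,
                )
                continue
            if strand == ".":
                logger.warning(
                    "%s:%d: strand '.'; stored as '+'", path, lineno
                )
                strand = "+"
            cons_start = (
                int(attr["ConsStart"]) - 1 if "ConsStart" in attr else None
            )
            cons_end = int(attr["ConsEnd"]) if "ConsEnd" in attr else None
            copies.append(
                TECopy(
                    copy_id=attr.get("ID", f"gff{lineno}"),
                    family_id=attr["Family"],
                    chrom=chrom,
                    start=int(start1) - 1,
                    end=int(end1),
                    strand=strand,
                    cons_start=cons_start,
                    cons_end=cons_end,
                    identity_pct=(
                        float(attr["Identity"]) if "Identity" in attr else None
                    ),
                    full_length=attr.get("FullLength") == "1",
                    joined_from=tuple(
                        attr["JoinedFrom"].split(",")
                    )
                    if "JoinedFrom" in attr
                    else (),
                )
            )
    return copies


def write_gff3(copies: Iterable[TECopy], path: str | Path) -> None:
    """Write copies as GFF3 with attributes in a fixed order."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in copies:
            attrs = [f"ID={c.copy_id}", f"Family={c.family_id}"]
            if c.identity_pct is not None:
                attrs.append(f"Identity={c.identity_pct:g}")
            if c.cons_start is not None and c.cons_end is not None:
                attrs.append(f"ConsStart={c.cons_start + 1}")
                attrs.append(f"ConsEnd={c.cons_end}")
            if c.full_length:
                attrs.append("FullLength=1")
            if c.joined_from:
                attrs.append("JoinedFrom=" + ",".join(c.joined_from))
            fh.write(
                "\t".join(
                    [
                        c.chrom,
                        _GFF_SOURCE,
                        _GFF_TYPE,
                        str(c.start + 1),
                        str(c.end),
                        ".",
                        c.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED, FASTA, TSV


def read_bed(path: str | Path) -> SimpleRepeatTrack:
    """Read 3-column BED (0-based half-open) into a merged repeat track."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split("\t")
            if len(toks) < 3:
                raise MalformedRecordError(
                    f"{path}:{lineno}: expected >=3 BED columns"
                )
            intervals.setdefault(toks[0], []).append(
                (int(toks[1]), int(toks[2]))
            )
    return SimpleRepeatTrack(intervals=intervals)


def write_bed(
    records: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write (chrom, start, end, name) rows as BED4."""
    with open(path, "w") as fh:
        for chrom, start, end, name in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_fasta(path: str | Path) -> GenomeAssembly:
    return GenomeAssembly(
        sequences={
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
        }
    )


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_family_table(path: str | Path) -> tuple[list[TEFamily], dict[str, int]]:
    """Read a family metadata TSV: family_id, order_label,
    consensus_length[, ltr_length].

    Returns the families plus a map family_id -> terminal-repeat length
    (0 where absent), used for LTR extraction.
    """
    families: list[TEFamily] = []
    ltr_len: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            toks = line.rstrip("\n").split("\t")
            try:
                fam_id = toks[idx["family_id"]]
                families.append(
                    TEFamily(
                        family_id=fam_id,
                        te_class=TEClass(toks[idx["order_label"]]),
                        consensus_length=int(toks[idx["consensus_length"]]),
                    )
                )
                ltr_len[fam_id] = (
                    int(toks[idx["ltr_length"]]) if "ltr_length" in idx else 0
                )
            except (KeyError, IndexError, ValueError) as exc:
                raise MalformedRecordError(f"{path}:{lineno}: {exc}") from exc
    return families, ltr_len


def write_family_table(
    families: Iterable[TEFamily],
    path: str | Path,
    ltr_lengths: dict[str, int] | None = None,
) -> None:
    ltr_lengths = ltr_lengths or {}
    with open(path, "w") as fh:
        fh.write("family_id\torder_label\tconsensus_length\tltr_length\n")
        for f in families:
            fh.write(
                f"{f.family_id}\t{f.te_class.order_label}\t"
                f"{f.consensus_length}\t{ltr_lengths.get(f.family_id, 0)}\n"
            )


def write_table(df, path: str | Path, float_cols: dict[str, int] | None = None):
    """Write a DataFrame as TSV with deterministic formatting.

    ``float_cols`` maps column name -> decimal places (default 2, the
    precision used for Mb and % columns in the genome summary table).
    """
    df = df.copy()
    float_cols = float_cols or {}
    for col in df.columns:
        if df[col].dtype.kind == "f":
            nd = float_cols.get(col, 2)
            df[col] = df[col].map(lambda x, nd=nd: f"{x:.{nd}f}")
    df.to_csv(path, sep="\t", index=False)
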