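"""Nest/cluster topology and density profiling of TE copies.

Conventions: a TE strictly contained within another TE copy is a *nest*
(the insert reports its smallest enclosing host); TEs lying within 10 kb
of each other chain into *clusters* (single linkage on the end-to-start
gap); density is counted in consecutive 10 kb windows with each copy
assigned to the window holding its start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from telandscape.model import GenomeAssembly, TECopy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TopologyParams:
    cluster_gap_bp: int = 10_000
    terminal_region_bp: int = 1_000_000
    window_bp: int = 10_000
    window_step_bp: int | None = None  # None -> tiling (step = window)

    def __post_init__(self) -> None:
        if min(self.cluster_gap_bp, self.terminal_region_bp, self.window_bp) <= 0:
            raise ValueError("all topology parameters must be > 0")


@dataclass
class Cluster:
    chrom: str
    start: int
    end: int
    members: tuple[str, ...]


@dataclass
class TopologyReport:
    """Nests (host, insert), clusters (>=2 members), and derived tallies."""

    nests: list[tuple[str, str]] = field(default_factory=list)
    clusters: list[Cluster] = field(default_factory=list)

    @property
    def n_nests(self) -> int:
        return len(self.nests)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def involved_copy_ids(self) -> set[str]:
        ids: set[str] = set()
        for host, insert in self.nests:
            ids.add(host)
            ids.add(insert)
        for cl in self.clusters:
            ids.update(cl.members)
        return ids


def find_nests(copies: list[TECopy]) -> list[tuple[str, str]]:
    """Find strict containments: (host, insert) with >=1 bp flank each side.

    Each insert reports only its smallest enclosing host, so a triple
    nesting A > B > C yields (A, B) and (B, C).
    """
    nests: list[tuple[str, str]] = []
    by_chrom: dict[str, list[TECopy]] = {}
    for c in copies:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom_copies in by_chrom.values():
        tree = IntervalTree()
        for c in chrom_copies:
            tree.addi(c.start, c.end, c)
        for c in chrom_copies:
            hosts = [
                iv.data
                for iv in tree.overlap(c.start, c.end)
                if iv.data is not c
                and iv.data.start < c.start
                and c.end < iv.data.end
            ]
            if hosts:
                # smallest enclosing host; ties broken by (start, copy_id)
                host = min(
                    hosts, key=lambda h: (h.length, h.start, h.copy_id)
                )
                nests.append((host.copy_id, c.copy_id))
    nests.sort()
    return nests


def find_clusters(
    copies: list[TECopy], params: TopologyParams = TopologyParams()
) -> list[Cluster]:
    """Single-linkage chaining of copies within ``cluster_gap_bp``.

    Consecutive copies (sorted by start) whose gap next.start - prev.end
    is at most the threshold join one cluster; overlapping copies have
    gap <= 0 and always chain. Clusters require >= 2 members.
    """
    clusters: list[Cluster] = []
    by_chrom: dict[str, list[TECopy]] = {}
    for c in copies:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        chain: list[TECopy] = []
        chain_end = None
        for c in sorted(by_chrom[chrom], key=lambda x: (x.start, x.end)):
            if chain and c.start - chain_end <= params.cluster_gap_bp:
                chain.append(c)
                chain_end = max(chain_end, c.end)
            else:
                if len(chain) >= 2:
                    clusters.append(_close_chain(chrom, chain))
                chain = [c]
                chain_end = c.end
        if len(chain) >= 2:
            clusters.append(_close_chain(chrom, chain))
    return clusters


def _close_chain(chrom: str, chain: list[TECopy]) -> Cluster:
    return Cluster(
        chrom=chrom,
        start=min(c.start for c in chain),
        end=max(c.end for c in chain),
        members=tuple(sorted(c.copy_id for c in chain)),
    )


def density_profile(
    copies: list[TECopy],
    assembly: GenomeAssembly,
    params: TopologyParams = TopologyParams(),
) -> dict[str, list[int]]:
    """Copies per consecutive window along each chromosome.

    A copy counts in the window containing its start, so the profile sums
    to the chromosome's copy count. With ``window_step_bp`` set below the
    window size the windows slide and overlap (and the conservation
    property no longer holds); the default is tiling.
    """
    step = params.window_step_bp or params.window_bp
    profiles: dict[str, list[int]] = {}
    starts_by_chrom: dict[str, list[int]] = {}
    for c in copies:
        starts_by_chrom.setdefault(c.chrom, []).append(c.start)
    for chrom, length in assembly.lengths.items():
        n_windows = max(1, -(-length // step))
        counts = [0] * n_windows
        for s in starts_by_chrom.get(chrom, ()):
            if step == params.window_bp:
                counts[s // step] += 1
            else:
                first = max(0, (s - params.window_bp) // step + 1)
                for w in range(first, min(n_windows, s // step + 1)):
                    if w * step <= s < w * step + params.window_bp:
                        counts[w] += 1
        profiles[chrom] = counts
    return profiles


def terminal_enrichment(
    report: TopologyReport,
    assembly: GenomeAssembly,
    params: TopologyParams = TopologyParams(),
    copies: list[TECopy] | None = None,
) -> tuple[int, float]:
    """Count nests/clusters whose span overlaps a terminal chromosome region.

    A nest or cluster is terminal iff its span overlaps [0, t) or
    [L - t, L) with t the terminal region size. Chromosomes shorter than
    2t are entirely terminal (logged). Returns (count, fraction).
    """
    lengths = assembly.lengths
    spans: list[tuple[str, int, int]] = [
        (cl.chrom, cl.start, cl.end) for cl in report.clusters
    ]
    if report.nests:
        if copies is None:
            raise ValueError("copies required to locate nest spans")
        by_id = {c.copy_id: c for c in copies}
        for host, insert in report.nests:
            h, i = by_id[host], by_id[insert]
            spans.append((h.chrom, min(h.start, i.start), max(h.end, i.end)))
    t = params.terminal_region_bp
    n_terminal = 0
    for chrom, start, end in spans:
        length = lengths[chrom]
        if length < 2 * t:
            logger.debug(
                "%s shorter than 2x terminal region; wholly terminal", chrom
            )
            n_terminal += 1
            continue
        if start < t or end > length - t:
            n_terminal += 1
    total = len(spans)
    return n_terminal, (n_terminal / total if total else 0.0)


# Orders grouped for the per-order breakdown of nested/clustered copies.
_ORDER_GROUPS = {
    "Gypsy_Copia": ("Gypsy", "Copia"),
    "TIR": ("TIR",),
    "LINE": ("LINE", "Tad", "Deceiver", "L1"),
}


def nested_or_clustered_fraction(
    copies: list[TECopy],
    report: TopologyReport,
    order_of_family: dict[str, str] | None = None,
) -> tuple[float, dict[str, float]]:
    """Fraction of copies that are nest hosts, nest inserts or cluster
    members, with a per-order-group breakdown (fraction of all copies)."""
    if not copies:
        return 0.0, {}
    involved = report.involved_copy_ids()
    frac = len(involved & {c.copy_id for c in copies}) / len(copies)
    breakdown: dict[str, float] = {}
    if order_of_family:
        for group, orders in _ORDER_GROUPS.items():
            members = [
                c
                for c in copies
                if order_of_family.get(c.family_id) in orders
            ]
            hit = [c for c in members if c.copy_id in involved]
            breakdown[group] = len(hit) / len(copies)
    return frac, breakdown


def analyze_topology(
    copies: list[TECopy], params: TopologyParams = TopologyParams()
) -> TopologyReport:
    """Convenience: nests + clusters in one report."""
    return TopologyReport(
        nests=find_nests(copies), clusters=find_clusters(copies, params)
    )
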