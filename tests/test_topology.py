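"""Nests, clusters, density windows and terminal enrichment, checked
against brute-force oracles."""

import numpy as np
import pytest

from telandscape.model import GenomeAssembly, TECopy
from telandscape.topology import (
    TopologyParams,
    TopologyReport,
    analyze_topology,
    density_profile,
    find_clusters,
    find_nests,
    nested_or_clustered_fraction,
    terminal_enrichment,
)


def copy(cid, start, end, chrom="c1", family="F1"):
    return TECopy(cid, family, chrom, start, end)


def random_instance(rng, n_max=200, span=200_000):
    n = int(rng.integers(2, n_max + 1))
    starts = rng.integers(0, span, n)
    lengths = rng.integers(1, 5000, n)
    return [
        copy(f"c{i}", int(s), int(s + l))
        for i, (s, l) in enumerate(zip(starts, lengths))
    ]


def brute_force_nests(copies):
    """All-pairs strict-containment; each insert keeps its smallest host."""
    out = []
    for b in copies:
        hosts = [
            a
            for a in copies
            if a is not b
            and a.chrom == b.chrom
            and a.start < b.start
            and b.end < a.end
        ]
        if hosts:
            host = min(hosts, key=lambda h: (h.length, h.start, h.copy_id))
            out.append((host.copy_id, b.copy_id))
    return sorted(out)


def brute_force_clusters(copies, gap=10_000):
    """Transitive closure of the pairwise interval-gap <= gap relation."""
    n = len(copies)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            a, b = copies[i], copies[j]
            if i != j and a.chrom == b.chrom:
                g = max(b.start - a.end, a.start - b.end)
                if g <= gap:
                    adj[i][j] = True
    # floyd-warshall style closure
    comp = list(range(n))

    def find(i):
        while comp[i] != i:
            comp[i] = comp[comp[i]]
            i = comp[i]
        return i

    for i in range(n):
        for j in range(n):
            if adj[i][j]:
                comp[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(copies[i].copy_id)
    return sorted(
        tuple(sorted(g)) for g in groups.values() if len(g) >= 2
    )


class TestNests:
    def test_simple_containment(self):
        nests = find_nests([copy("h", 1000, 8000), copy("i", 2000, 3000)])
        assert nests == [("h", "i")]

    def test_overlap_without_containment_is_not_a_nest(self):
        nests = find_nests([copy("a", 1000, 8000), copy("b", 7500, 9000)])
        assert nests == []

    def test_shared_boundary_is_not_strict_containment(self):
        nests = find_nests([copy("a", 1000, 8000), copy("b", 1000, 3000)])
        assert nests == []

    def test_triple_nesting_reports_smallest_host(self):
        nests = find_nests(
            [
                copy("A", 0, 10_000),
                copy("B", 1000, 9000),
                copy("C", 2000, 3000),
            ]
        )
        assert nests == [("A", "B"), ("B", "C")]

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(30):
            copies = random_instance(rng, n_max=80)
            assert find_nests(copies) == brute_force_nests(copies)

    def test_irreflexive_and_antisymmetric(self, rng):
        for _ in range(10):
            copies = random_instance(rng, n_max=60)
            nests = set(find_nests(copies))
            for host, insert in nests:
                assert host != insert
                assert (insert, host) not in nests


class TestClusters:
    def test_within_gap_chains(self):
        (cl,) = find_clusters([copy("a", 100, 500), copy("b", 5000, 6000)])
        assert cl.members == ("a", "b")
        assert (cl.start, cl.end) == (100, 6000)

    def test_beyond_gap_excluded(self):
        clusters = find_clusters(
            [
                copy("a", 100, 500),
                copy("b", 5000, 6000),
                copy("c", 20_000, 21_000),
            ]
        )
        assert [cl.members for cl in clusters] == [("a", "b")]

    def test_singletons_are_not_clusters(self):
        assert find_clusters([copy("a", 0, 100)]) == []

    def test_adjacent_chain_of_five(self):
        copies = [copy(f"c{i}", i * 1001, i * 1001 + 1000) for i in range(5)]
        (cl,) = find_clusters(copies)
        assert len(cl.members) == 5

    def test_matches_brute_force_closure(self, rng):
        for _ in range(30):
            copies = random_instance(rng, n_max=100)
            got = sorted(cl.members for cl in find_clusters(copies))
            assert got == brute_force_clusters(copies)


class TestDensity:
    asm = GenomeAssembly(sequences={"c1": "A" * 20_000})

    def test_copies_counted_by_start_window(self):
        profile = density_profile(
            [copy("a", 1, 50), copy("b", 5000, 5100), copy("c", 9999, 12_000)],
            self.asm,
        )
        assert profile["c1"] == [3, 0]

    def test_half_open_boundary(self):
        profile = density_profile([copy("a", 10_000, 10_100)], self.asm)
        assert profile["c1"] == [0, 1]

    def test_window_conservation(self, default_sim):
        from telandscape.simulate import truth_to_copies

        asm, truth, _ = default_sim
        copies = truth_to_copies(truth)
        profile = density_profile(copies, asm)
        per_chrom = {}
        for c in copies:
            per_chrom[c.chrom] = per_chrom.get(c.chrom, 0) + 1
        for chrom, counts in profile.items():
            assert sum(counts) == per_chrom.get(chrom, 0)


class TestTerminal:
    asm = GenomeAssembly(sequences={"LG1": "A" * 5_000_000})

    def _report(self, start, end):
        from telandscape.topology import Cluster

        return TopologyReport(
            clusters=[Cluster("LG1", start, end, ("a", "b"))]
        )

    @pytest.mark.parametrize(
        "start,end,terminal",
        [
            (200_000, 400_000, True),  # inside [0, 1 Mb)
            (2_000_000, 2_100_000, False),  # interior
            (900_000, 1_200_000, True),  # straddles the boundary
            (4_200_000, 4_300_000, True),  # inside [L-1 Mb, L)
            (1_000_000, 1_100_000, False),  # starts exactly at 1 Mb
        ],
    )
    def test_overlap_rule(self, start, end, terminal):
        n, _frac = terminal_enrichment(self._report(start, end), self.asm)
        assert n == (1 if terminal else 0)

    def test_short_chromosome_wholly_terminal(self):
        asm = GenomeAssembly(sequences={"s": "A" * 1_500_000})
        from telandscape.topology import Cluster

        report = TopologyReport(
            clusters=[Cluster("s", 740_000, 760_000, ("a", "b"))]
        )
        n, frac = terminal_enrichment(report, asm)
        assert (n, frac) == (1, 1.0)


class TestNestedOrClusteredFraction:
    def test_isolated_copies_zero(self):
        copies = [copy("a", 0, 100), copy("b", 50_000, 50_100)]
        frac, _ = nested_or_clustered_fraction(
            copies, analyze_topology(copies)
        )
        assert frac == 0.0

    def test_adjacent_pair_is_one(self):
        copies = [copy("a", 0, 100), copy("b", 101, 200)]
        frac, _ = nested_or_clustered_fraction(
            copies, analyze_topology(copies)
        )
        assert frac == 1.0

    def test_simulator_truth_fraction_recovered(self, default_sim):
        from telandscape.simulate import truth_to_copies

        _, truth, _ = default_sim
        copies = truth_to_copies(truth)
        frac, _ = nested_or_clustered_fraction(
            copies, analyze_topology(copies)
        )
        assert frac == pytest.approx(
            truth.nested_or_clustered_fraction(), abs=1e-12
        )
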