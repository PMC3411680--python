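"""Synthetic TE landscapes with planted ground truth.

Generates a multi-chromosome genome carrying TE copies of known family,
age, truncation state, nesting and clustering, so that every pipeline
stage can be checked against truth. Copies diverge from their family
consensus under the two-rate (Kimura two-parameter) substitution process
the dating estimator inverts: per site, independently on each lineage,
with overall rate r substitutions/site/year and transition:transversion
rate bias kappa. The two LTRs of an element are identical at insertion
and each evolves independently for the element's age, so their expected
pairwise K2P distance is 2·r·age.

Nested insertion splits the host's genomic span, but truth keeps one host
record spanning the interruption — the representation fragment joining is
expected to reconstruct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from telandscape.dating import DEFAULT_RATE
from telandscape.model import (
    GenomeAssembly,
    TEClass,
    TECopy,
    TEFamily,
    revcomp,
)

logger = logging.getLogger(__name__)

_BASES = "ACGT"
# transition partner of A,C,G,T (A<->G, C<->T)
_TS_PARTNER = np.array([2, 3, 0, 1])
# the two transversion partners of each base
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass(frozen=True)
class FamilySpec:
    """One simulated family: order, consensus length, terminal-repeat
    length (LTR or TIR orders), and how many copies to plant."""

    order_label: str
    consensus_length: int
    repeat_length: int = 0
    copy_count: int = 10

    def __post_init__(self) -> None:
        TEClass(self.order_label)  # validates the label
        if self.consensus_length <= 0:
            raise ValueError("consensus_length must be > 0")
        if self.repeat_length and self.repeat_length >= self.consensus_length / 2:
            raise ValueError("terminal repeat must be < half the consensus")


# Desk-scale default emulating the structure of a TE-rich fungal genome:
# LTR superfamilies dominate (Copia > Gypsy), with TIR, LINE, MITE and a
# LARD family alongside. ~280 copies over 3 x 1 Mb.
DEFAULT_FAMILIES: tuple[FamilySpec, ...] = (
    FamilySpec("Copia", 5000, 300, 40),
    FamilySpec("Copia", 5000, 300, 30),
    FamilySpec("Copia", 4500, 250, 20),
    FamilySpec("Gypsy", 6000, 350, 30),
    FamilySpec("Gypsy", 5500, 350, 20),
    FamilySpec("LARD", 4000, 400, 10),
    FamilySpec("TIR", 2500, 50, 40),
    FamilySpec("TIR", 2000, 40, 30),
    FamilySpec("LINE", 5000, 0, 30),
    FamilySpec("MITE", 400, 30, 30),
)

# Age mixture over the three expansion periods (years); weights sum to 1.
DEFAULT_AGE_PERIODS: tuple[tuple[float, float], ...] = (
    (0.0, 0.5e6),
    (1.0e6, 5.0e6),
    (10.0e6, 57.0e6),
)
DEFAULT_AGE_WEIGHTS: tuple[float, ...] = (0.30, 0.35, 0.35)


@dataclass(frozen=True)
class SimConfig:
    """Conditions of a simulated TE landscape."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length_bp: int = 1_000_000
    family_specs: tuple[FamilySpec, ...] = DEFAULT_FAMILIES
    age_periods: tuple[tuple[float, float], ...] = DEFAULT_AGE_PERIODS
    age_weights: tuple[float, ...] = DEFAULT_AGE_WEIGHTS
    rate_r: float = DEFAULT_RATE
    kappa: float = 2.0
    gc: float = 0.5
    truncation_prob: float = 0.4
    truncation_extent: tuple[float, float] = (0.2, 0.8)
    nest_prob: float = 0.2
    cluster_prob: float = 0.4
    cluster_gap_bp: tuple[int, int] = (200, 10_000)
    max_retries: int = 50

    def __post_init__(self) -> None:
        for p in (
            self.truncation_prob,
            self.nest_prob,
            self.cluster_prob,
            self.gc,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0,1]")
        if self.nest_prob + self.cluster_prob > 1.0:
            raise ValueError("nest_prob + cluster_prob must be <= 1")
        if abs(sum(self.age_weights) - 1.0) > 1e-9:
            raise ValueError("age_weights must sum to 1")
        if self.rate_r <= 0 or self.kappa <= 0:
            raise ValueError("rate_r and kappa must be > 0")
        if self.n_chroms <= 0 or self.chrom_length_bp <= 0:
            raise ValueError("genome dimensions must be > 0")


@dataclass
class SimTruthRecord:
    """Ground truth for one planted copy."""

    copy_id: str
    family_id: str
    chrom: str
    start: int
    end: int
    strand: str
    true_age_years: float
    truncated: bool
    cons_start: int
    cons_end: int
    identity_pct: float
    nest_parent: str | None = None
    cluster_id: str | None = None
    interrupted: bool = False


@dataclass
class SimTruth:
    records: list[SimTruthRecord] = field(default_factory=list)
    consensi: dict[str, str] = field(default_factory=dict)

    def nested_or_clustered_fraction(self) -> float:
        involved = {
            r.copy_id
            for r in self.records
            if r.nest_parent is not None or r.cluster_id is not None
        }
        involved |= {
            r.nest_parent for r in self.records if r.nest_parent is not None
        }
        return len(involved) / len(self.records) if self.records else 0.0


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p_gc, p_at = gc / 2.0, (1.0 - gc) / 2.0
    idx = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(_BASES[i] for i in idx)


def make_consensus(
    spec: FamilySpec, rng: np.random.Generator, gc: float = 0.5
) -> str:
    """Random consensus with the order's terminal-repeat structure.

    LTR orders carry two identical terminal repeats; TIR/MITE orders
    carry terminal inverted repeats (the 3' repeat is the reverse
    complement of the 5' one).
    """
    k = spec.repeat_length
    te_class = TEClass(spec.order_label)
    if k == 0:
        return random_sequence(spec.consensus_length, gc, rng)
    body = random_sequence(spec.consensus_length - 2 * k, gc, rng)
    head = random_sequence(k, gc, rng)
    tail = head if te_class.has_ltr else revcomp(head)
    return head + body + tail


def _k2p_category_probs(
    age_years: float, r: float, kappa: float
) -> tuple[float, float, float]:
    """(P same, P transition, P each-transversion) after one lineage of
    ``age_years`` under the K2P process with total rate r and bias kappa."""
    beta = r / (kappa + 2.0)
    alpha = kappa * beta
    t = age_years
    e1 = np.exp(-2.0 * (alpha + beta) * t)
    e2 = np.exp(-4.0 * beta * t)
    p_same = 0.25 + 0.5 * e1 + 0.25 * e2
    p_ts = 0.25 - 0.5 * e1 + 0.25 * e2
    p_tv_each = 0.25 - 0.25 * e2
    return p_same, p_ts, p_tv_each


def mutate_by_age(
    seq: str,
    age_years: float,
    r: float,
    kappa: float,
    rng: np.random.Generator,
) -> str:
    """Evolve one lineage of ``seq`` for ``age_years`` under the K2P
    process (no indels). Age 0 returns the sequence unchanged."""
    if age_years < 0:
        raise ValueError("age must be >= 0")
    if age_years == 0.0:
        return seq
    idx = np.fromiter(
        ("ACGT".index(c) if c in "ACGT" else -1 for c in seq),
        dtype=np.int64,
        count=len(seq),
    )
    p_same, p_ts, p_tv = _k2p_category_probs(age_years, r, kappa)
    u = rng.random(len(seq))
    choice = rng.integers(0, 2, size=len(seq))  # which transversion partner
    out = idx.copy()
    valid = idx >= 0
    ts_mask = valid & (u >= p_same) & (u < p_same + p_ts)
    tv_mask = valid & (u >= p_same + p_ts)  # 2 * p_tv total mass remains
    out[ts_mask] = _TS_PARTNER[idx[ts_mask]]
    out[tv_mask] = _TV_PARTNERS[idx[tv_mask], choice[tv_mask]]
    return "".join(
        _BASES[i] if i >= 0 else c for i, c in zip(out, seq)
    )


def simulate_ltr_pair(
    ltr_length: int,
    age_years: float,
    r: float = DEFAULT_RATE,
    kappa: float = 2.0,
    rng: np.random.Generator | None = None,
    gc: float = 0.5,
) -> tuple[str, str]:
    """One element's 5'/3' LTR pair: identical at insertion, each lineage
    evolved independently for ``age_years``."""
    if rng is None:
        rng = np.random.default_rng(0)
    ancestral = random_sequence(ltr_length, gc, rng)
    return (
        mutate_by_age(ancestral, age_years, r, kappa, rng),
        mutate_by_age(ancestral, age_years, r, kappa, rng),
    )


def _identity_pct(a: str, b: str) -> float:
    assert len(a) == len(b)
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * matches / len(a)


def _sample_age(config: SimConfig, rng: np.random.Generator) -> float:
    i = rng.choice(len(config.age_periods), p=list(config.age_weights))
    lo, hi = config.age_periods[i]
    return float(rng.uniform(lo, hi))


def simulate(config: SimConfig = SimConfig()) -> tuple[GenomeAssembly, SimTruth, list[TEFamily]]:
    """Build the genome: background chromosomes, then planted copies.

    Placement per copy: with ``nest_prob`` inside a random existing copy
    (splitting the host; the host's truth record keeps its full
    interrupted extent), with ``cluster_prob`` within <= 10 kb downstream
    of an existing copy, otherwise uniformly at random avoiding the
    interior of existing copies. A failed placement after
    ``max_retries`` is logged and the copy skipped.
    """
    rng = np.random.default_rng(config.seed)
    chroms = {
        f"chr{i + 1}": random_sequence(config.chrom_length_bp, config.gc, rng)
        for i in range(config.n_chroms)
    }
    truth = SimTruth()
    families: list[TEFamily] = []

    specs: list[tuple[str, FamilySpec]] = []
    order_counter: dict[str, int] = {}
    for spec in config.family_specs:
        order_counter[spec.order_label] = (
            order_counter.get(spec.order_label, 0) + 1
        )
        fam_id = f"{spec.order_label}-{order_counter[spec.order_label]}"
        specs.append((fam_id, spec))
        consensus = make_consensus(spec, rng, config.gc)
        truth.consensi[fam_id] = consensus
        families.append(
            TEFamily(
                family_id=fam_id,
                te_class=TEClass(spec.order_label),
                consensus_length=spec.consensus_length,
            )
        )

    # interleave copies across families so nests/clusters mix families
    queue: list[str] = []
    for fam_id, spec in specs:
        queue.extend([fam_id] * spec.copy_count)
    rng.shuffle(queue)
    spec_of = dict(specs)

    n_placed = 0
    for fam_id in queue:
        spec = spec_of[fam_id]
        consensus = truth.consensi[fam_id]
        age = _sample_age(config, rng)
        seq = mutate_by_age(consensus, age, config.rate_r, config.kappa, rng)
        identity = _identity_pct(seq, consensus)
        cons_start, cons_end = 0, len(consensus)
        truncated = rng.random() < config.truncation_prob
        if truncated:
            frac = rng.uniform(*config.truncation_extent)
            cut = max(1, int(frac * len(seq)))
            cut = min(cut, len(seq) - 30)  # keep something alignable
            if rng.random() < 0.5:
                seq = seq[cut:]
                cons_start = cut
            else:
                seq = seq[: len(seq) - cut]
                cons_end = len(consensus) - cut
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = revcomp(seq) if strand == "-" else seq

        placement = _place(chroms, truth, config, rng, len(inserted))
        if placement is None:
            logger.warning("placement failed for a %s copy; skipped", fam_id)
            continue
        chrom, pos, nest_parent = placement
        n_placed += 1
        copy_id = f"sim{n_placed:04d}.{fam_id}"

        # splice in and shift/extend existing truth coordinates
        chroms[chrom] = (
            chroms[chrom][:pos] + inserted + chroms[chrom][pos:]
        )
        ln = len(inserted)
        for rec in truth.records:
            if rec.chrom != chrom:
                continue
            if rec.start < pos < rec.end:
                rec.end += ln
                rec.interrupted = True
            elif rec.start >= pos:
                rec.start += ln
                rec.end += ln
        truth.records.append(
            SimTruthRecord(
                copy_id=copy_id,
                family_id=fam_id,
                chrom=chrom,
                start=pos,
                end=pos + ln,
                strand=strand,
                true_age_years=age,
                truncated=truncated,
                cons_start=cons_start,
                cons_end=cons_end,
                identity_pct=identity,
                nest_parent=nest_parent,
            )
        )

    _assign_cluster_ids(truth, gap_bp=10_000)
    return GenomeAssembly(sequences=chroms), truth, families


def _place(
    chroms: dict[str, str],
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
    insert_len: int,
) -> tuple[str, int, str | None] | None:
    """Choose (chrom, position, nest_parent) for the next copy."""
    names = sorted(chroms)
    existing = truth.records
    mode = rng.random()
    if existing and mode < config.nest_prob:
        for _ in range(config.max_retries):
            host = existing[rng.integers(0, len(existing))]
            if host.end - host.start < 3:
                continue
            pos = int(rng.integers(host.start + 1, host.end - 1))
            # the true parent is the smallest record strictly containing
            # pos (the chosen host may itself contain nested copies)
            enclosing = [
                r
                for r in existing
                if r.chrom == host.chrom and r.start < pos < r.end
            ]
            parent = min(enclosing, key=lambda r: (r.end - r.start, r.start))
            return host.chrom, pos, parent.copy_id
        return None
    if existing and mode < config.nest_prob + config.cluster_prob:
        for _ in range(config.max_retries):
            anchor = existing[rng.integers(0, len(existing))]
            gap = int(rng.integers(*config.cluster_gap_bp))
            pos = anchor.end + gap
            if pos > len(chroms[anchor.chrom]):
                continue
            if _inside_existing(existing, anchor.chrom, pos):
                continue
            return anchor.chrom, pos, None
        return None
    for _ in range(config.max_retries):
        chrom = names[rng.integers(0, len(names))]
        pos = int(rng.integers(0, len(chroms[chrom]) + 1))
        if _inside_existing(existing, chrom, pos):
            continue
        return chrom, pos, None
    return None


def _inside_existing(
    records: list[SimTruthRecord], chrom: str, pos: int
) -> bool:
    return any(
        r.chrom == chrom and r.start < pos < r.end for r in records
    )


def _assign_cluster_ids(truth: SimTruth, gap_bp: int) -> None:
    """Label cluster membership by brute-force transitive closure of the
    pairwise end-to-start gap <= gap_bp relation (independent of the
    topology module's chaining implementation)."""
    recs = truth.records
    n = len(recs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = recs[i], recs[j]
            if a.chrom != b.chrom:
                continue
            gap = max(b.start - a.end, a.start - b.end)
            if gap <= gap_bp:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    cluster_no = 0
    for root in sorted(groups, key=lambda r: min(groups[r])):
        members = groups[root]
        if len(members) < 2:
            continue
        cluster_no += 1
        for i in members:
            recs[i].cluster_id = f"cl{cluster_no:03d}"


def truth_to_copies(truth: SimTruth) -> list[TECopy]:
    """Perfect annotations derived from truth, as pipeline input."""
    return [
        TECopy(
            copy_id=r.copy_id,
            family_id=r.family_id,
            chrom=r.chrom,
            start=r.start,
            end=r.end,
            strand=r.strand,
            cons_start=r.cons_start,
            cons_end=r.cons_end,
            identity_pct=r.identity_pct,
        )
        for r in truth.records
    ]


def write_truth_gff3(truth: SimTruth, path: str | Path) -> None:
    """Truth GFF3 carrying every SimTruth field as attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in sorted(truth.records, key=lambda x: (x.chrom, x.start)):
            attrs = [
                f"ID={r.copy_id}",
                f"Family={r.family_id}",
                f"Identity={r.identity_pct:g}",
                f"ConsStart={r.cons_start + 1}",
                f"ConsEnd={r.cons_end}",
                f"TrueAge={r.true_age_years:.1f}",
                f"Truncated={int(r.truncated)}",
                f"Interrupted={int(r.interrupted)}",
            ]
            if r.nest_parent:
                attrs.append(f"NestParent={r.nest_parent}")
            if r.cluster_id:
                attrs.append(f"ClusterId={r.cluster_id}")
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        "telandscape-sim",
                        "dispersed_repeat",
                        str(r.start + 1),
                        str(r.end),
                        ".",
                        r.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def write_truth_tsv(truth: SimTruth, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "copy_id": r.copy_id,
                "family_id": r.family_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "true_age_years": r.true_age_years,
                "truncated": r.truncated,
                "cons_start": r.cons_start,
                "cons_end": r.cons_end,
                "identity_pct": r.identity_pct,
                "nest_parent": r.nest_parent or "",
                "cluster_id": r.cluster_id or "",
                "interrupted": r.interrupted,
            }
            for r in sorted(
                truth.records, key=lambda x: (x.chrom, x.start)
            )
        ]
    )
    df.to_csv(path, sep="\t", index=False)
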