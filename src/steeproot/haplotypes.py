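"""Coding-sequence haplotypes, parsimony networks, and phenotype contrasts.

A panel of pre-aligned, equal-length CDS sequences is collapsed into
haplotypes (distinct sequence variants); each haplotype is classified
by whether its substitutions relative to a reference change the encoded
protein; haplotypes are connected into a minimum spanning network over
Hamming distances (every edge belonging to at least one minimum
spanning tree is kept, so equally parsimonious connections survive);
and a phenotype is compared between haplotype groups with a two-sided
Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from Bio.Seq import Seq
from scipy import stats

_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)


def roman(n: int) -> str:
    if n < 1:
        raise ValueError("roman numerals start at 1")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


@dataclass(frozen=True)
class Haplotype:
    haplotype_id: str  # Roman numeral, by descending count then first occurrence
    sequence: str
    members: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GroupAngleComparison:
    median_a: float
    sd_a: float
    n_a: int
    median_b: float
    sd_b: float
    n_b: int
    statistic: float
    p_value: float


def _compatible(a: str, b: str) -> bool:
    return all(x == y or x == "N" or y == "N" for x, y in zip(a, b))


def collapse_haplotypes(
    panel: Mapping[str, str],
    max_missing_frac: float = 0.1,
) -> tuple[list[Haplotype], list[tuple[str, str]]]:
    """Group accessions with identical CDS sequences into haplotypes.

    N is missing data: accessions whose N fraction exceeds
    ``max_missing_frac`` are dropped (reported in the second return
    value), and an N-containing accession joins an N-free haplotype only
    when compatible with exactly one of them — ambiguous or unmatched
    sequences form their own haplotype keyed by their literal sequence,
    which keeps the partition invariant to the panel's row order.

    Haplotype IDs are Roman numerals assigned by descending member
    count, ties broken by first occurrence in the panel.
    """
    if not panel:
        raise ValueError("empty panel")
    lengths = {len(s) for s in panel.values()}
    if len(lengths) != 1:
        raise ValueError(f"panel sequences must be equal length, got lengths {sorted(lengths)}")

    dropped: list[tuple[str, str]] = []
    clean: dict[str, str] = {}
    for acc, seq in panel.items():
        seq = seq.upper()
        if seq.count("N") / len(seq) > max_missing_frac:
            dropped.append((acc, "too_much_missing_data"))
        else:
            clean[acc] = seq

    order = {acc: i for i, acc in enumerate(clean)}
    groups: dict[str, list[str]] = {}
    complete_sigs = sorted(
        {s for s in clean.values() if "N" not in s},
        key=lambda s: min(order[a] for a, q in clean.items() if q == s),
    )
    leftovers: dict[str, list[str]] = {}
    for acc, seq in clean.items():
        if "N" not in seq:
            groups.setdefault(seq, []).append(acc)
        else:
            matches = [s for s in complete_sigs if _compatible(seq, s)]
            if len(matches) == 1:
                groups.setdefault(matches[0], []).append(acc)
            else:
                leftovers.setdefault(seq, []).append(acc)
    groups.update(leftovers)

    ranked = sorted(
        groups.items(),
        key=lambda kv: (-len(kv[1]), min(order[a] for a in kv[1])),
    )
    return (
        [
            Haplotype(roman(i + 1), sig, tuple(sorted(members, key=order.get)))
            for i, (sig, members) in enumerate(ranked)
        ],
        dropped,
    )


def classify_haplotype(
    haplotype: Haplotype | str,
    reference_cds: str,
) -> tuple[str, list[str]]:
    """Label a haplotype missense or synonymous against a reference CDS.

    Returns the label and the substitution list in protein notation
    (e.g. ``F391L``); positions where either sequence has N are skipped.
    The label is "missense" iff at least one substitution changes the
    encoded amino acid (nonsense counts as protein-changing).
    """
    seq = haplotype.sequence if isinstance(haplotype, Haplotype) else haplotype
    if len(seq) != len(reference_cds):
        raise ValueError("haplotype and reference CDS lengths differ")
    if len(seq) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    subs: list[str] = []
    missense = False
    for codon_i in range(len(seq) // 3):
        ref_codon = reference_cds[3 * codon_i : 3 * codon_i + 3]
        alt_codon = seq[3 * codon_i : 3 * codon_i + 3]
        if alt_codon == ref_codon or "N" in alt_codon or "N" in ref_codon:
            continue
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if alt_aa != ref_aa:
            missense = True
            subs.append(f"{ref_aa}{codon_i + 1}{alt_aa}")
    return ("missense" if missense else "synonymous"), subs


def hamming(a: str, b: str) -> int:
    """Pairwise-deletion Hamming distance (positions with N excluded)."""
    if len(a) != len(b):
        raise ValueError("sequences must be equal length")
    return sum(1 for x, y in zip(a, b) if x != y and x != "N" and y != "N")


def build_parsimony_network(
    haplotypes: Sequence[Haplotype],
    connection_limit: int | None = None,
) -> nx.Graph:
    """Minimum spanning network over haplotype Hamming distances.

    Keeps every edge that appears in at least one minimum spanning tree
    (Kruskal with ties retained: an edge of weight w is kept iff its
    endpoints are disconnected in the graph of all strictly lighter
    kept edges). Edges heavier than ``connection_limit`` are then
    removed, which may disconnect the network.
    """
    g = nx.Graph()
    for h in haplotypes:
        g.add_node(h.haplotype_id, count=h.count, sequence=h.sequence)
    if len(haplotypes) < 2:
        return g

    edges = sorted(
        (
            (hamming(a.sequence, b.sequence), a.haplotype_id, b.haplotype_id)
            for i, a in enumerate(haplotypes)
            for b in haplotypes[i + 1 :]
        ),
        key=lambda e: e[0],
    )
    kept = nx.Graph()
    kept.add_nodes_from(g.nodes)
    i = 0
    while i < len(edges):
        w = edges[i][0]
        tier = []
        while i < len(edges) and edges[i][0] == w:
            tier.append(edges[i])
            i += 1
        # evaluate the whole tier against components of strictly lighter edges
        comp = {n: c for c, nodes in enumerate(nx.connected_components(kept)) for n in nodes}
        additions = [(u, v, w) for w, u, v in tier if comp[u] != comp[v]]
        for u, v, w_ in additions:
            kept.add_edge(u, v, weight=w_)

    if connection_limit is not None:
        heavy = [(u, v) for u, v, d in kept.edges(data=True) if d["weight"] > connection_limit]
        kept.remove_edges_from(heavy)
    for n, d in g.nodes(data=True):
        kept.nodes[n].update(d)
    return kept


def compare_angle_groups(
    angles_a: Sequence[float],
    angles_b: Sequence[float],
) -> GroupAngleComparison:
    """Median/SD per group and a two-sided Mann-Whitney U test."""
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(np.concatenate([a, b])) == 0.0:
        stat, p = len(a) * len(b) / 2.0, 1.0
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupAngleComparison(
        median_a=float(np.median(a)), sd_a=float(np.std(a, ddof=1)), n_a=len(a),
        median_b=float(np.median(b)), sd_b=float(np.std(b, ddof=1)), n_b=len(b),
        statistic=float(stat), p_value=float(p),
    )
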