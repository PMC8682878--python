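"""Mitochondrial haplotype collapsing, step distances, and networks.

Aligned whole-mitogenome sequences are collapsed into unique
haplotypes (ignoring positions where either sequence is ambiguous or
gapped), pairwise step distances are Hamming counts over mutually
unambiguous positions, and the haplotype network is a minimum spanning
tree over the complete step-distance graph with a deterministic
lexicographic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Haplotype",
    "read_alignment",
    "collapse_haplotypes",
    "step_distances",
    "minimum_spanning_network",
    "mutation_frequency",
    "shared_haplotypes",
    "sequences_from_vcf_subset",
]

_UNAMBIGUOUS = set("ACGT")


@dataclass
class Haplotype:
    hap_id: str
    sequence: str
    carriers: list[str] = field(default_factory=list)


def read_alignment(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA into (sample_id, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _comparable(a: str, b: str) -> np.ndarray:
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    ok = np.isin(arr_a, [c.encode() for c in _UNAMBIGUOUS]) & np.isin(
        arr_b, [c.encode() for c in _UNAMBIGUOUS]
    )
    return (arr_a != arr_b) & ok


def hamming_steps(a: str, b: str) -> int:
    """Nucleotide differences, excluding positions where either
    sequence is ambiguous (non-ACGT) or gapped."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    return int(_comparable(a, b).sum())


def collapse_haplotypes(records: list[tuple[str, str]]) -> list[Haplotype]:
    """Collapse sequences identical at all mutually unambiguous positions.

    Haplotypes are numbered H01, H02, ... in order of first appearance;
    carrier lists preserve input order.
    """
    lengths = {len(seq) for _, seq in records}
    if len(lengths) > 1:
        raise ValueError("sequences must be aligned to equal length")
    haplotypes: list[Haplotype] = []
    for sample_id, seq in records:
        for hap in haplotypes:
            if hamming_steps(hap.sequence, seq) == 0:
                hap.carriers.append(sample_id)
                break
        else:
            haplotypes.append(
                Haplotype(f"H{len(haplotypes) + 1:02d}", seq, [sample_id])
            )
    return haplotypes


def step_distances(haplotypes: list[Haplotype]) -> pd.DataFrame:
    """Symmetric integer step-distance matrix between haplotypes."""
    ids = [h.hap_id for h in haplotypes]
    n = len(haplotypes)
    dist = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = hamming_steps(
                haplotypes[i].sequence, haplotypes[j].sequence
            )
    return pd.DataFrame(dist, index=ids, columns=ids)


def minimum_spanning_network(distances: pd.DataFrame) -> list[tuple[str, str, int]]:
    """Minimum spanning tree edges (hap_i, hap_j, steps), Kruskal with a
    lexicographic tie-break on the haplotype-id pair for determinism."""
    ids = list(distances.index)
    g = nx.Graph()
    g.add_nodes_from(ids)
    edges = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            edges.append((int(distances.loc[a, b]), a, b))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    for w, a, b in edges:
        g.add_edge(a, b, weight=w)
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    return sorted((a, b, g.edges[a, b]["weight"]) for a, b in mst.edges)


def mutation_frequency(steps: int, seq_length_bp: int) -> tuple[float, float]:
    """Steps as a percent of the sequence length.

    Returns ``(full precision, rounded to 1 significant figure)`` —
    e.g. 19 steps over 16,822 bp is 0.1130%, reported as 0.1%.
    """
    if seq_length_bp <= 0:
        raise ValueError("sequence length must be positive")
    if steps < 0:
        raise ValueError("steps must be nonnegative")
    pct = steps / seq_length_bp * 100.0
    if pct == 0:
        return 0.0, 0.0
    exponent = int(np.floor(np.log10(abs(pct))))
    rounded = round(pct, -exponent)
    return pct, rounded


def shared_haplotypes(
    haplotypes: list[Haplotype], group_labels: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Haplotype sharing between groups.

    Returns ``(sharing, nearest)``: the sharing table lists each
    haplotype with its per-group carrier counts and whether it spans
    more than one group; the nearest table gives, per group pair, the
    minimum step distance between haplotypes private to each side.
    """
    groups = sorted(set(group_labels.values()))
    rows = []
    hap_groups: dict[str, set[str]] = {}
    for hap in haplotypes:
        counts = {g: 0 for g in groups}
        for s in hap.carriers:
            counts[group_labels[s]] += 1
        present = {g for g, c in counts.items() if c > 0}
        hap_groups[hap.hap_id] = present
        rows.append({"hap_id": hap.hap_id, **counts, "shared": len(present) > 1})
    sharing = pd.DataFrame(rows)
    dist = step_distances(haplotypes)
    near_rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            only1 = [h.hap_id for h in haplotypes if hap_groups[h.hap_id] == {g1}]
            only2 = [h.hap_id for h in haplotypes if hap_groups[h.hap_id] == {g2}]
            if only1 and only2:
                best = min(int(dist.loc[a, b]) for a in only1 for b in only2)
            else:
                best = np.nan
            near_rows.append({"group1": g1, "group2": g2, "min_unshared_steps": best})
    return sharing, pd.DataFrame(near_rows)


def sequences_from_vcf_subset(gm, reference: str, contig: str) -> list[tuple[str, str]]:
    """Rebuild per-sample mitochondrial sequences from a reference plus
    the VCF variant subset on the given contig.

    Mitochondria are effectively haploid; a sample's base at a variant
    site is the alt allele when its dosage is >= 1, the reference
    otherwise, and 'N' when missing.
    """
    mask = (gm.variants["chrom"] == contig).to_numpy()
    sub = gm.take_variants(mask)
    seqs = []
    ref = list(reference.upper())
    for i, sample in enumerate(sub.sample_ids):
        seq = ref.copy()
        for j, row in enumerate(sub.variants.itertuples(index=False)):
            d = sub.dosage[i, j]
            if d == -1:
                seq[row.pos - 1] = "N"
            elif d >= 1:
                seq[row.pos - 1] = row.alt
        seqs.append((sample, "".join(seq)))
    return seqs
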