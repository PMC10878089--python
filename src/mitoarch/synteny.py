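"""Collinearity between mitogenome pairs.

Synteny is detected transparently: exact k-mer matches (default k = 15, both
orientations) are merged along diagonals into maximal exact-match anchors,
then chained into collinear blocks when consecutive co-oriented anchors are
separated by at most ``max_gap`` on both genomes. Telomere and central-repeat
intervals can be masked beforehand, since terminal repeats produce spurious
self-similarity. Block totals per genome pair and per species group, plus a
census of blocks above a length threshold (default 2.5 kbp), summarize how
much collinear sequence survives between divergent genomes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._genetics import revcomp
from .io import GeneOrder, Mitogenome


@dataclass(frozen=True)
class Anchor:
    g1_start: int
    g1_end: int
    g2_start: int
    g2_end: int
    orientation: str = "same"  # "same" | "inverted"
    identity: float = 1.0
    kind: str = "kmer"

    @property
    def length(self) -> int:
        return self.g1_end - self.g1_start


@dataclass
class SyntenyBlock:
    anchors: list[Anchor]
    orientation: str

    @property
    def g1_span(self) -> tuple[int, int]:
        return (min(a.g1_start for a in self.anchors),
                max(a.g1_end for a in self.anchors))

    @property
    def g2_span(self) -> tuple[int, int]:
        return (min(a.g2_start for a in self.anchors),
                max(a.g2_end for a in self.anchors))

    @property
    def length(self) -> int:
        s, e = self.g1_span
        return e - s


def _seq(g) -> str:
    return g.sequence if isinstance(g, Mitogenome) else str(g)


def _masked(seq: str, mask: list[tuple[int, int]] | None) -> str:
    if not mask:
        return seq
    chars = list(seq)
    for s, e in mask:
        for i in range(max(s, 0), min(e, len(chars))):
            chars[i] = "N"
    return "".join(chars)


def _kmer_hits(s1: str, s2: str, k: int) -> list[tuple[int, int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(s1) - k + 1):
        kmer = s1[i:i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    hits = []
    for j in range(len(s2) - k + 1):
        kmer = s2[j:j + k]
        if "N" in kmer:
            continue
        for i in index.get(kmer, ()):
            hits.append((i, j))
    return hits


def _merge_diagonal(hits: list[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    """Merge overlapping/adjacent k-mer hits on the same diagonal into
    maximal runs; returns (g1_start, g2_start, length)."""
    by_diag: dict[int, list[int]] = {}
    for i, j in hits:
        by_diag.setdefault(j - i, []).append(i)
    runs = []
    for diag, starts in by_diag.items():
        starts.sort()
        run_start = prev = starts[0]
        for s in starts[1:]:
            if s <= prev + k:
                prev = s
            else:
                runs.append((run_start, run_start + diag, prev + k - run_start))
                run_start = prev = s
        runs.append((run_start, run_start + diag, prev + k - run_start))
    return runs


def find_anchors(
    g1,
    g2,
    mode: str = "kmer",
    k: int = 15,
    min_identity: float = 1.0,
    mask1: list[tuple[int, int]] | None = None,
    mask2: list[tuple[int, int]] | None = None,
    orders: tuple[GeneOrder, GeneOrder] | None = None,
) -> list[Anchor]:
    """Anchors between two genomes.

    ``kmer`` mode reports maximal exact matches of length >= k in both
    orientations (masked intervals excluded). ``orthologs`` mode pairs
    single-copy shared genes from the two gene orders.
    """
    if mode == "orthologs":
        if orders is None:
            raise ValueError("orthologs mode needs the two gene orders")
        o1, o2 = orders
        g1_feats = {f.name: f for f in g1.features}
        g2_feats = {f.name: f for f in g2.features}
        shared = set(o1.labels) & set(o2.labels)
        anchors = []
        for name in sorted(shared):
            f1, f2 = g1_feats.get(name), g2_feats.get(name)
            if f1 is None or f2 is None:
                continue
            anchors.append(Anchor(
                g1_start=f1.start, g1_end=f1.end,
                g2_start=f2.start, g2_end=f2.end,
                orientation="same" if f1.strand == f2.strand else "inverted",
                kind="gene",
            ))
        return anchors
    if mode != "kmer":
        raise ValueError(f"unknown anchor mode {mode!r}")

    s1 = _masked(_seq(g1).upper(), mask1)
    s2 = _masked(_seq(g2).upper(), mask2)
    anchors = []
    for orientation, target in (("same", s2), ("inverted", revcomp(s2))):
        runs = _merge_diagonal(_kmer_hits(s1, target, k), k)
        for i, j, length in runs:
            if orientation == "same":
                g2s, g2e = j, j + length
            else:
                g2s, g2e = len(s2) - (j + length), len(s2) - j
            anchors.append(Anchor(
                g1_start=i, g1_end=i + length, g2_start=g2s, g2_end=g2e,
                orientation=orientation, identity=1.0, kind="kmer",
            ))
    anchors.sort(key=lambda a: (a.g1_start, a.g1_end, a.g2_start))
    return anchors


def chain_blocks(anchors: list[Anchor], max_gap: int = 1000) -> list[SyntenyBlock]:
    """Chain co-oriented anchors into collinear blocks.

    Anchors join a chain when the gap to the previous anchor is <= max_gap
    on both genomes and coordinates advance consistently with the chain
    orientation (g2 decreasing for inverted chains). Candidate chains whose
    g1 spans overlap are resolved greedily by total anchor length (ties by
    leftmost start).
    """
    chains: list[SyntenyBlock] = []
    for orientation in ("same", "inverted"):
        subset = sorted(
            (a for a in anchors if a.orientation == orientation),
            key=lambda a: (a.g1_start, a.g1_end),
        )
        open_chains: list[list[Anchor]] = []
        for a in subset:
            placed = False
            for chain in open_chains:
                last = chain[-1]
                gap1 = a.g1_start - last.g1_end
                if gap1 < 0 or gap1 > max_gap:
                    continue
                if orientation == "same":
                    gap2 = a.g2_start - last.g2_end
                else:
                    gap2 = last.g2_start - a.g2_end
                if 0 <= gap2 <= max_gap:
                    chain.append(a)
                    placed = True
                    break
            if not placed:
                open_chains.append([a])
        chains.extend(
            SyntenyBlock(anchors=c, orientation=orientation) for c in open_chains
        )

    # greedy overlap resolution on genome-1 coordinates
    chains.sort(
        key=lambda b: (-sum(a.length for a in b.anchors), b.g1_span[0])
    )
    chosen: list[SyntenyBlock] = []
    for b in chains:
        s, e = b.g1_span
        if all(e <= c.g1_span[0] or c.g1_span[1] <= s for c in chosen):
            chosen.append(b)
    chosen.sort(key=lambda b: b.g1_span[0])
    return chosen


def block_summary(
    blocks_by_pair: dict[tuple[str, str], list[SyntenyBlock]],
    group_labels: dict[str, str] | None = None,
    long_threshold: int = 2500,
) -> dict[str, pd.DataFrame]:
    """Per-pair totals, per-group means, and long-block census.

    Totals are measured on the first genome's coordinates. A pair belongs to
    a group when both genomes carry that group label; cross-group pairs are
    labelled ``between``.
    """
    rows = []
    for (a, b), blocks in blocks_by_pair.items():
        total = sum(bl.length for bl in blocks)
        n_long = sum(1 for bl in blocks if bl.length > long_threshold)
        if group_labels:
            ga, gb = group_labels.get(a), group_labels.get(b)
            group = ga if ga == gb else "between"
        else:
            group = "all"
        rows.append({
            "genome_1": a, "genome_2": b, "total_bp": total,
            "n_blocks": len(blocks), "n_long_blocks": n_long, "group": group,
        })
    pairs = pd.DataFrame(rows)
    groups = (
        pairs.groupby("group")
        .agg(mean_total_bp=("total_bp", "mean"),
             n_pairs=("total_bp", "count"),
             n_long_blocks=("n_long_blocks", "sum"))
        .reset_index()
    )
    return {"per_pair": pairs, "per_group": groups}
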