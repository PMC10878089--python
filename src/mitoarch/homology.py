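"""Orthology, core genes, concatenated alignments and distance trees.

Comparative mitogenomics starts from orthogroups — clusters of homologous
genes across genomes. Two grouping modes are offered: ``by_name`` trusts the
annotation labels, and ``rbh`` clusters reciprocal best hits under global
protein alignment (BLOSUM62, affine gaps) by single linkage. Core genes are
the single-copy orthogroups present in every genome; their protein-guided
codon alignments are concatenated (with partition boundaries recorded) and
summarized by a neighbor-joining tree with column-resampling bootstrap.

Maximum-likelihood inference and clock dating are deliberately out of scope:
the concatenated alignment and a partition file are exported for external
tools instead.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from ._genetics import DEFAULT_TABLE
from .io import Mitogenome, translate_cds
from .selection import _protein_aligner, _strip_terminal_stop, _check_translatable


class EmptyProteomeError(ValueError):
    pass


class MissingSequenceError(ValueError):
    pass


class UndefinedDistanceError(ValueError):
    pass


@dataclass
class Orthogroup:
    id: str
    members: list[tuple[str, str]]  # (genome_id, gene label)
    representative: str = ""

    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}

    def single_copy_in(self, n_genomes: int) -> bool:
        gs = [g for g, _ in self.members]
        return len(gs) == n_genomes and len(set(gs)) == n_genomes


@dataclass
class CoreGeneSet:
    orthogroup_ids: list[str]

    @property
    def count(self) -> int:
        return len(self.orthogroup_ids)


@dataclass
class ConcatAlignment:
    taxa: list[str]
    blocks: dict[str, dict[str, str]]  # gene -> taxon -> aligned codon row
    partitions: list[int]  # cumulative end column (nt) per gene block

    def row(self, taxon: str) -> str:
        return "".join(self.blocks[g][taxon] for g in self.blocks)

    @property
    def total_columns(self) -> int:
        return self.partitions[-1] if self.partitions else 0

    def variable_columns(self) -> int:
        rows = [self.row(t) for t in self.taxa]
        return sum(
            1 for i in range(len(rows[0]))
            if len({r[i] for r in rows} - {"-", "N"}) > 1
        )


def get_proteome(genome: Mitogenome, table: int = DEFAULT_TABLE) -> dict[str, str]:
    """Translated PCG products of a genome, keyed by gene label."""
    prots = {}
    for f in genome.features:
        if f.category == "PCG":
            cds = genome.feature_seq(f)
            prots[f.name] = translate_cds(cds, table)
    return prots


def _best_hits(
    query: dict[str, str], subject: dict[str, str]
) -> dict[str, str]:
    """Best subject label per query protein (global BLOSUM62 score,
    ties broken lexicographically)."""
    aligner = _protein_aligner()
    out = {}
    for qname, qseq in query.items():
        best = None
        for sname in sorted(subject):
            score = aligner.score(qseq, subject[sname])
            if best is None or score > best[0]:
                best = (score, sname)
        out[qname] = best[1]
    return out


def infer_orthogroups(
    genomes: list[Mitogenome],
    mode: str = "by_name",
    table: int = DEFAULT_TABLE,
) -> list[Orthogroup]:
    """Orthogroups across >= 2 genomes.

    ``by_name`` groups identical gene labels; ``rbh`` computes reciprocal
    best hits between every genome pair and takes single-linkage components
    over the RBH edges.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    proteomes = {}
    for g in genomes:
        p = get_proteome(g, table)
        if not p:
            raise EmptyProteomeError(f"genome {g.id!r} has no translated PCGs")
        proteomes[g.id] = p

    nodes = [(gid, name) for gid, prots in proteomes.items() for name in prots]
    parent = {n: n for n in nodes}

    def find(n):
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    if mode == "by_name":
        by_label: dict[str, list[tuple[str, str]]] = {}
        for gid, name in nodes:
            by_label.setdefault(name, []).append((gid, name))
        for members in by_label.values():
            for m in members[1:]:
                union(members[0], m)
    elif mode == "rbh":
        gids = sorted(proteomes)
        for i, a in enumerate(gids):
            for b in gids[i + 1:]:
                fwd = _best_hits(proteomes[a], proteomes[b])
                rev = _best_hits(proteomes[b], proteomes[a])
                for qa, sb in fwd.items():
                    if rev.get(sb) == qa:
                        union((a, qa), (b, sb))
    else:
        raise ValueError(f"unknown orthogrouping mode {mode!r}")

    comps: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for n in nodes:
        comps.setdefault(find(n), []).append(n)
    groups = []
    ordered = sorted(comps.values(), key=lambda ms: (min(m[1] for m in ms), ms))
    for i, members in enumerate(ordered, start=1):
        labels = sorted(m[1] for m in members)
        rep = max(set(labels), key=lambda x: (labels.count(x), x))
        groups.append(Orthogroup(
            id=f"OG{i:04d}", members=sorted(members), representative=rep
        ))
    return groups


def core_genes(orthogroups: list[Orthogroup], n_genomes: int) -> CoreGeneSet:
    """Single-copy orthogroups present in all genomes."""
    return CoreGeneSet([
        og.id for og in orthogroups if og.single_copy_in(n_genomes)
    ])


def _align_proteins_msa(prots: dict[str, str]) -> dict[str, str]:
    """Multiple protein alignment; pairwise for 2 taxa, mafft otherwise."""
    taxa = sorted(prots)
    if len({prots[t] for t in taxa}) == 1 or len({len(prots[t]) for t in taxa}) == 1:
        # equal-length (or identical) proteins need no gaps
        return {t: prots[t] for t in taxa}
    if len(taxa) == 2:
        aln = _protein_aligner().align(prots[taxa[0]], prots[taxa[1]])[0]
        return {taxa[0]: str(aln[0]), taxa[1]: str(aln[1])}
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.faa"
        fin.write_text("".join(f">{t}\n{prots[t]}\n" for t in taxa))
        res = subprocess.run(
            ["mafft", "--auto", "--quiet", "--anysymbol", str(fin)],
            capture_output=True, text=True, check=True,
        )
    out: dict[str, str] = {}
    cur = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            cur = line[1:].split()[0]
            out[cur] = ""
        elif cur is not None:
            out[cur] += line.strip()
    return out


def _back_translate(aligned_prot: str, cds: str) -> str:
    out, i = [], 0
    for aa in aligned_prot:
        if aa == "-":
            out.append("---")
        else:
            out.append(cds[3 * i:3 * i + 3])
            i += 1
    return "".join(out)


def concat_core_alignment(
    core: CoreGeneSet,
    sequences: dict[str, dict[str, str]],
    table: int = DEFAULT_TABLE,
    taxa: list[str] | None = None,
) -> ConcatAlignment:
    """Concatenated protein-guided codon alignments of the core genes.

    ``sequences`` maps orthogroup id -> taxon -> CDS. Every core gene must
    have a sequence for every taxon (the union over genes when ``taxa`` is
    not given); partition boundaries (cumulative end columns, nt) are
    recorded per gene.
    """
    if taxa is None:
        taxa = sorted({t for og in core.orthogroup_ids for t in sequences.get(og, {})})
    else:
        taxa = sorted(taxa)
    missing = [
        (t, og) for og in core.orthogroup_ids for t in taxa
        if t not in sequences.get(og, {})
    ]
    if missing:
        raise MissingSequenceError(f"missing sequences for: {missing}")
    blocks: dict[str, dict[str, str]] = {}
    partitions: list[int] = []
    total = 0
    for og in core.orthogroup_ids:
        cds = {
            t: _strip_terminal_stop(
                _check_translatable(sequences[og][t].upper(), f"{og}/{t}", table),
                table,
            )
            for t in taxa
        }
        prots = {t: translate_cds(cds[t], table) for t in taxa}
        aligned = _align_proteins_msa(prots)
        blocks[og] = {t: _back_translate(aligned[t], cds[t]) for t in taxa}
        total += len(next(iter(blocks[og].values())))
        partitions.append(total)
    return ConcatAlignment(taxa=taxa, blocks=blocks, partitions=partitions)


def _pairwise_distance(a: str, b: str, distance: str) -> float:
    pairs = [
        (x, y) for x, y in zip(a, b)
        if x in "ACGT" and y in "ACGT"
    ]
    if not pairs:
        raise UndefinedDistanceError("no jointly resolved columns")
    p = sum(x != y for x, y in pairs) / len(pairs)
    if distance == "p_dist":
        return p
    if distance == "jc69":
        if p >= 0.75:
            raise UndefinedDistanceError(f"JC69 saturated (p = {p:.3f})")
        return -0.75 * np.log(1 - 4 * p / 3)
    raise ValueError(f"unknown distance {distance!r}")


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    bips = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            other = taxa - side
            bips.add(min(side, other, key=sorted))
    return bips


def nj_tree(
    alignment: ConcatAlignment,
    distance: str = "p_dist",
    bootstrap_n: int = 0,
    seed: int | None = None,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Neighbor-joining tree with optional column-resampling bootstrap.

    Returns the tree (branch lengths from the full alignment) and a mapping
    bipartition -> support percentage; supports are also written onto the
    internal nodes. Bootstrap resamples alignment columns with a fixed seed,
    so identical seeds give identical supports.
    """
    taxa = alignment.taxa
    if len(taxa) < 3:
        raise ValueError("need at least three taxa")
    rows = {t: alignment.row(t) for t in taxa}

    def dm_from_columns(cols: np.ndarray | None) -> DistanceMatrix:
        if cols is None:
            seqs = rows
        else:
            seqs = {
                t: "".join(rows[t][i] for i in cols) for t in taxa
            }
        mat = np.zeros((len(taxa), len(taxa)))
        for i, a in enumerate(taxa):
            for j in range(i + 1, len(taxa)):
                d = _pairwise_distance(seqs[a], seqs[taxa[j]], distance)
                mat[i, j] = mat[j, i] = d
        return DistanceMatrix(mat, ids=taxa)

    tree = nj(dm_from_columns(None))
    taxa_set = frozenset(taxa)
    support: dict[frozenset[str], float] = {
        bip: 0.0 for bip in _bipartitions(tree, taxa_set)
    }
    if bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        L = alignment.total_columns
        for _ in range(bootstrap_n):
            cols = rng.integers(0, L, size=L)
            try:
                bt = nj(dm_from_columns(cols))
            except UndefinedDistanceError:
                continue
            for bip in _bipartitions(bt, taxa_set):
                if bip in support:
                    support[bip] += 1
        support = {k: 100.0 * v / bootstrap_n for k, v in support.items()}
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            key = min(side, taxa_set - side, key=sorted)
            if key in support:
                node.name = f"{support[key]:.0f}"
    return tree, support


def write_phylip(alignment: ConcatAlignment, path) -> None:
    """Relaxed PHYLIP export of the concatenated alignment."""
    with open(path, "w") as fh:
        fh.write(f" {len(alignment.taxa)} {alignment.total_columns}\n")
        for t in alignment.taxa:
            fh.write(f"{t}  {alignment.row(t)}\n")


def write_partitions(alignment: ConcatAlignment, path) -> None:
    """RAxML-style partition file (DNA, one charset per gene block)."""
    with open(path, "w") as fh:
        start = 1
        for gene, end in zip(alignment.blocks, alignment.partitions):
            fh.write(f"DNA, {gene} = {start}-{end}\n")
            start = end + 1
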