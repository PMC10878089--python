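"""Mitogenome input/output, gene orders and region-level composition.

Linear mitochondrial genomes arrive as a FASTA sequence plus feature
annotations in GFF3 or GenBank flat-file form. Internally every interval is
0-based half-open; GFF3's 1-based inclusive coordinates are converted on the
way in and restored on the way out.

Feature categories follow the functional classes used for ciliate
mitogenomes: protein-coding genes (PCG), tRNA, rRNA, terminal telomeric
repeats, the AT-rich central repeat (CR) region, and everything else.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

from ._genetics import DEFAULT_TABLE, codon_table, revcomp, stop_codons

CATEGORIES = ("PCG", "tRNA", "rRNA", "telomere", "central_repeat", "other")

#: base-attribution priority for region accounting (highest first);
#: intergenic is whatever no feature covers
REGION_PRIORITY = ("telomere", "central_repeat", "PCG", "rRNA", "tRNA", "other")

_GFF_TYPE_TO_CATEGORY = {
    "CDS": "PCG",
    "gene": "PCG",
    "mRNA": "PCG",
    "protein_coding_gene": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "telomere": "telomere",
    "repeat_region": "central_repeat",
}

_CATEGORY_TO_GFF_TYPE = {
    "PCG": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "telomere": "telomere",
    "central_repeat": "repeat_region",
    "other": "region",
}


class MalformedAnnotationError(ValueError):
    """Annotation refers to a missing contig, bad coordinates or bad strand."""


class EmptyOrderError(ValueError):
    """No features matched the requested categories."""


class InternalStopWarning(UserWarning):
    """A CDS translation contained an internal stop codon."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated interval on a mitogenome (0-based, half-open)."""

    name: str
    category: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.name}")
        if self.strand not in "+-":
            raise MalformedAnnotationError(
                f"feature {self.name!r}: unknown strand symbol {self.strand!r}"
            )
        if not 0 <= self.start < self.end:
            raise MalformedAnnotationError(
                f"feature {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.category == "PCG" and self.end - self.start < 3:
            raise MalformedAnnotationError(
                f"feature {self.name!r}: PCG shorter than one codon"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Mitogenome:
    """A linear (or circular) mitochondrial genome with ordered features."""

    id: str
    sequence: str
    topology: str = "linear"
    features: list[GeneFeature] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        self.sequence = self.sequence.upper()
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        for f in self.features:
            if f.end > len(self.sequence):
                raise MalformedAnnotationError(
                    f"feature {f.name!r} end {f.end} beyond genome length "
                    f"{len(self.sequence)}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.name))

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_seq(self, feat: GeneFeature) -> str:
        """Coding-strand sequence of a feature."""
        s = self.sequence[feat.start:feat.end]
        return revcomp(s) if feat.strand == "-" else s


@dataclass
class GeneOrder:
    """Signed gene order: ordered (label, strand) pairs plus the label universe."""

    genome_id: str
    elements: list[tuple[str, str]]
    universe: frozenset[str] = frozenset()

    def __post_init__(self):
        labels = [g for g, _ in self.elements]
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate gene labels in order for {self.genome_id}")
        if not self.universe:
            self.universe = frozenset(labels)

    @property
    def labels(self) -> list[str]:
        return [g for g, _ in self.elements]

    def strand_of(self, label: str) -> str:
        for g, s in self.elements:
            if g == label:
                return s
        raise KeyError(label)


@dataclass(frozen=True)
class RegionStats:
    region: str  # PCG / tRNA / rRNA / telomere / central_repeat / intergenic
    length: int
    fraction: float
    gc: float


def _disambiguate(names: list[str]) -> list[str]:
    """Suffix duplicate labels positionally: nad1, nad1 -> nad1_a, nad1_b."""
    counts: dict[str, int] = {}
    for n in names:
        counts[n] = counts.get(n, 0) + 1
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if counts[n] == 1:
            out.append(n)
        else:
            i = seen.get(n, 0)
            seen[n] = i + 1
            out.append(f"{n}_{chr(ord('a') + i)}")
    return out


def _features_from_gff3(path: str, seq_id: str, seq_len: int) -> list[GeneFeature]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    for f in db.all_features():
        if f.seqid != seq_id:
            raise MalformedAnnotationError(
                f"annotation contig {f.seqid!r} absent from FASTA (expected {seq_id!r})"
            )
        name = (f.attributes.get("Name") or f.attributes.get("ID") or
                f.attributes.get("gene") or [f.id])[0]
        category = _GFF_TYPE_TO_CATEGORY.get(f.featuretype, "other")
        start, end = f.start - 1, f.end  # 1-based inclusive -> 0-based half-open
        if not 0 <= start < end <= seq_len:
            raise MalformedAnnotationError(
                f"feature {name!r}: coordinates {f.start}..{f.end} out of range "
                f"for {seq_len} bp genome"
            )
        if f.strand not in "+-":
            raise MalformedAnnotationError(
                f"feature {name!r}: unknown strand symbol {f.strand!r}"
            )
        feats.append((start, end, name, category, f.strand))
    feats.sort()
    names = _disambiguate([n for _, _, n, _, _ in feats])
    return [
        GeneFeature(name=nm, category=c, start=s, end=e, strand=st)
        for (s, e, _, c, st), nm in zip(feats, names)
    ]


_GENBANK_TYPE_TO_CATEGORY = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "telomere": "telomere",
}


def _features_from_genbank(path: str, seq_len: int) -> list[GeneFeature]:
    rec = SeqIO.read(path, "genbank")
    feats = []
    for f in rec.features:
        if f.type == "source":
            continue
        if f.type == "repeat_region":
            rpt = (f.qualifiers.get("rpt_type") or ["central_repeat"])[0]
            category = "telomere" if rpt == "telomere" else "central_repeat"
        else:
            category = _GENBANK_TYPE_TO_CATEGORY.get(f.type)
            if category is None:
                if f.type == "gene":
                    continue  # gene/CDS pairs: keep the CDS only
                category = "other"
        name = (f.qualifiers.get("gene") or f.qualifiers.get("product")
                or f.qualifiers.get("locus_tag") or [f.type])[0]
        start, end = int(f.location.start), int(f.location.end)
        if not 0 <= start < end <= seq_len:
            raise MalformedAnnotationError(
                f"feature {name!r}: coordinates out of range for {seq_len} bp genome"
            )
        strand = "-" if f.location.strand == -1 else "+"
        feats.append((start, end, name, category, strand))
    feats.sort()
    names = _disambiguate([n for _, _, n, _, _ in feats])
    return [
        GeneFeature(name=nm, category=c, start=s, end=e, strand=st)
        for (s, e, _, c, st), nm in zip(feats, names)
    ]


def read_mitogenome(
    fasta_path: str | os.PathLike | None,
    annotation_path: str | os.PathLike,
    dialect: str = "gff3",
    topology: str = "linear",
) -> Mitogenome:
    """Read a mitogenome from FASTA + GFF3, or from a GenBank flat file.

    For ``dialect="genbank"`` the sequence embedded in the flat file is used
    when ``fasta_path`` is None.
    """
    if dialect == "gff3":
        rec = SeqIO.read(str(fasta_path), "fasta")
        seq = str(rec.seq)
        feats = _features_from_gff3(str(annotation_path), rec.id, len(seq))
        gid = rec.id
    elif dialect == "genbank":
        gb = SeqIO.read(str(annotation_path), "genbank")
        if fasta_path is not None:
            rec = SeqIO.read(str(fasta_path), "fasta")
            if rec.id != gb.id and rec.id != gb.name:
                raise MalformedAnnotationError(
                    f"GenBank record {gb.id!r} does not match FASTA id {rec.id!r}"
                )
            seq, gid = str(rec.seq), rec.id
        else:
            seq, gid = str(gb.seq), gb.id
        feats = _features_from_genbank(str(annotation_path), len(seq))
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return Mitogenome(
        id=gid, sequence=seq, topology=topology, features=feats,
        source=str(annotation_path),
    )


def write_mitogenome(genome: Mitogenome, fasta_path, gff_path) -> None:
    """Write FASTA plus GFF3 (1-based inclusive) for a mitogenome."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.id}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for f in genome.features:
            ftype = _CATEGORY_TO_GFF_TYPE[f.category]
            fh.write(
                f"{genome.id}\tmito-arch\t{ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.name};Name={f.name}\n"
            )


def extract_gene_order(
    genome: Mitogenome, categories: frozenset[str] = frozenset({"PCG", "tRNA", "rRNA"})
) -> GeneOrder:
    """Signed gene order of the features in the given categories, by start."""
    feats = [f for f in genome.features if f.category in categories]
    if not feats:
        raise EmptyOrderError(
            f"genome {genome.id!r} has no features in categories {sorted(categories)}"
        )
    feats.sort(key=lambda f: f.start)
    return GeneOrder(
        genome_id=genome.id, elements=[(f.name, f.strand) for f in feats]
    )


def region_stats(
    genome: Mitogenome, exclude_telomeres: bool = False
) -> list[RegionStats]:
    """Per-class length, genome fraction and GC content.

    Each base is attributed to exactly one class, overlapping features
    resolved by priority (telomere > CR > PCG > rRNA > tRNA > other);
    uncovered bases are intergenic, so class lengths always sum to the genome
    length. With ``exclude_telomeres`` the fraction denominator is the
    genome length minus telomeric bases (telomere fraction itself stays
    relative to the full length).
    """
    L = len(genome)
    codes = {c: i + 1 for i, c in enumerate(REGION_PRIORITY)}
    cover = np.zeros(L, dtype=np.int8)  # 0 = intergenic
    # paint lowest priority first so higher priorities overwrite
    for cat in reversed(REGION_PRIORITY):
        for f in genome.features:
            if f.category == cat:
                cover[f.start:f.end] = codes[cat]
    seq = np.frombuffer(genome.sequence.encode(), dtype="S1")
    is_gc = (seq == b"G") | (seq == b"C")
    is_known = is_gc | (seq == b"A") | (seq == b"T")

    telomere_len = int(np.sum(cover == codes["telomere"]))
    denom = L - telomere_len if exclude_telomeres else L

    out = []
    for cat in list(REGION_PRIORITY) + ["intergenic"]:
        mask = cover == (codes[cat] if cat != "intergenic" else 0)
        length = int(mask.sum())
        known = int((mask & is_known).sum())
        gc = float((mask & is_gc).sum() / known) if known else float("nan")
        if cat == "telomere" or not exclude_telomeres:
            frac = length / L
        else:
            frac = length / denom if denom else float("nan")
        out.append(RegionStats(region=cat, length=length, fraction=frac, gc=gc))
    return out


def translate_cds(seq: str, table: int = DEFAULT_TABLE) -> str:
    """Translate a CDS; terminal stop stripped, internal stop warned.

    A trailing partial codon is trimmed. Internal stops are rendered as ``*``
    and flagged with :class:`InternalStopWarning` — they usually indicate an
    annotation in need of review, not a fatal input.
    """
    seq = seq.upper()
    seq = seq[: len(seq) - len(seq) % 3]
    if not seq:
        return ""
    stops = stop_codons(table)
    fwd = codon_table(table).forward_table
    aas = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if codon in stops:
            aas.append("*")
        else:
            aas.append(fwd.get(codon, "X"))
    if aas and aas[-1] == "*":
        aas.pop()
    prot = "".join(aas)
    if "*" in prot:
        warnings.warn(
            f"internal stop codon at protein position {prot.index('*') + 1}",
            InternalStopWarning,
            stacklevel=2,
        )
    return prot


def stop_codon_usage(genomes: list[Mitogenome], table: int = DEFAULT_TABLE):
    """Per-genome counts of terminal stop codons over annotated PCGs.

    Returns a DataFrame indexed by genome id with columns TAA/TAG/other.
    Under translation table 4 only TAA and TAG terminate; any PCG whose
    annotated terminal codon is neither is counted as "other".
    """
    import pandas as pd

    rows = {}
    for g in genomes:
        counts = {"TAA": 0, "TAG": 0, "other": 0}
        for f in g.features:
            if f.category != "PCG":
                continue
            cds = g.feature_seq(f)
            term = cds[len(cds) - len(cds) % 3 - 3:][:3] if len(cds) % 3 else cds[-3:]
            counts[term if term in ("TAA", "TAG") else "other"] += 1
        rows[g.id] = counts
    return pd.DataFrame.from_dict(rows, orient="index").astype(int)
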