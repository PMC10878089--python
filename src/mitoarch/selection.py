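"""Selection-pressure profiling of mitochondrial protein-coding genes.

Ka/Ks (dN/dS) — the ratio of nonsynonymous to synonymous substitution rates —
is estimated with the Nei-Gojobori (1986) counting method: per-codon
synonymous/nonsynonymous site fractions averaged over the two sequences,
pathway-averaged difference counts for codons differing at more than one
position, and a Jukes-Cantor multiple-hit correction of the proportions.
Ratios below 1 indicate purifying selection; mitochondrial electron-transport
genes are typically far more constrained than ribosomal-protein or
lineage-specific genes.

Codon alignments are built protein-first: a global amino-acid alignment
(BLOSUM62, affine gaps) is back-translated so gaps always occupy whole
codons. Sliding-window series localize selection shifts along a gene, and
per-family/per-pair summaries plus a regression of Ka/Ks on rearrangement
frequency reproduce the genome-wide comparative analyses.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from ._genetics import (
    BASES,
    DEFAULT_TABLE,
    sense_codons,
    stop_codons,
    translate_codon,
)
from .io import translate_cds

#: default gene-family assignment by label prefix
FAMILY_PREFIXES = {
    "nad": "nad", "cob": "cob", "cox": "cox", "atp": "atp",
    "rpl": "rpg", "rps": "rpg", "ymf": "ymf",
}


class UntranslatableCDSError(ValueError):
    pass


@dataclass
class CodonAlignment:
    """Codon-aligned nucleotide rows (gaps in whole codons)."""

    rows: list[str]
    gene: str = ""
    table: int = DEFAULT_TABLE

    def __post_init__(self):
        lens = {len(r) for r in self.rows}
        if len(lens) != 1:
            raise ValueError("alignment rows differ in length")
        (L,) = lens
        if L % 3:
            raise ValueError("alignment length not divisible by 3")
        for r in self.rows:
            for i in range(0, L, 3):
                c = r[i:i + 3]
                if "-" in c and c != "---":
                    raise ValueError(f"gap not codon-aligned at column {i}")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3

    def codon_columns(self) -> list[tuple[str, ...]]:
        return [
            tuple(r[i:i + 3] for r in self.rows)
            for i in range(0, len(self.rows[0]), 3)
        ]

    def gap_free_codon_count(self) -> int:
        return sum(
            1 for col in self.codon_columns()
            if all(c != "---" and set(c) <= set(BASES) for c in col)
        )


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: float  # NaN when Ks == 0 or saturated
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    codons: int
    method: str = "NG86"
    saturated: bool = False


@dataclass
class WindowSeries:
    starts: list[int]  # window start, codon units on alignment coordinates
    results: list[KaKsResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "start_codon": self.starts,
            "ka": [r.ka for r in self.results],
            "ks": [r.ks for r in self.results],
            "ratio": [r.ratio for r in self.results],
        })


@functools.lru_cache(maxsize=4)
def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


def _check_translatable(cds: str, name: str, table: int) -> str:
    if len(cds) < 3:
        raise UntranslatableCDSError(f"{name}: shorter than one codon")
    trimmed = cds[: len(cds) - len(cds) % 3]
    stops = stop_codons(table)
    for i in range(0, len(trimmed) - 3, 3):
        if trimmed[i:i + 3] in stops:
            raise UntranslatableCDSError(
                f"{name}: internal stop codon at nt {i + 1}"
            )
    return trimmed


def _strip_terminal_stop(cds: str, table: int) -> str:
    if cds[-3:] in stop_codons(table):
        return cds[:-3]
    return cds


def align_codons(
    cds_a: str, cds_b: str, table: int = DEFAULT_TABLE, gene: str = ""
) -> CodonAlignment:
    """Protein-guided global codon alignment of two CDS.

    Both sequences must translate cleanly (terminal stop allowed and
    stripped). The amino-acid alignment is computed under BLOSUM62 with
    affine gaps and back-translated, so all gaps are whole codons.
    """
    a = _strip_terminal_stop(_check_translatable(cds_a.upper(), "cds_a", table), table)
    b = _strip_terminal_stop(_check_translatable(cds_b.upper(), "cds_b", table), table)
    pa, pb = translate_cds(a, table), translate_cds(b, table)
    aln = _protein_aligner().align(pa, pb)[0]
    ra, rb = [], []
    ia = ib = 0
    for ca, cb in zip(aln[0], aln[1]):
        if ca == "-":
            ra.append("---")
        else:
            ra.append(a[3 * ia:3 * ia + 3])
            ia += 1
        if cb == "-":
            rb.append("---")
        else:
            rb.append(b[3 * ib:3 * ib + 3])
            ib += 1
    return CodonAlignment(rows=["".join(ra), "".join(rb)], gene=gene, table=table)


@functools.lru_cache(maxsize=8)
def _site_fractions(table: int) -> dict[str, tuple[float, float]]:
    """NG86 per-codon (synonymous, nonsynonymous) site counts.

    At each codon position the synonymous fraction is the share of the three
    possible point changes that preserve the amino acid; changes creating a
    stop codon count as nonsynonymous, so s + n = 3 for every sense codon.
    """
    out = {}
    stops = stop_codons(table)
    for codon in sense_codons(table):
        aa = translate_codon(codon, table)
        s = 0.0
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                if mut not in stops and translate_codon(mut, table) == aa:
                    s += 1 / 3
        out[codon] = (s, 3.0 - s)
    return out


def _pathway_counts(ca: str, cb: str, table: int) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts over all
    mutational pathways between two codons; pathways through stop codons are
    excluded (all-pathways average is used if every pathway is blocked)."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    stops = stop_codons(table)

    def walk(allow_stops: bool) -> tuple[float, float, int]:
        s_tot = n_tot = 0.0
        n_paths = 0
        for perm in itertools.permutations(diff_pos):
            cur = ca
            s = n = 0.0
            ok = True
            for pos in perm:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if nxt in stops and not allow_stops:
                    ok = False
                    break
                if translate_codon(cur, table) == translate_codon(nxt, table):
                    s += 1
                else:
                    n += 1
                cur = nxt
            if ok:
                s_tot += s
                n_tot += n
                n_paths += 1
        return s_tot, n_tot, n_paths

    s_tot, n_tot, n_paths = walk(allow_stops=False)
    if n_paths == 0:
        s_tot, n_tot, n_paths = walk(allow_stops=True)
    return s_tot / n_paths, n_tot / n_paths


def _jc_correct(p: float) -> tuple[float, bool]:
    """Jukes-Cantor correction of a proportion; saturated when p >= 3/4."""
    if p >= 0.75:
        return math.nan, True
    return -0.75 * math.log(1 - 4 * p / 3), False


def kaks_ng86(aln: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks for a pairwise codon alignment.

    Codon columns with gaps, ambiguous bases, or a stop codon in either
    sequence are dropped. The ratio is NaN when Ks = 0 (no synonymous
    divergence) or when either proportion is saturated (p >= 0.75).
    """
    if len(aln.rows) != 2:
        raise ValueError("NG86 is pairwise; give a two-row alignment")
    table = aln.table
    stops = stop_codons(table)
    fractions = _site_fractions(table)
    s_sites = n_sites = 0.0
    s_diffs = n_diffs = 0.0
    used = 0
    for ca, cb in aln.codon_columns():
        if "---" in (ca, cb) or not (set(ca) | set(cb)) <= set(BASES):
            continue
        if ca in stops or cb in stops:
            continue
        sa, na = fractions[ca]
        sb, nb = fractions[cb]
        s_sites += (sa + sb) / 2
        n_sites += (na + nb) / 2
        sd, nd = _pathway_counts(ca, cb, table)
        s_diffs += sd
        n_diffs += nd
        used += 1
    if used == 0:
        raise ValueError("no usable (gap-free, unambiguous) codon columns")
    ps = s_diffs / s_sites if s_sites else 0.0
    pn = n_diffs / n_sites if n_sites else 0.0
    ks, sat_s = _jc_correct(ps)
    ka, sat_n = _jc_correct(pn)
    ka = abs(ka) if ka == ka else ka  # -0.0 -> 0.0
    saturated = sat_s or sat_n
    if pn == 0.0 and s_diffs > 0:
        ratio = 0.0  # no nonsynonymous divergence at all
    elif saturated or ks != ks or ka != ka or ks == 0.0:
        ratio = math.nan
    else:
        ratio = ka / ks
    return KaKsResult(
        ka=ka, ks=ks, ratio=ratio, n_sites=n_sites, s_sites=s_sites,
        n_diffs=n_diffs, s_diffs=s_diffs, codons=used, saturated=saturated,
    )


def sliding_kaks(
    aln: CodonAlignment, window: int = 30, step: int = 6
) -> WindowSeries:
    """kaks_ng86 in sliding windows of ``window`` codons every ``step``.

    Windows are placed on alignment codon coordinates. An alignment shorter
    than one window yields a single full-length window.
    """
    if window < 10:
        raise ValueError("window must be >= 10 codons")
    n = aln.n_codons
    if n <= window:
        return WindowSeries(starts=[0], results=[kaks_ng86(aln)])
    starts, results = [], []
    for start in range(0, n - window + 1, step):
        sub = CodonAlignment(
            rows=[r[3 * start:3 * (start + window)] for r in aln.rows],
            gene=aln.gene, table=aln.table,
        )
        starts.append(start)
        results.append(kaks_ng86(sub))
    return WindowSeries(starts=starts, results=results)


def assign_family(gene: str, family_map: dict[str, str] | None = None) -> str:
    """Gene family from label prefix (nad/cob/cox/atp/rpg/ymf, else other)."""
    if family_map and gene in family_map:
        return family_map[gene]
    base = gene.lower()
    for prefix, fam in FAMILY_PREFIXES.items():
        if base.startswith(prefix):
            return fam
    return "other"


def family_summary(
    results: pd.DataFrame, family_map: dict[str, str] | None = None
) -> dict[str, pd.DataFrame]:
    """Mean Ka/Ks per gene, per gene family, and per species pair.

    ``results`` needs columns gene, pair, ratio; NaN ratios (Ks = 0 or
    saturation) are excluded, and the number of contributing comparisons is
    reported alongside each mean.
    """
    df = results.copy()
    df["family"] = [assign_family(g, family_map) for g in df["gene"]]
    defined = df.dropna(subset=["ratio"])

    def agg(by: str) -> pd.DataFrame:
        g = defined.groupby(by)["ratio"]
        return pd.DataFrame({"mean_ratio": g.mean(), "n": g.count()})

    return {"per_gene": agg("gene"), "per_family": agg("family"),
            "per_pair": agg("pair")}


def rf_kaks_correlation(
    rf: pd.Series, mean_ratio: pd.Series
) -> dict[str, float]:
    """OLS of per-gene mean Ka/Ks on per-gene RF: R-squared and slope p.

    Returns a dict with r_squared, p_value, slope, intercept, n, and a
    ``degenerate`` flag set when RF has zero variance.
    """
    joined = pd.concat(
        {"rf": rf, "ratio": mean_ratio}, axis=1, join="inner"
    ).dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 genes with both RF and Ka/Ks defined")
    x, y = joined["rf"].to_numpy(float), joined["ratio"].to_numpy(float)
    if np.allclose(x.var(), 0):
        return {"r_squared": math.nan, "p_value": math.nan, "slope": math.nan,
                "intercept": math.nan, "n": len(joined), "degenerate": True}
    fit = stats.linregress(x, y)
    return {"r_squared": fit.rvalue ** 2, "p_value": fit.pvalue,
            "slope": fit.slope, "intercept": fit.intercept,
            "n": len(joined), "degenerate": False}
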