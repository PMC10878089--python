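"""Population-level mitogenome statistics from allele-depth matrices.

The unit of input is a strain x site x base depth matrix (pileup-derived:
for each strain and genomic site, the number of reads supporting A, C, G and
T). From it the module derives per-strain major-allele consensus haplotypes,
SNPs between strains, heteroplasmic sites within strains (intermediate
minor-allele fractions), nucleotide diversity, linkage-disequilibrium decay,
and the association between genetic identity (IBS) and geographic distance.

Read mapping and raw variant calling are upstream of this contract; the
expected TSV is one row per strain x site: strain, site, ref, A, C, G, T.
Because mitochondria are effectively haploid and (here) non-recombining,
LD r-squared is computed on haplotypes directly, and its independence from
inter-site distance is the diagnostic for absent recombination.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASES = "ACGT"
EARTH_RADIUS_KM = 6371.0


class EmptyCoverageError(ValueError):
    pass


@dataclass
class VariantMatrix:
    strains: list[str]
    sites: np.ndarray  # genome coordinates, shape (S,)
    ref: np.ndarray  # reference base per site, shape (S,), dtype <U1
    depths: np.ndarray  # shape (n_strains, S, 4) in A,C,G,T order

    def __post_init__(self):
        self.sites = np.asarray(self.sites)
        self.ref = np.asarray(self.ref)
        self.depths = np.asarray(self.depths)
        n, s, b = self.depths.shape
        if n != len(self.strains) or s != len(self.sites) or b != 4:
            raise ValueError("depth array shape does not match strains/sites")
        if (self.depths < 0).any():
            raise ValueError("negative depths")

    @classmethod
    def from_tsv(cls, path) -> "VariantMatrix":
        df = pd.read_csv(path, sep="\t")
        strains = sorted(df["strain"].unique())
        sites = np.sort(df["site"].unique())
        site_idx = {s: i for i, s in enumerate(sites)}
        strain_idx = {s: i for i, s in enumerate(strains)}
        ref = np.array(["N"] * len(sites))
        depths = np.zeros((len(strains), len(sites), 4), dtype=int)
        for row in df.itertuples(index=False):
            i, j = strain_idx[row.strain], site_idx[row.site]
            ref[j] = row.ref
            depths[i, j] = [row.A, row.C, row.G, row.T]
        return cls(strains=strains, sites=sites, ref=ref, depths=depths)

    def to_tsv(self, path) -> None:
        rows = []
        for i, strain in enumerate(self.strains):
            for j, site in enumerate(self.sites):
                a, c, g, t = self.depths[i, j]
                rows.append((strain, site, self.ref[j], a, c, g, t))
        pd.DataFrame(
            rows, columns=["strain", "site", "ref", "A", "C", "G", "T"]
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class HeteroplasmyCall:
    strain: str
    site: int
    major: str
    minor: str
    minor_fraction: float
    depth: int


@dataclass(frozen=True)
class StrainMeta:
    strain: str
    species: str
    latitude: float
    longitude: float

    def __post_init__(self):
        if not (abs(self.latitude) <= 90 and abs(self.longitude) <= 180):
            raise ValueError(f"{self.strain}: coordinates out of range")


def consensus_haplotypes(vm: VariantMatrix, min_depth: int = 1) -> pd.DataFrame:
    """Major-allele consensus per strain over covered sites.

    Sites with total depth below ``min_depth`` are masked as N. Depth ties
    are resolved in favour of the reference base when it is among the tied
    maxima, otherwise alphabetically.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    total = vm.depths.sum(axis=2)
    out = np.full((len(vm.strains), len(vm.sites)), "N", dtype="<U1")
    base_arr = np.array(list(BASES))
    for i in range(len(vm.strains)):
        if (total[i] == 0).all():
            raise EmptyCoverageError(f"strain {vm.strains[i]!r} has no coverage")
        for j in range(len(vm.sites)):
            if total[i, j] < min_depth:
                continue
            d = vm.depths[i, j]
            top = d.max()
            tied = base_arr[d == top]
            if vm.ref[j] in tied:
                out[i, j] = vm.ref[j]
            else:
                out[i, j] = tied[0]
    return pd.DataFrame(out, index=vm.strains, columns=vm.sites)


def call_snps(consensus: pd.DataFrame) -> dict:
    """Polymorphic sites among strain consensuses and per-kb density.

    A site is a SNP when >= 2 distinct non-masked bases occur; density is
    SNPs per kb of sites covered (non-masked) in >= 2 strains.
    """
    if len(consensus) < 2:
        raise ValueError("need >= 2 strains")
    arr = consensus.to_numpy()
    snp_sites = []
    covered = 0
    for j, site in enumerate(consensus.columns):
        bases = {b for b in arr[:, j] if b != "N"}
        if sum(1 for b in arr[:, j] if b != "N") >= 2:
            covered += 1
        if len(bases) >= 2:
            snp_sites.append(site)
    density = len(snp_sites) / (covered / 1000.0) if covered else math.nan
    return {"sites": snp_sites, "count": len(snp_sites),
            "covered_sites": covered, "density_per_kb": density}


def write_snps_vcf(
    consensus: pd.DataFrame, path, contig: str = "mito", ref: np.ndarray | None = None
) -> None:
    """Minimal haploid VCF 4.2 export of the SNP sites among consensuses.

    REF is taken from ``ref`` when given, else from the first unmasked
    strain; remaining observed bases become ALT alleles, and each strain's
    GT indexes into REF+ALT (. when masked).
    """
    snps = call_snps(consensus)["sites"]
    arr = consensus.to_numpy()
    col_of = {s: i for i, s in enumerate(consensus.columns)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(consensus.index) + "\n"
        )
        for site in snps:
            j = col_of[site]
            col = arr[:, j]
            observed = [b for b in col if b != "N"]
            if ref is not None and ref[j] in "ACGT":
                ref_base = str(ref[j])
            else:
                ref_base = observed[0]
            alts = sorted({b for b in observed if b != ref_base})
            alleles = [ref_base] + alts
            gts = [
                "." if b == "N" else str(alleles.index(b)) for b in col
            ]
            fh.write(
                f"{contig}\t{int(site) + 1}\t.\t{ref_base}\t{','.join(alts)}\t"
                f".\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def call_heteroplasmy(
    vm: VariantMatrix, maf_min: float = 0.05, depth_min: int = 50
) -> list[HeteroplasmyCall]:
    """Within-strain heteroplasmic sites.

    A strain x site is called when the minor-allele fraction (second-highest
    base depth / total depth) is >= maf_min at total depth >= depth_min.
    """
    calls = []
    for i, strain in enumerate(vm.strains):
        for j, site in enumerate(vm.sites):
            d = vm.depths[i, j]
            depth = int(d.sum())
            if depth < depth_min:
                continue
            order = np.argsort(d, kind="stable")[::-1]
            major, minor = order[0], order[1]
            frac = d[minor] / depth
            if d[minor] > 0 and frac >= maf_min:
                calls.append(HeteroplasmyCall(
                    strain=strain, site=int(site),
                    major=BASES[major], minor=BASES[minor],
                    minor_fraction=float(frac), depth=depth,
                ))
    return calls


def nucleotide_diversity(
    consensus: pd.DataFrame,
    gene_intervals: dict[str, tuple[int, int]] | None = None,
) -> dict:
    """Nucleotide diversity pi: mean pairwise difference per jointly covered
    site, averaged over all strain pairs.

    With ``gene_intervals`` (name -> half-open site-coordinate interval) a
    per-gene pi restricted to each interval is reported as well. Pairs with
    zero jointly covered sites are excluded.
    """
    if len(consensus) < 2:
        raise ValueError("need >= 2 strains")
    sites = np.asarray(consensus.columns)
    arr = consensus.to_numpy()

    def pi_over(mask: np.ndarray) -> float:
        vals = []
        for i, j in itertools.combinations(range(len(arr)), 2):
            a, b = arr[i][mask], arr[j][mask]
            joint = (a != "N") & (b != "N")
            if not joint.any():
                continue
            vals.append((a[joint] != b[joint]).sum() / joint.sum())
        return float(np.mean(vals)) if vals else math.nan

    out = {"pi": pi_over(np.ones(len(sites), dtype=bool)), "per_gene": {}}
    if gene_intervals:
        for gene, (s, e) in gene_intervals.items():
            out["per_gene"][gene] = pi_over((sites >= s) & (sites < e))
    return out


def _biallelic_sites(consensus: pd.DataFrame) -> list[tuple[int, np.ndarray]]:
    """(site, binary coding) for biallelic sites with no masked strain."""
    arr = consensus.to_numpy()
    out = []
    for j, site in enumerate(consensus.columns):
        col = arr[:, j]
        if (col == "N").any():
            continue
        alleles = sorted(set(col))
        if len(alleles) == 2:
            out.append((int(site), (col == alleles[1]).astype(float)))
    return out


def haploid_r2(x: np.ndarray, y: np.ndarray) -> float:
    """r^2 = D^2 / (pA pa pB pb) for two binary haploid site vectors."""
    pa, pb = x.mean(), y.mean()
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom == 0:
        return math.nan
    d = (x * y).mean() - pa * pb
    return float(d * d / denom)


def ld_r2_decay(consensus: pd.DataFrame, max_pairs: int | None = None,
                seed: int | None = None) -> dict:
    """Pairwise haploid r^2 vs inter-site distance, with decay correlations.

    Monomorphic and masked sites are skipped. Returns the per-pair table and
    Pearson/Spearman correlations of r^2 with distance (a significant
    negative trend is the signature of recombination). ``max_pairs``
    subsamples site pairs reproducibly for large matrices.
    """
    if len(consensus) < 4:
        raise ValueError("need >= 4 strains for informative r^2")
    sites = _biallelic_sites(consensus)
    if len(sites) < 2:
        raise ValueError("need >= 2 biallelic sites")
    pairs = list(itertools.combinations(range(len(sites)), 2))
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    rows = []
    for i, j in pairs:
        (s1, x), (s2, y) = sites[i], sites[j]
        r2 = haploid_r2(x, y)
        if r2 == r2:
            rows.append({"site_1": s1, "site_2": s2,
                         "distance": abs(s2 - s1), "r2": r2})
    table = pd.DataFrame(rows)
    out = {"pairs": table}
    if len(table) >= 3 and table["r2"].var() > 0 and table["distance"].var() > 0:
        pear = stats.pearsonr(table["distance"], table["r2"])
        spear = stats.spearmanr(table["distance"], table["r2"])
        out.update(
            pearson_r=float(pear.statistic), pearson_p=float(pear.pvalue),
            spearman_r=float(spear.statistic), spearman_p=float(spear.pvalue),
        )
    else:
        out.update(pearson_r=math.nan, pearson_p=math.nan,
                   spearman_r=math.nan, spearman_p=math.nan)
    return out


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (Earth radius 6371 km)."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def ibs_matrix(consensus: pd.DataFrame) -> pd.DataFrame:
    """Identity-by-state: fraction of jointly covered sites with identical
    bases, per strain pair (diagonal = 1)."""
    strains = list(consensus.index)
    arr = consensus.to_numpy()
    n = len(strains)
    mat = np.ones((n, n))
    for i, j in itertools.combinations(range(n), 2):
        joint = (arr[i] != "N") & (arr[j] != "N")
        if not joint.any():
            mat[i, j] = mat[j, i] = math.nan
        else:
            mat[i, j] = mat[j, i] = (arr[i][joint] == arr[j][joint]).mean()
    return pd.DataFrame(mat, index=strains, columns=strains)


def ibs_vs_geography(
    consensus: pd.DataFrame,
    meta: list[StrainMeta],
    permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """Mantel test of log(IBS) against log(geographic distance).

    The statistic is the Pearson correlation between the off-diagonal
    entries of log(IBS) and log(km + 1) (the +1 offset absorbs zero
    distances); the permutation null rearranges strains jointly in rows and
    columns of one matrix. R-squared is the squared Mantel r.
    """
    by_strain = {m.strain: m for m in meta}
    strains = [s for s in consensus.index if s in by_strain]
    if len(strains) < 4:
        raise ValueError("need >= 4 strains with coordinates")
    ibs = ibs_matrix(consensus.loc[strains]).to_numpy()
    n = len(strains)
    km = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = by_strain[strains[i]], by_strain[strains[j]]
        km[i, j] = km[j, i] = haversine_km(
            a.latitude, a.longitude, b.latitude, b.longitude
        )
    iu = np.triu_indices(n, k=1)
    x = np.log(km[iu] + 1.0)
    y = np.log(ibs[iu])
    if np.allclose(x.var(), 0) or np.allclose(y.var(), 0) or np.isnan(y).any():
        return {"mantel_r": math.nan, "r_squared": math.nan, "p": math.nan,
                "km": km, "ibs": ibs, "strains": strains, "degenerate": True}

    def corr(mat: np.ndarray) -> float:
        return float(np.corrcoef(np.log(mat[iu] + 1.0), y)[0, 1])

    r_obs = corr(km)
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(permutations):
        perm = rng.permutation(n)
        if abs(corr(km[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-12:
            hits += 1
    return {
        "mantel_r": r_obs, "r_squared": r_obs ** 2,
        "p": hits / (permutations + 1),
        "km": km, "ibs": ibs, "strains": strains, "degenerate": False,
    }
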