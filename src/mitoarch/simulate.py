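"""Ground-truthed synthetic data for every pipeline stage.

Each generator emits both the data and a :class:`SimulationTruth` record
sufficient to reconstruct it, so downstream detectors and estimators can be
scored against known answers:

* ``evolve_gene_order`` — applies a known number of single-gene losses,
  strand inversions and translocations to an ancestral signed gene order;
* ``simulate_codon_pair`` — two codon sequences diverged under an M0-style
  continuous-time codon model (transition/transversion ratio kappa,
  nonsynonymous rate multiplier omega, uniform sense-codon frequencies,
  substitutions into stop codons forbidden);
* ``simulate_population`` — strain haplotypes mutated from a reference at a
  per-site rate theta with no recombination (star genealogy by default, or a
  serial "chain" genealogy that shares mutations along lineages), planted
  heteroplasmic sites, sequencing depth/error, and geographic coordinates;
* ``build_repeat_genome`` — a linear genome with planted terminal telomeric
  tandem repeats, an AT-rich central repeat insert, and toy gene features.

Same seed, same bytes: every generator is driven by a single
``numpy.random.default_rng`` seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from ._genetics import (
    BASES,
    DEFAULT_TABLE,
    is_synonymous,
    is_transition,
    sense_codons,
)
from .io import GeneFeature, GeneOrder, Mitogenome
from .popgen import StrainMeta, VariantMatrix


@dataclass
class SimulationTruth:
    seed: int | None
    events: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gene orders


def evolve_gene_order(
    ancestral: GeneOrder,
    n_loss: int = 0,
    n_inv: int = 0,
    n_trans: int = 0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    genome_id: str | None = None,
) -> tuple[GeneOrder, SimulationTruth]:
    """Apply planted losses, inversions and translocations in random order.

    Losses pick distinct genes uniformly; inversions flip the strand of a
    uniformly chosen surviving gene; translocations move a surviving gene to
    a uniformly chosen new position. The truth log records each event in
    application order, so replaying it on the ancestor reproduces the
    output exactly.
    """
    if min(n_loss, n_inv, n_trans) < 0:
        raise ValueError("event counts must be >= 0")
    if n_loss >= len(ancestral.elements):
        raise ValueError("cannot lose all (or more) genes")
    rng = rng if rng is not None else np.random.default_rng(seed)
    ops = ["loss"] * n_loss + ["inversion"] * n_inv + ["translocation"] * n_trans
    ops = [ops[i] for i in rng.permutation(len(ops))]
    elements = list(ancestral.elements)
    events: list[dict] = []
    for op in ops:
        if op == "loss":
            i = int(rng.integers(len(elements)))
            gene, _ = elements.pop(i)
            events.append({"type": "loss", "gene": gene, "position": i})
        elif op == "inversion":
            i = int(rng.integers(len(elements)))
            gene, strand = elements[i]
            elements[i] = (gene, "-" if strand == "+" else "+")
            events.append({"type": "inversion", "gene": gene, "position": i})
        else:
            i = int(rng.integers(len(elements)))
            gene, strand = elements.pop(i)
            j = int(rng.integers(len(elements) + 1))
            elements.insert(j, (gene, strand))
            events.append({
                "type": "translocation", "gene": gene,
                "position": i, "new_position": j,
            })
    order = GeneOrder(
        genome_id=genome_id or f"{ancestral.genome_id}_evolved",
        elements=elements,
        universe=ancestral.universe,
    )
    truth = SimulationTruth(
        seed=seed, events=events,
        params={"n_loss": n_loss, "n_inv": n_inv, "n_trans": n_trans},
    )
    return order, truth


def replay_gene_order(ancestral: GeneOrder, truth: SimulationTruth) -> GeneOrder:
    """Re-apply a truth event log to the ancestor (determinism check)."""
    elements = list(ancestral.elements)
    for ev in truth.events:
        if ev["type"] == "loss":
            elements.pop(ev["position"])
        elif ev["type"] == "inversion":
            g, s = elements[ev["position"]]
            elements[ev["position"]] = (g, "-" if s == "+" else "+")
        else:
            g, s = elements.pop(ev["position"])
            elements.insert(ev["new_position"], (g, s))
    return GeneOrder(
        genome_id=f"{ancestral.genome_id}_replayed", elements=elements,
        universe=ancestral.universe,
    )


def random_gene_order(
    n_genes: int, seed: int | None = None, genome_id: str = "ancestor"
) -> GeneOrder:
    """Ancestral order g001..gNNN with random strands."""
    rng = np.random.default_rng(seed)
    elements = [
        (f"g{i + 1:03d}", "+" if rng.random() < 0.5 else "-")
        for i in range(n_genes)
    ]
    return GeneOrder(genome_id=genome_id, elements=elements)


# ---------------------------------------------------------------------------
# codon evolution


def _m0_rate_matrix(omega: float, kappa: float, table: int) -> tuple[np.ndarray, tuple[str, ...]]:
    """M0 instantaneous rate matrix over sense codons, scaled to one
    expected substitution per codon per unit time at uniform frequencies."""
    codons = sense_codons(table)
    n = len(codons)
    q = np.zeros((n, n))
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            rate = kappa if is_transition(ci[k], cj[k]) else 1.0
            if not is_synonymous(ci, cj, table):
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -np.mean(np.diag(q))
    return q / mean_rate, codons


def simulate_codon_pair(
    n_codons: int,
    omega: float,
    kappa: float = 2.0,
    t: float = 0.3,
    table: int = DEFAULT_TABLE,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, str, SimulationTruth]:
    """Two codon sequences diverged by total branch length ``t``.

    The ancestor is drawn uniformly over sense codons and evolved for t/2
    down each of two branches under the M0 model (kappa, omega); time is in
    expected substitutions per codon. Stop codons are unreachable. The truth
    stores the ancestral codon string alongside both descendants.
    """
    if omega <= 0 or t <= 0:
        raise ValueError("omega and t must be > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    q, codons = _m0_rate_matrix(omega, kappa, table)
    p = expm(q * (t / 2.0))
    p = np.clip(p, 0, None)
    p /= p.sum(axis=1, keepdims=True)
    n = len(codons)
    anc_idx = rng.integers(0, n, size=n_codons)
    child_a = np.array([rng.choice(n, p=p[i]) for i in anc_idx])
    child_b = np.array([rng.choice(n, p=p[i]) for i in anc_idx])
    anc = "".join(codons[i] for i in anc_idx)
    a = "".join(codons[i] for i in child_a)
    b = "".join(codons[i] for i in child_b)
    truth = SimulationTruth(
        seed=seed,
        events=[{"ancestor": anc, "child_a": a, "child_b": b}],
        params={"n_codons": n_codons, "omega": omega, "kappa": kappa, "t": t},
    )
    return a, b, truth


# ---------------------------------------------------------------------------
# populations


def simulate_population(
    ref_length: int = 2000,
    n_strains: int = 8,
    theta_per_site: float = 0.01,
    het_spec: list[tuple[int, int, float]] | None = None,
    depth: float = 100.0,
    error_rate: float = 0.005,
    coords_spec: tuple[tuple[float, float], tuple[float, float]] | None = ((18.0, 53.0), (75.0, 135.0)),
    genealogy: str = "star",
    species: str = "sp",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[VariantMatrix, list[StrainMeta], SimulationTruth]:
    """A strain population with known mutations, heteroplasmies and depths.

    Haplotypes descend from a single reference with per-site mutation
    probability ``theta_per_site`` and no recombination: under the default
    star genealogy each strain mutates independently; under ``chain`` each
    strain inherits the previous strain's haplotype before adding its own
    mutations (shared mutations create linkage structure). ``het_spec``
    plants heteroplasmy as (strain index, site, minor fraction) triples.
    Depths are Poisson(``depth``); each read reports a wrong base uniformly
    with probability ``error_rate``. Coordinates are uniform over the given
    (lat, lon) ranges.
    """
    if not 0 <= theta_per_site < 0.75:
        raise ValueError("theta_per_site must be in [0, 0.75)")
    if depth < 1:
        raise ValueError("mean depth must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    base_idx = {b: i for i, b in enumerate(BASES)}
    ref = rng.choice(list(BASES), size=ref_length)
    haplotypes = np.tile(ref, (n_strains, 1))
    mutations: list[dict] = []
    parent = ref
    for s in range(n_strains):
        template = parent if genealogy == "chain" else ref
        hap = template.copy()
        hit = rng.random(ref_length) < theta_per_site
        for j in np.nonzero(hit)[0]:
            alts = [b for b in BASES if b != hap[j]]
            hap[j] = alts[int(rng.integers(3))]
            mutations.append({"strain": s, "site": int(j), "base": hap[j]})
        haplotypes[s] = hap
        parent = hap

    het_spec = het_spec or []
    sites = np.arange(ref_length)
    depths = np.zeros((n_strains, ref_length, 4), dtype=int)
    het_lookup = {(s, j): f for s, j, f in het_spec}
    for s in range(n_strains):
        n_reads = rng.poisson(depth, size=ref_length)
        for j in range(ref_length):
            nr = int(n_reads[j])
            if nr == 0:
                continue
            major = haplotypes[s, j]
            frac = het_lookup.get((s, j), 0.0)
            minor = None
            if frac > 0:
                alts = [b for b in BASES if b != major]
                minor = alts[int(rng.integers(3))]
            true_bases = np.full(nr, major, dtype="<U1")
            if minor is not None:
                from_minor = rng.random(nr) < frac
                true_bases[from_minor] = minor
            err = rng.random(nr) < error_rate
            for k in np.nonzero(err)[0]:
                wrong = [b for b in BASES if b != true_bases[k]]
                true_bases[k] = wrong[int(rng.integers(3))]
            for b in BASES:
                depths[s, j, base_idx[b]] = int((true_bases == b).sum())

    strains = [f"{species}_{s + 1:02d}" for s in range(n_strains)]
    vm = VariantMatrix(strains=strains, sites=sites, ref=ref, depths=depths)
    meta = []
    if coords_spec is not None:
        (lat_lo, lat_hi), (lon_lo, lon_hi) = coords_spec
        for s, name in enumerate(strains):
            meta.append(StrainMeta(
                strain=name, species=species,
                latitude=float(rng.uniform(lat_lo, lat_hi)),
                longitude=float(rng.uniform(lon_lo, lon_hi)),
            ))
    truth = SimulationTruth(
        seed=seed,
        events=mutations,
        params={
            "ref": "".join(ref),
            "haplotypes": ["".join(h) for h in haplotypes],
            "het_spec": list(het_spec),
            "theta_per_site": theta_per_site,
            "depth": depth, "error_rate": error_rate, "genealogy": genealogy,
        },
    )
    return vm, meta, truth


# ---------------------------------------------------------------------------
# repeat-bearing genomes


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(BASES), size=length, p=p))


def build_repeat_genome(
    core_length: int = 5000,
    telomere_spec: dict | None = None,
    cr_spec: dict | None = None,
    n_genes: int = 8,
    seed: int | None = None,
    genome_id: str = "synthetic",
) -> tuple[Mitogenome, SimulationTruth]:
    """Linear genome: 5' telomere + gene-bearing core (+ CR insert) + 3' telomere.

    ``telomere_spec`` keys: unit_length, copies, gc (shared by both ends; the
    two ends get independent random units). ``cr_spec`` keys: length, at
    (AT fraction of the insert). Toy PCG features of 300 bp alternate strand
    across the core; the CR is inserted mid-core and annotated, as are both
    telomeres. The truth records each planted element's unit/position.
    """
    rng = np.random.default_rng(seed)
    events: list[dict] = []

    def telomere(end: str) -> str:
        if not telomere_spec:
            return ""
        p = telomere_spec["unit_length"]
        copies = telomere_spec["copies"]
        unit = _random_seq(rng, p, telomere_spec.get("gc", 0.35))
        events.append({
            "type": "telomere", "end": end, "unit": unit,
            "unit_length": p, "copies": copies,
        })
        return unit * copies

    tel5 = telomere("5prime")

    gene_len = 300
    spacing = max((core_length - n_genes * gene_len) // (n_genes + 1), 10)
    core = _random_seq(rng, core_length, gc=0.30)
    features: list[GeneFeature] = []
    gene_positions = []
    pos = spacing
    for i in range(n_genes):
        if pos + gene_len > core_length:
            break
        gene_positions.append((pos, pos + gene_len, "+" if i % 2 else "-"))
        pos += gene_len + spacing

    cr_seq = ""
    cr_at_core = None
    if cr_spec:
        at = cr_spec.get("at", 1.0)
        cr_unit = _random_seq(rng, cr_spec.get("unit_length", 25), gc=1 - at)
        reps = int(np.ceil(cr_spec["length"] / len(cr_unit)))
        cr_seq = (cr_unit * reps)[: cr_spec["length"]]
        # insert midway through the core, but never inside a gene
        cr_at_core = core_length // 2
        for s, e, _ in gene_positions:
            if s < cr_at_core < e:
                cr_at_core = e
        events.append({
            "type": "central_repeat", "core_offset": cr_at_core,
            "length": len(cr_seq), "unit": cr_unit, "at": at,
        })

    tel3 = telomere("3prime")

    if cr_at_core is not None:
        core = core[:cr_at_core] + cr_seq + core[cr_at_core:]
    seq = tel5 + core + tel3
    off = len(tel5)

    def shift_start(x: int) -> int:
        return x + len(cr_seq) if cr_at_core is not None and x >= cr_at_core else x

    def shift_end(x: int) -> int:
        return x + len(cr_seq) if cr_at_core is not None and x > cr_at_core else x

    if tel5:
        features.append(GeneFeature(
            name="telomere_5p", category="telomere", start=0, end=len(tel5),
            strand="+",
        ))
    for i, (s, e, strand) in enumerate(gene_positions):
        features.append(GeneFeature(
            name=f"gene{i + 1:02d}", category="PCG",
            start=off + shift_start(s), end=off + shift_end(e), strand=strand,
        ))
    if cr_at_core is not None:
        features.append(GeneFeature(
            name="CR", category="central_repeat",
            start=off + cr_at_core, end=off + cr_at_core + len(cr_seq),
            strand="+",
        ))
    if tel3:
        features.append(GeneFeature(
            name="telomere_3p", category="telomere",
            start=len(seq) - len(tel3), end=len(seq), strand="+",
        ))
    genome = Mitogenome(
        id=genome_id, sequence=seq, topology="linear", features=features,
        source="synthetic",
    )
    truth = SimulationTruth(
        seed=seed, events=events,
        params={"core_length": core_length, "n_genes": len(gene_positions)},
    )
    return genome, truth
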