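import numpy as np
import pytest

from mitoarch._genetics import revcomp, sense_codons
from mitoarch.homology import (
    ConcatAlignment,
    EmptyProteomeError,
    MissingSequenceError,
    Orthogroup,
    concat_core_alignment,
    core_genes,
    infer_orthogroups,
    nj_tree,
    write_partitions,
    write_phylip,
)
from mitoarch.io import GeneFeature, Mitogenome
from mitoarch.simulate import simulate_codon_pair


def _genome_with_genes(gid, genes, seed=0):
    """Genome whose PCGs are supplied CDS strings laid head-to-tail."""
    rng = np.random.default_rng(seed)
    parts, feats, pos = [], [], 0
    for name, cds in genes.items():
        spacer = "".join(rng.choice(list("ACGT"), size=20))
        parts.append(spacer)
        pos += 20
        parts.append(cds)
        feats.append(GeneFeature(name, "PCG", pos, pos + len(cds), "+"))
        pos += len(cds)
    parts.append("ACGT")
    return Mitogenome(id=gid, sequence="".join(parts), features=feats)


def _random_cds(rng, n_codons):
    codons = sense_codons(4)
    return "".join(codons[i] for i in rng.integers(0, len(codons), size=n_codons))


def _mutate_cds(rng, cds, frac):
    codons = sense_codons(4)
    out = list(cds)
    n = len(cds) // 3
    for i in rng.choice(n, size=max(1, int(frac * n)), replace=False):
        out[3 * i:3 * i + 3] = codons[int(rng.integers(len(codons)))]
    return "".join(out)


class TestOrthogroups:
    def test_by_name_groups_identical_labels(self, rng):
        genomes = [
            _genome_with_genes(f"g{i}", {
                "cox1": _random_cds(rng, 50), "cob": _random_cds(rng, 40),
            }, seed=i)
            for i in range(3)
        ]
        groups = infer_orthogroups(genomes, mode="by_name")
        assert len(groups) == 2
        assert all(len(og.members) == 3 for og in groups)

    def test_missing_gene_shrinks_group_and_core(self, rng):
        full = {"cox1": _random_cds(rng, 50), "cob": _random_cds(rng, 40)}
        genomes = [
            _genome_with_genes("g1", full, seed=1),
            _genome_with_genes("g2", full, seed=2),
            _genome_with_genes("g3", {"cox1": full["cox1"]}, seed=3),
        ]
        groups = infer_orthogroups(genomes, mode="by_name")
        by_rep = {og.representative: og for og in groups}
        assert len(by_rep["cob"].members) == 2
        core = core_genes(groups, 3)
        assert core.count == 1

    def test_rbh_recovers_planted_families_with_decoys(self, rng):
        base = {f"fam{j}": _random_cds(rng, 60) for j in range(4)}
        genomes = []
        for i in range(3):
            genes = {
                name: _mutate_cds(rng, cds, 0.10)
                for name, cds in base.items()
            }
            # a decoy private to each genome, unrelated to every family
            genes[f"decoy_{i}"] = _random_cds(rng, 60)
            # labels scrambled so rbh cannot cheat via names
            genomes.append(_genome_with_genes(
                f"g{i}", {f"x{i}_{k}": v for k, v in genes.items()}, seed=10 + i
            ))
        groups = infer_orthogroups(genomes, mode="rbh")
        sizes = sorted(len(og.members) for og in groups)
        # 4 planted families of size 3; decoys may or may not clump
        assert sizes.count(3) == 4

    def test_by_name_and_rbh_agree_when_labels_truthful(self, rng):
        base = {f"fam{j}": _random_cds(rng, 60) for j in range(3)}
        genomes = [
            _genome_with_genes(
                f"g{i}",
                {k: _mutate_cds(rng, v, 0.05) for k, v in base.items()},
                seed=20 + i,
            )
            for i in range(3)
        ]
        by_name = infer_orthogroups(genomes, mode="by_name")
        rbh = infer_orthogroups(genomes, mode="rbh")
        as_sets = lambda gs: {frozenset(og.members) for og in gs}
        assert as_sets(by_name) == as_sets(rbh)

    def test_empty_proteome_raises_with_genome_name(self):
        g1 = _genome_with_genes("g1", {"cox1": "ATGAAAGGG"})
        g2 = Mitogenome(id="empty", sequence="ACGT" * 10)
        with pytest.raises(EmptyProteomeError, match="empty"):
            infer_orthogroups([g1, g2])


class TestCoreGenes:
    def test_counts(self):
        groups = [
            Orthogroup("OG1", [("a", "x"), ("b", "x"), ("c", "x")]),
            Orthogroup("OG2", [("a", "y"), ("b", "y"), ("c", "y")]),
            Orthogroup("OG3", [("a", "z"), ("b", "z")]),
        ]
        assert core_genes(groups, 3).count == 2

    def test_duplicated_member_excluded(self):
        groups = [Orthogroup("OG1", [("a", "x_a"), ("a", "x_b"), ("b", "x")])]
        assert core_genes(groups, 2).count == 0

    def test_all_universal_single_copy(self):
        groups = [
            Orthogroup(f"OG{i}", [("a", f"g{i}"), ("b", f"g{i}")])
            for i in range(5)
        ]
        assert core_genes(groups, 2).count == 5


class TestConcatAlignment:
    def test_identical_sequences_have_zero_variable_columns(self, rng):
        cds = _random_cds(rng, 30)
        core = core_genes(
            [Orthogroup("OG1", [("t1", "g"), ("t2", "g"), ("t3", "g")])], 3
        )
        aln = concat_core_alignment(
            core, {"OG1": {"t1": cds, "t2": cds, "t3": cds}}
        )
        assert aln.variable_columns() == 0

    def test_partition_boundaries(self, rng):
        g1, g2 = _random_cds(rng, 10), _random_cds(rng, 20)
        core = core_genes(
            [Orthogroup("OG1", [("t1", "a"), ("t2", "a")]),
             Orthogroup("OG2", [("t1", "b"), ("t2", "b")])], 2
        )
        aln = concat_core_alignment(
            core, {"OG1": {"t1": g1, "t2": g1}, "OG2": {"t1": g2, "t2": g2}}
        )
        assert aln.partitions == [30, 90]
        assert aln.total_columns == 90

    def test_planted_substitution_count_recovered(self, rng):
        cds = _random_cds(rng, 50)
        mutated = list(cds)
        planted = [4, 40, 100]  # single-nt edits at distinct columns
        for pos in planted:
            mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos]]
        mutated = "".join(mutated)
        core = core_genes([Orthogroup("OG1", [("t1", "g"), ("t2", "g")])], 2)
        aln = concat_core_alignment(core, {"OG1": {"t1": cds, "t2": mutated}})
        assert aln.variable_columns() == len(planted)

    def test_missing_sequence_error_lists_taxon_and_gene(self):
        core = core_genes([Orthogroup("OG1", [("t1", "g"), ("t2", "g")])], 2)
        with pytest.raises(MissingSequenceError, match="t2"):
            concat_core_alignment(
                core, {"OG1": {"t1": "ATGAAA"}}, taxa=["t1", "t2"]
            )

    def test_phylip_and_partition_export(self, rng, tmp_path):
        cds = _random_cds(rng, 12)
        core = core_genes([Orthogroup("OG1", [("t1", "g"), ("t2", "g")])], 2)
        aln = concat_core_alignment(core, {"OG1": {"t1": cds, "t2": cds}})
        write_phylip(aln, tmp_path / "a.phy")
        write_partitions(aln, tmp_path / "a.part")
        assert (tmp_path / "a.phy").read_text().splitlines()[0].split() == ["2", "36"]
        assert "OG1 = 1-36" in (tmp_path / "a.part").read_text()


def _alignment_from_rows(rows: dict[str, str]) -> ConcatAlignment:
    n = len(next(iter(rows.values())))
    return ConcatAlignment(
        taxa=sorted(rows), blocks={"g": dict(rows)}, partitions=[n]
    )


class TestNjTree:
    def test_three_taxa_unique_topology(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=300))
        rows = {"t1": a, "t2": a[:-3] + "AAA", "t3": a[:-30] + "C" * 30}
        tree, support = nj_tree(_alignment_from_rows(rows))
        assert {t.name for t in tree.tips()} == {"t1", "t2", "t3"}

    def test_additive_distances_recover_topology_and_lengths(self):
        # quartet ((A,B),(C,D)) with additive path lengths; NJ must return
        # the same tree metric
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        # branch lengths: A=2, B=3, internal=4, C=5, D=6
        d = {
            ("A", "B"): 5, ("A", "C"): 11, ("A", "D"): 12,
            ("B", "C"): 12, ("B", "D"): 13, ("C", "D"): 11,
        }
        ids = ["A", "B", "C", "D"]
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            mat[i, j] = mat[j, i] = v
        tree = skbio_nj(DistanceMatrix(mat, ids=ids))
        for (x, y), v in d.items():
            assert tree.find(x).distance(tree.find(y)) == pytest.approx(v)
        # AB vs CD must be the split: A and B share their first internal node
        ab_anc = tree.lowest_common_ancestor(["A", "B"])
        assert {t.name for t in ab_anc.tips()} in ({"A", "B"}, {"C", "D"})

    def test_clean_split_gets_full_support(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=600))
        b = list(a)
        for i in range(0, 600, 4):
            b[i] = {"A": "G", "G": "A", "C": "T", "T": "C"}[b[i]]
        b = "".join(b)
        rows = {"t1": a, "t2": a, "t3": b, "t4": b}
        tree, support = nj_tree(
            _alignment_from_rows(rows), bootstrap_n=50, seed=1
        )
        assert support[frozenset({"t1", "t2"})] == pytest.approx(100.0)

    def test_bootstrap_deterministic_under_seed(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=400))
        rows = {
            f"t{i}": "".join(
                c if rng.random() > 0.05 else "ACGT"[int(rng.integers(4))]
                for c in a
            )
            for i in range(5)
        }
        aln = _alignment_from_rows(rows)
        _, s1 = nj_tree(aln, bootstrap_n=30, seed=99)
        _, s2 = nj_tree(aln, bootstrap_n=30, seed=99)
        assert s1 == s2
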