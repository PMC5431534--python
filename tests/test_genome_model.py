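import math

import numpy as np
import pytest

from plastocomp.catalogue import CATALOGUE, SUBCATEGORY_COUNTS, classify_gene
from plastocomp.genome_model import (
    AnnotatedGenome,
    GeneFeature,
    coefficient_of_variation,
    compute_features,
    detect_inverted_repeat,
    revcomp,
    standardize_annotations,
)
from plastocomp.synthetic_data import PlastomeSpec, simulate_plastome

from conftest import brute_force_features


class TestCatalogue:
    def test_total_and_subcategory_counts(self):
        assert len(CATALOGUE) == 126
        expected = {
            ("I", "photosystem I"): 6,
            ("I", "photosystem II"): 15,
            ("I", "cytochrome b6f"): 7,
            ("I", "ATP synthase"): 6,
            ("I", "RuBisCo"): 1,
            ("I", "NAD(P)H dehydrogenase"): 11,
            ("II", "transfer RNA"): 31,
            ("II", "ribosomal RNA"): 4,
            ("II", "RNA polymerase"): 4,
            ("II", "ribosomal subunit"): 21,
            ("III", "ycf"): 8,
            ("III", "open reading frame"): 2,
            ("III", "potential protein-coding"): 10,
        }
        assert SUBCATEGORY_COUNTS == expected

    @pytest.mark.parametrize(
        "name, category, subcategory",
        [
            ("psaA", "I", "photosystem I"),
            ("trnH-GUG", "II", "transfer RNA"),
            ("ycf1", "III", "ycf"),
            ("rps8", "II", "ribosomal subunit"),
            ("RBCL", "I", "RuBisCo"),        # case-insensitive
            ("trnH_GUG", "II", "transfer RNA"),  # punctuation-normalized
            ("orf999", "III", "open reading frame"),  # pattern fallback
        ],
    )
    def test_classify(self, name, category, subcategory):
        entry = classify_gene(name)
        assert (entry.category, entry.subcategory) == (category, subcategory)

    def test_unknown_symbol_raises(self):
        with pytest.raises(KeyError, match="notagene"):
            classify_gene("notagene")


class TestCoefficientOfVariation:
    def test_hand_formula(self):
        assert coefficient_of_variation([2, 4]) == pytest.approx(
            math.sqrt(2) / 3, abs=1e-12
        )

    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation([7.0, 7.0, 7.0]) == 0.0

    @pytest.mark.parametrize("c", [0.5, 2.0, 1e6])
    def test_scale_invariance(self, c, rng):
        x = rng.gamma(5.0, 2.0, size=20)
        assert coefficient_of_variation(c * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-10
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


def _rand_seq(rng, n, gc=0.4):
    return "".join(
        rng.choice(list("ACGT"), size=n, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    )


class TestStandardize:
    def _genome(self, gid, genes, n=6000):
        return AnnotatedGenome(gid, "ACGT" * (n // 4), genes)

    def test_successive_same_name_merged_to_multisegment(self):
        g = self._genome("s1", [
            GeneFeature("clpP", "+", [(100, 200)]),
            GeneFeature("clpP", "+", [(300, 400)]),
        ])
        (out,) = standardize_annotations([g])
        assert len(out.genes) == 1
        assert out.genes[0].segments == [(100, 200), (300, 400)]

    def test_distant_ir_duplicates_not_merged(self):
        g = self._genome("s1", [
            GeneFeature("rrn16", "+", [(0, 100)]),
            GeneFeature("rrn16", "-", [(5800, 5900)]),
        ])
        (out,) = standardize_annotations([g], max_merge_gap=1000)
        assert len(out.genes) == 2

    def test_orf_overlapping_catalogue_gene_dropped(self):
        g = self._genome("s1", [
            GeneFeature("ndhA", "+", [(500, 1600)]),
            GeneFeature("orf188", "+", [(600, 1100)]),
        ])
        (out,) = standardize_annotations([g])
        assert [f.name for f in out.genes] == ["ndhA"]

    def test_singleton_gene_removed_across_set(self):
        g1 = self._genome("s1", [
            GeneFeature("rbcL", "+", [(0, 900)]),
            GeneFeature("orf574", "+", [(2000, 2600)]),
        ])
        g2 = self._genome("s2", [GeneFeature("rbcL", "+", [(0, 900)])])
        g3 = self._genome("s3", [GeneFeature("rbcL", "+", [(0, 900)])])
        out = standardize_annotations([g1, g2, g3])
        assert [f.name for f in out[0].genes] == ["rbcL"]

    def test_catalogue_overlap_flagged_not_merged(self):
        g = self._genome("s1", [
            GeneFeature("psbA", "+", [(3000, 4000)]),
            GeneFeature("psbB", "+", [(3900, 4800)]),
        ])
        out, issues = standardize_annotations([g], with_report=True)
        assert len(out[0].genes) == 2
        assert len(issues) == 1
        assert set(issues[0].genes) == {"psbA", "psbB"}


class TestIRDetection:
    def test_constructed_quadripartite(self, rng):
        lsc = _rand_seq(rng, 600)
        ir = _rand_seq(rng, 100)
        ssc = _rand_seq(rng, 200)
        genome = AnnotatedGenome("c1", lsc + ir + ssc + revcomp(ir))
        part = detect_inverted_repeat(genome, min_len=50, min_identity=1.0)
        assert part is not None
        assert part.ir_len == 100
        assert part.lsc == (0, 600)
        assert part.irb == (600, 700)
        assert part.ssc == (700, 900)
        assert part.ira == (900, 1000)

    def test_no_repeat_returns_absent(self, rng):
        genome = AnnotatedGenome("c2", _rand_seq(rng, 2000))
        assert detect_inverted_repeat(genome, min_len=50, min_identity=1.0) is None

    def test_recovers_generator_ground_truth(self):
        for seed in range(5):
            genome, _ = simulate_plastome(PlastomeSpec.random(seed, scale=0.2))
            found = detect_inverted_repeat(genome, min_len=1000, min_identity=1.0)
            true = genome.partition
            assert found is not None
            assert (found.lsc, found.irb, found.ssc, found.ira) == (
                true.lsc, true.irb, true.ssc, true.ira)


class TestComputeFeatures:
    def test_trivial_sequence_no_genes(self):
        f = compute_features(AnnotatedGenome("t", "ATGC" * 25))
        assert (f.TL, f.GCC, f.GRL, f.IGRL, f.GN) == (100, 0.5, 0, 100, 0)
        assert f.IRL == 0 and f.LSCL is None and f.SSCL is None

    def test_genome_without_r_partition_identity_holds(self, rng):
        spec = PlastomeSpec(lsc_len=3000, ssc_len=1000, ir_len=0,
                            genes_lsc=["rbcL", "psbA"], seed=3)
        genome, truth = simulate_plastome(spec)
        f = compute_features(genome)
        assert f.IRL == 0 and f.LSCL is None
        assert f.GRL + f.IGRL == f.TL
        assert f == truth

    def test_overlapping_segments_counted_once(self):
        g = AnnotatedGenome("o", "ACGT" * 250, [
            GeneFeature("rbcL", "+", [(0, 100)]),
            GeneFeature("atpA", "+", [(50, 150)]),
        ])
        f = compute_features(g)
        assert f.GRL == 150 and f.IGRL == f.TL - 150 and f.GN == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        genome, truth = simulate_plastome(PlastomeSpec.random(seed, scale=0.15))
        f = compute_features(genome)
        oracle = brute_force_features(genome)
        assert f.TL == oracle["TL"]
        assert f.GRL == oracle["GRL"]
        assert f.IGRL == oracle["IGRL"]
        assert f.GN == oracle["GN"]
        assert f.GCC == pytest.approx(oracle["GCC"], abs=1e-12)
        # quadripartite identity
        assert f.LSCL + f.SSCL + 2 * f.IRL == f.TL
        assert f == truth

    def test_gene_out_of_range_errors(self):
        g = AnnotatedGenome("x", "ACGT" * 10)
        g.genes.append(GeneFeature("rbcL", "+", [(30, 50)]))
        with pytest.raises(ValueError):
            compute_features(g)


class TestIO:
    def test_genbank_roundtrip(self, tmp_path):
        from plastocomp.io import read_genbank, write_genbank

        genome, _ = simulate_plastome(PlastomeSpec.random(1, scale=0.1), "sp1")
        path = tmp_path / "sp1.gb"
        write_genbank(genome, str(path))
        back = read_genbank(str(path))
        assert back.sequence == genome.sequence
        assert [(f.name, f.segments, f.strand) for f in back.genes] == [
            (f.name, f.segments, f.strand) for f in genome.genes
        ]

    def test_fasta_gff3_roundtrip(self, tmp_path):
        from plastocomp.io import read_fasta_gff3, write_fasta_gff3

        genome, _ = simulate_plastome(PlastomeSpec.random(2, scale=0.1), "sp2")
        # include a multi-segment feature
        genome.genes[0] = GeneFeature(
            "clpP", "+", [(10, 60), (100, 160)], "protein"
        )
        fa, gff = tmp_path / "sp2.fasta", tmp_path / "sp2.gff3"
        write_fasta_gff3(genome, str(fa), str(gff))
        back = read_fasta_gff3(str(fa), str(gff))
        assert back.sequence == genome.sequence
        got = sorted((f.name, tuple(f.segments)) for f in back.genes)
        want = sorted((f.name, tuple(f.segments)) for f in genome.genes)
        assert got == want
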