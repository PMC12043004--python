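"""Sequential SNP-to-gene mapping and the regionizing partition."""

import numpy as np
import pandas as pd
import pytest

from prsx.io_formats import Cs2gLink, GeneAnnotation, GwasAssociation
from prsx.mapping import (
    Stage,
    links_frame,
    map_all,
    map_cs2g,
    map_fallback,
    map_positional,
    regionize,
    regions_frame,
    synthetic_locus_label,
)


def _variants(rows):
    """rows: (variant_id, chrom, pos[, p_hat, beta_std])"""
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "p_hat",
                                     "beta_std"][: len(rows[0])])
    if "p_hat" not in df.columns:
        df["p_hat"] = 0.5
        df["beta_std"] = 0.1
    return df


GENE = GeneAnnotation("G1", "1", 1_000_000, 1_050_000)


class TestPositional:
    @pytest.mark.parametrize(
        "pos, window, linked, detail",
        [
            (800_000, 200_000, True, 200_000),   # exactly on the boundary
            (800_000, 199_999, False, None),
            (1_250_000, 200_000, True, 200_000),  # downstream boundary
            (1_020_000, 200_000, True, 0),        # inside the gene body
            (1_000_000, 0, True, 0),              # start edge, zero window
        ],
    )
    def test_window_boundaries_inclusive(self, pos, window, linked, detail):
        links = map_positional(_variants([("rs1", "1", pos)]), [GENE], window)
        if linked:
            assert len(links) == 1 and links[0].detail == detail
            assert links[0].stage is Stage.POSITIONAL
        else:
            assert links == []

    def test_other_chromosome_never_links(self):
        links = map_positional(_variants([("rs1", "2", 1_020_000)]), [GENE])
        assert links == []

    def test_against_brute_force_all_pairs_oracle(self, rng):
        genes = [
            GeneAnnotation(f"G{i}", str(rng.integers(1, 4)),
                           int(s := rng.integers(1, 10**7)),
                           int(s + rng.integers(1, 100_000)))
            for i in range(20)
        ]
        snps = [(f"rs{i}", str(rng.integers(1, 4)), int(rng.integers(1, 10**7)))
                for i in range(500)]
        window = 200_000
        links = map_positional(_variants(snps), genes, window)
        got = {(l.variant_id, l.gene) for l in links}
        expected = {
            (vid, g.gene)
            for vid, chrom, pos in snps
            for g in genes
            if chrom == g.chrom and g.start - window <= pos <= g.end + window
        }
        assert got == expected

    def test_monotone_in_window(self, rng):
        snps = [(f"rs{i}", "1", int(rng.integers(1, 3 * 10**6))) for i in range(100)]
        prev: set = set()
        for window in (0, 50_000, 200_000, 500_000):
            cur = {(l.variant_id, l.gene)
                   for l in map_positional(_variants(snps), [GENE], window)}
            assert prev <= cur
            prev = cur


class TestCs2g:
    CS2G = [Cs2gLink("rs1", "GA", 0.9), Cs2gLink("rs1", "GB", 0.4),
            Cs2gLink("rs2", "GC", 0.2)]

    def test_unlinked_variant_takes_all_rows(self):
        links = map_cs2g(_variants([("rs1", "9", 100)]), self.CS2G)
        assert {(l.gene, l.detail) for l in links} == {("GA", 0.9), ("GB", 0.4)}
        assert all(l.stage is Stage.CS2G for l in links)

    def test_min_score_filters(self):
        links = map_cs2g(_variants([("rs1", "9", 100)]), self.CS2G, min_score=0.5)
        assert [l.gene for l in links] == ["GA"]

    def test_sequential_rule_positionally_linked_skips_cs2g(self):
        variants = _variants([("rs1", "1", 1_020_000), ("rs2", "9", 100)])
        links = map_all(variants, [GENE], self.CS2G, [])
        stage_of = {l.variant_id: l.stage for l in links}
        assert stage_of["rs1"] is Stage.POSITIONAL
        assert stage_of["rs2"] is Stage.CS2G

    def test_cs2g_only_variants_all_gain_links(self, rng):
        k = 7
        variants = _variants([(f"rs{i}", "9", 100 + i) for i in range(k)])
        cs2g = [Cs2gLink(f"rs{i}", f"G{i}", 0.5) for i in range(k)]
        links = map_all(variants, [GENE], cs2g, [])
        assert {l.variant_id for l in links if l.stage is Stage.CS2G} == {
            f"rs{i}" for i in range(k)
        }


class TestFallback:
    def test_no_association_in_range_gives_synthetic_locus(self):
        links = map_fallback(_variants([("rs1", "7", 23_456_789, 0.3, 0.2)]), [])
        assert links[0].gene == "chr7:23Mb"
        assert links[0].detail == pytest.approx(2 * 0.3 * 0.7 * 0.04)

    def test_smallest_p_wins(self):
        gwas = [GwasAssociation("1", 1000, "FAR_BUT_SMALL_P", 1e-9),
                GwasAssociation("1", 150, "NEAR_BIG_P", 1e-3)]
        links = map_fallback(_variants([("rs1", "1", 100, 0.5, 0.1)]), gwas)
        assert links[0].gene == "FAR_BUT_SMALL_P"

    def test_equal_p_broken_by_distance_then_name(self):
        gwas = [GwasAssociation("1", 1000, "FAR", 1e-6),
                GwasAssociation("1", 150, "NEAR", 1e-6)]
        links = map_fallback(_variants([("rs1", "1", 100, 0.5, 0.1)]), gwas)
        assert links[0].gene == "NEAR"
        gwas = [GwasAssociation("1", 200, "BBB", 1e-6),
                GwasAssociation("1", 200, "AAA", 1e-6)]
        links = map_fallback(_variants([("rs1", "1", 100, 0.5, 0.1)]), gwas)
        assert links[0].gene == "AAA"

    def test_max_dist_excludes_far_associations(self):
        gwas = [GwasAssociation("1", 5_000_000, "FAR", 1e-9)]
        links = map_fallback(_variants([("rs1", "1", 100, 0.5, 0.1)]), gwas,
                             max_dist_bp=1_000_000)
        assert links[0].gene == synthetic_locus_label("1", 100)

    def test_totality_every_variant_linked(self, fitted):
        linked = {l.variant_id for l in fitted.links}
        assert linked == set(fitted.harmonized.variants["variant_id"])


def _closure_oracle(gene_snps: dict[str, set]) -> list[frozenset]:
    """Brute-force transitive closure over the shared-SNP relation."""
    comps = [({g}, set(s)) for g, s in gene_snps.items()]
    changed = True
    while changed:
        changed = False
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                if comps[i][1] & comps[j][1]:
                    comps[i] = (comps[i][0] | comps[j][0],
                                comps[i][1] | comps[j][1])
                    del comps[j]
                    changed = True
                    break
            if changed:
                break
    return [frozenset(c[0]) for c in comps]


def _mk_links(gene_snps, variants):
    from prsx.mapping import SnpGeneLink
    return [SnpGeneLink(s, g, Stage.POSITIONAL, 0.0)
            for g, snps in gene_snps.items() for s in snps]


class TestRegionize:
    def test_two_genes_sharing_one_snp_merge(self):
        gene_snps = {"A": {"rs1", "rs2"}, "B": {"rs2", "rs3"}}
        variants = _variants([("rs1", "1", 100), ("rs2", "1", 200),
                              ("rs3", "1", 300)])
        (region,) = regionize(_mk_links(gene_snps, variants), variants)
        assert region.region_id == "A+B"
        assert region.variant_ids == {"rs1", "rs2", "rs3"}
        assert region.span == (100, 300)

    def test_disjoint_genes_stay_separate(self):
        gene_snps = {"A": {"rs1"}, "B": {"rs2"}}
        variants = _variants([("rs1", "1", 100), ("rs2", "1", 200)])
        regions = regionize(_mk_links(gene_snps, variants), variants)
        assert len(regions) == 2

    def test_chain_closure_matches_oracle(self, rng):
        genes = [f"G{i}" for i in range(30)]
        snps = [f"rs{i}" for i in range(120)]
        gene_snps = {
            g: {snps[int(i)] for i in rng.integers(0, len(snps), 5)} for g in genes
        }
        variants = _variants([(s, "1", 100 + i) for i, s in enumerate(snps)])
        regions = regionize(_mk_links(gene_snps, variants), variants)
        assert sorted(tuple(sorted(r.genes)) for r in regions) == sorted(
            tuple(sorted(c)) for c in _closure_oracle(gene_snps)
        )

    def test_partition_of_variants(self, rng):
        genes = [f"G{i}" for i in range(15)]
        snps = [f"rs{i}" for i in range(60)]
        gene_snps = {g: {snps[int(i)] for i in rng.integers(0, 60, 4)} for g in genes}
        variants = _variants([(s, "1", 100 + i) for i, s in enumerate(snps)])
        regions = regionize(_mk_links(gene_snps, variants), variants)
        all_assigned = [v for r in regions for v in r.variant_ids]
        assert len(all_assigned) == len(set(all_assigned))  # pairwise disjoint
        assert set(all_assigned) == set().union(*gene_snps.values())

    def test_region_id_truncation_past_three_genes(self):
        gene_snps = {f"G{i}": {"shared", f"rs{i}"} for i in range(5)}
        variants = _variants(
            [("shared", "1", 50)] + [(f"rs{i}", "1", 100 + 10 * i) for i in range(5)]
        )
        (region,) = regionize(_mk_links(gene_snps, variants), variants)
        assert region.region_id.endswith("+2 more")
        assert len(region.genes) == 5

    def test_deterministic_region_table(self, small_sim, fitted):
        df1 = regions_frame(fitted.regions).to_csv(sep="\t")
        links2 = map_all(fitted.harmonized.variants, small_sim.annotation,
                         small_sim.cs2g, small_sim.gwas)
        df2 = regions_frame(
            regionize(links2, fitted.harmonized.variants, small_sim.annotation)
        ).to_csv(sep="\t")
        assert df1 == df2


class TestStagePriority:
    def test_each_variant_links_from_single_earliest_stage(self, fitted):
        df = links_frame(fitted.links)
        stages_per_variant = df.groupby("variant_id")["stage"].nunique()
        assert (stages_per_variant == 1).all()

    def test_planted_stages_recovered(self, small_sim, fitted):
        expect = {"positional": "positional", "cs2g": "cs2g",
                  "gwas_fallback": "gwas_fallback",
                  "synthetic_locus": "gwas_fallback"}
        got = links_frame(fitted.links).drop_duplicates("variant_id").set_index(
            "variant_id")["stage"]
        for vid, planted in small_sim.truth["stage_by_snp"].items():
            assert got[vid] == expect[planted], vid
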