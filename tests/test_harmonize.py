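"""Allele matching, frequency estimation and PRS standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prsx import io_formats as io
from prsx.harmonize import (
    DegeneratePRSError,
    estimate_allele_freq,
    harmonize,
    match_alleles,
    standardize,
)
from prsx.io_formats import MISSING, GenotypePanel, ScoringVariant
from prsx.model import PRSDecomposition
from prsx.synthetic import SimConfig, simulate


def _panel(bim_rows, dosage):
    bim = pd.DataFrame(bim_rows, columns=["chrom", "variant_id", "cm", "pos",
                                          "a1", "a2"])
    dosage = np.asarray(dosage, dtype=np.int8)
    return GenotypePanel([f"S{j}" for j in range(dosage.shape[0])],
                         list(bim["variant_id"]), bim, dosage)


class TestMatchAlleles:
    def test_direct_match_no_flip(self):
        panel = _panel([("1", "rs1", "0", 100, "A", "G")], [[1], [2]])
        scoring = [ScoringVariant("rs1", "1", 100, "A", "G", 0.5)]
        idx, sign, rep = match_alleles(scoring, panel)
        assert list(idx) == [0] and list(sign) == [1]
        assert rep.n_matched == 1 and rep.n_sign_flipped == 0

    def test_swapped_alleles_reflect_dosage(self):
        panel = _panel([("1", "rs1", "0", 100, "G", "A")], [[0], [2]])
        scoring = [ScoringVariant("rs1", "1", 100, "A", "G", 0.5)]
        idx, sign, rep = match_alleles(scoring, panel)
        assert list(sign) == [-1]
        assert rep.n_sign_flipped == 1
        h = standardize(panel, scoring, idx, sign, rep)
        # panel counted G; dosages 0,2 of G are 2,0 of the effect allele A
        np.testing.assert_allclose(h.dosage_effect[:, 0], [2.0, 0.0])

    def test_palindromic_variant_dropped_as_ambiguous(self):
        panel = _panel([("1", "rs1", "0", 100, "A", "T")], [[1], [2]])
        scoring = [ScoringVariant("rs1", "1", 100, "A", "T", 0.5)]
        _, _, rep = match_alleles(scoring, panel)
        assert rep.n_ambiguous_dropped == 1 and rep.n_matched == 0

    def test_mismatching_allele_set_is_unmatched(self):
        panel = _panel([("1", "rs1", "0", 100, "C", "G")], [[1], [2]])
        scoring = [ScoringVariant("rs1", "1", 100, "A", "G", 0.5)]
        _, _, rep = match_alleles(scoring, panel)
        assert rep.n_unmatched == 1

    def test_report_partitions_scoring_variants(self, small_sim):
        _, _, rep = match_alleles(small_sim.scoring, small_sim.panel)
        assert rep.n_matched + rep.n_unmatched + rep.n_ambiguous_dropped == len(
            small_sim.scoring
        )

    def test_duplicate_panel_variant_id_raises(self):
        panel = _panel(
            [("1", "rs1", "0", 100, "A", "G"), ("1", "rs1", "0", 200, "C", "T")],
            [[1, 1], [2, 0]],
        )
        with pytest.raises(ValueError, match="duplicate"):
            match_alleles([ScoringVariant("rs1", "1", 100, "A", "G", 0.5)], panel)


class TestAlleleFreq:
    def test_simple_arithmetic(self):
        p_raw, p_clip = estimate_allele_freq(np.array([[0], [1], [2]]))
        assert p_raw[0] == p_clip[0] == 0.5

    def test_monomorphic_clipped_away_from_one(self):
        p_raw, p_clip = estimate_allele_freq(np.array([[2], [2]]))
        assert p_raw[0] == 1.0 and p_clip[0] == 1.0 - 1.0 / 6.0

    def test_hwe_cohort_estimate_within_3_se(self):
        rng = np.random.default_rng(42)
        n, p = 2000, 0.3
        dos = rng.binomial(2, p, size=(n, 1)).astype(np.int8)
        p_raw, _ = estimate_allele_freq(dos)
        se = np.sqrt(p * (1 - p) / (2 * n))
        assert abs(p_raw[0] - p) < 3 * se


class TestStandardize:
    def test_single_variant_hand_computation(self):
        # beta=1, dosages [0,2]: prs_raw=[0,2], sample sd (n-1) = sqrt(2),
        # centered dosage [-1,+1] => prs_std = [-1/sqrt(2), +1/sqrt(2)]
        panel = _panel([("1", "rs1", "0", 100, "A", "G")], [[0], [2]])
        scoring = [ScoringVariant("rs1", "1", 100, "A", "G", 1.0)]
        h = harmonize(scoring, panel)
        np.testing.assert_allclose(h.prs_std, [-1 / np.sqrt(2), 1 / np.sqrt(2)],
                                   atol=1e-12)
        assert h.sd_raw == pytest.approx(np.sqrt(2))

    def test_all_zero_betas_degenerate(self):
        panel = _panel([("1", "rs1", "0", 100, "A", "G")], [[0], [2]])
        scoring = [ScoringVariant("rs1", "1", 100, "A", "G", 0.0)]
        with pytest.raises(DegeneratePRSError, match="degenerate"):
            harmonize(scoring, panel)

    def test_cohort_mean_zero_sd_one(self, fitted):
        h = fitted.harmonized
        assert abs(h.prs_std.mean()) < 1e-8
        assert abs(h.prs_std.std(ddof=1) - 1) < 1e-8

    def test_affine_identity_between_raw_and_std(self, fitted):
        h = fitted.harmonized
        expected = (h.prs_raw - h.mean_raw) / h.sd_raw
        np.testing.assert_allclose(h.prs_std, expected, atol=1e-10)

    def test_beta_std_is_beta_raw_over_sd(self, fitted):
        v = fitted.harmonized.variants
        np.testing.assert_allclose(
            v["beta_std"], v["beta_raw"] / fitted.harmonized.sd_raw, atol=1e-12
        )

    def test_missing_dosage_contributes_zero(self):
        panel = _panel([("1", "rs1", "0", 100, "A", "G"),
                        ("1", "rs2", "0", 200, "C", "T")],
                       [[0, MISSING], [1, 0], [2, 2], [1, 1]])
        scoring = [ScoringVariant("rs1", "1", 100, "A", "G", 0.7),
                   ScoringVariant("rs2", "1", 200, "C", "T", -0.3)]
        h = harmonize(scoring, panel)
        # sample 0's rs2 call was missing; its centered dosage must be 0
        assert h.dosage_centered[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_variant_level_additivity(self, fitted):
        h = fitted.harmonized
        terms = h.dosage_centered * h.variants["beta_std"].to_numpy()[None, :]
        np.testing.assert_allclose(terms.sum(axis=1), h.prs_std, atol=1e-10)

    def test_literal_center_constant_mode(self):
        panel = _panel([("1", "rs1", "0", 100, "A", "G")], [[0], [2]])
        scoring = [ScoringVariant("rs1", "1", 100, "A", "G", 1.0)]
        h = harmonize(scoring, panel, center_constant="p")
        # centered by p=0.5 instead of 2p=1: dosages become [-0.5, 1.5]
        np.testing.assert_allclose(h.dosage_centered[:, 0], [-0.5, 1.5])


def _reflect(v: ScoringVariant) -> ScoringVariant:
    return ScoringVariant(v.variant_id, v.chrom, v.pos,
                          v.other_allele, v.effect_allele, -v.beta)


class TestInvariances:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_reflection_invariance(self, seed):
        """Swapping effect/other alleles while negating beta changes nothing."""
        rng = np.random.default_rng(seed)
        m, n = 8, 30
        sim = simulate(SimConfig(n_samples=n, seed=seed % 2**16,
                                 snps_per_gene=m, genes=[("G1", "1", 10**6, 2 * 10**6)],
                                 planted_h2_fractions=[0.9], n_intergenic_snps=0))
        flip = rng.random(m) < 0.5
        reflected = [_reflect(v) if f else v for v, f in zip(sim.scoring, flip)]
        h0 = harmonize(sim.scoring, sim.panel)
        h1 = harmonize(reflected, sim.panel)
        np.testing.assert_allclose(h1.prs_raw - h1.prs_raw.mean(),
                                   h0.prs_raw - h0.prs_raw.mean(), atol=1e-10)
        np.testing.assert_allclose(h1.prs_std, h0.prs_std, atol=1e-10)

    @pytest.mark.parametrize("c", [1e-3, 0.37, 7.3, 1e3])
    def test_global_beta_rescaling_absorbed(self, c, small_sim):
        scaled = [
            ScoringVariant(v.variant_id, v.chrom, v.pos, v.effect_allele,
                           v.other_allele, c * v.beta)
            for v in small_sim.scoring
        ]
        h0 = harmonize(small_sim.scoring, small_sim.panel)
        h1 = harmonize(scaled, small_sim.panel)
        np.testing.assert_allclose(h1.prs_std, h0.prs_std, atol=1e-10)


class TestIndividualMode:
    def test_individual_scored_against_reference_matches_cohort_fit(self, small_sim,
                                                                     fitted):
        # score one cohort member alone against the full cohort as reference:
        # frequencies/means/sd come from the reference, so the value agrees
        panel = small_sim.panel
        j = 7
        sub = io.GenotypePanel([panel.sample_ids[j]], list(panel.variant_ids),
                               panel.bim, panel.dosage[[j], :])
        model = PRSDecomposition(sub, small_sim.scoring, small_sim.gwas,
                                 small_sim.annotation, small_sim.cs2g)
        res = model.fit(reference=fitted)
        np.testing.assert_allclose(res.harmonized.prs_std[0],
                                   fitted.harmonized.prs_std[j], atol=1e-10)
        np.testing.assert_allclose(res.attribution.a_gene[0],
                                   fitted.attribution.a_gene[j], atol=1e-10)
        assert res.percentile(panel.sample_ids[j]) == pytest.approx(
            fitted.percentile(panel.sample_ids[j])
        )
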