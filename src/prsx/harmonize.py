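"""Align scoring variants to the genotype panel and standardize the PRS.

Harmonization reconciles the scoring file's allele orientation with the
genotype panel's counted allele (matching, reflecting ``2 - G``, dropping
ambiguous palindromic A/T and C/G variants), estimates effect-allele
frequencies, computes the raw PRS and rescales it to a standardized score:

    beta_std_i = beta_raw_i / sd(prs_raw)
    G'_ij      = G_ij - 2 * p_i          (mean-centered effect-allele dosage)
    prs_std_j  = sum_i beta_std_i * G'_ij

so that across a cohort ``prs_std`` has mean 0 and standard deviation 1
(sample, n-1 denominator), and each variant's centered term is its additive
contribution. Missing genotypes are imputed to ``2 * p_i`` (the cohort mean),
which makes their contribution exactly zero.

For a diploid 0/1/2 dosage the mean-zero centering constant is ``2p``; a
``center_constant="p"`` mode subtracting ``p`` instead is available, at the
cost of the mean-zero and SHAP-mean-zero identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypePanel, ScoringVariant

__all__ = [
    "HarmonizedPanel",
    "HarmonizationReport",
    "DegeneratePRSError",
    "match_alleles",
    "estimate_allele_freq",
    "standardize",
    "harmonize",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class DegeneratePRSError(ValueError):
    """The raw PRS has zero variance; no standardization is possible."""


@dataclass
class HarmonizationReport:
    """Per-variant accounting of allele matching.

    n_matched + n_unmatched + n_ambiguous_dropped equals the number of
    scoring variants offered; sign-flipped variants are a subset of matched.
    """

    matched: list[str] = field(default_factory=list)
    sign_flipped: list[str] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)
    ambiguous_dropped: list[str] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    @property
    def n_sign_flipped(self) -> int:
        return len(self.sign_flipped)

    @property
    def n_unmatched(self) -> int:
        return len(self.unmatched)

    @property
    def n_ambiguous_dropped(self) -> int:
        return len(self.ambiguous_dropped)

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(v, "matched", +1) for v in self.matched if v not in set(self.sign_flipped)]
            + [(v, "matched", -1) for v in self.sign_flipped]
            + [(v, "unmatched", 0) for v in self.unmatched]
            + [(v, "ambiguous_dropped", 0) for v in self.ambiguous_dropped]
        )
        return pd.DataFrame(rows, columns=["variant_id", "status", "sign"])


@dataclass
class HarmonizedPanel:
    """Aligned effect-allele dosage matrix with standardized weights and PRS.

    ``variants`` columns: variant_id, chrom, pos, effect_allele, p_hat,
    beta_raw, beta_std. ``dosage_effect`` is samples x variants, counts of
    the effect allele as floats with missing calls imputed to ``2 * p_hat``.
    ``p_hat`` is clipped away from 0/1 for downstream variance formulas; the
    centering itself uses the unclipped per-variant dosage mean so that
    centered contributions are exactly mean-zero even for monomorphic sites.
    """

    variants: pd.DataFrame
    dosage_effect: np.ndarray
    dosage_centered: np.ndarray
    sample_ids: list[str]
    prs_raw: np.ndarray
    prs_std: np.ndarray
    mean_raw: float
    sd_raw: float
    report: HarmonizationReport
    center_constant: str = "2p"

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def prs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "prs_raw": self.prs_raw,
             "prs_std": self.prs_std}
        )


def _is_palindromic(a: str, b: str) -> bool:
    return _COMPLEMENT.get(a) == b


def match_alleles(
    scoring: list[ScoringVariant], panel: GenotypePanel
) -> tuple[np.ndarray, np.ndarray, HarmonizationReport]:
    """Match scoring variants to panel variants and orient alleles.

    The join key is the variant id when both sides carry rsIDs, otherwise
    ``chrom:pos``. Returns parallel arrays over the *matched* scoring
    variants: ``index_map`` (scoring index -> panel column) and ``sign_map``
    (+1 when the panel's counted allele is the effect allele, -1 when the
    dosage must be reflected ``2 - G``), plus the report. Palindromic
    variants (A/T, C/G) are dropped as strand-ambiguous; allele pairs that
    match neither orientation are unmatched.
    """
    ids = pd.Index(panel.variant_ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate variant_id in panel: {dups[:5]}")

    both_rsid = all(v.variant_id.startswith("rs") for v in scoring) and all(
        str(v).startswith("rs") for v in panel.variant_ids
    )
    if both_rsid:
        key_to_col = {vid: i for i, vid in enumerate(panel.variant_ids)}
        keys = [v.variant_id for v in scoring]
    else:
        key_to_col = {
            f"{r.chrom}:{r.pos}": i for i, r in enumerate(panel.bim.itertuples())
        }
        keys = [f"{v.chrom}:{v.pos}" for v in scoring]

    a1 = panel.bim["a1"].to_numpy()
    a2 = panel.bim["a2"].to_numpy()
    report = HarmonizationReport()
    idx: list[int] = []
    sign: list[int] = []
    scoring_idx: list[int] = []
    for si, (v, key) in enumerate(zip(scoring, keys)):
        if _is_palindromic(v.effect_allele, v.other_allele):
            report.ambiguous_dropped.append(v.variant_id)
            continue
        col = key_to_col.get(key)
        if col is None:
            report.unmatched.append(v.variant_id)
            continue
        if v.effect_allele == a1[col] and v.other_allele == a2[col]:
            report.matched.append(v.variant_id)
            idx.append(col)
            sign.append(+1)
            scoring_idx.append(si)
        elif v.effect_allele == a2[col] and v.other_allele == a1[col]:
            report.matched.append(v.variant_id)
            report.sign_flipped.append(v.variant_id)
            idx.append(col)
            sign.append(-1)
            scoring_idx.append(si)
        else:
            report.unmatched.append(v.variant_id)
    index_map = np.array(idx, dtype=np.int64)
    sign_map = np.array(sign, dtype=np.int64)
    index_map_scoring = np.array(scoring_idx, dtype=np.int64)
    # stash the scoring-side indices on the report for the orchestrator
    report._scoring_indices = index_map_scoring  # type: ignore[attr-defined]
    return index_map, sign_map, report


def estimate_allele_freq(dosage_effect: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Effect-allele frequency per variant from hard calls.

    Returns ``(p_raw, p_clip)``: the plain estimate (effect-allele count over
    2 x non-missing calls) and the copy clipped to
    ``[1/(2n+2), 1 - 1/(2n+2)]`` to avoid degenerate 0/1 frequencies in
    variance formulas. Variants with all calls missing get NaN and should be
    dropped by the caller.
    """
    obs = dosage_effect != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_raw = np.where(obs, dosage_effect, 0).sum(axis=0) / (2.0 * n_obs)
    p_raw = np.where(n_obs == 0, np.nan, p_raw)
    n = dosage_effect.shape[0]
    eps = 1.0 / (2.0 * n + 2.0)
    return p_raw, np.clip(p_raw, eps, 1.0 - eps)


def standardize(
    panel: GenotypePanel,
    scoring: list[ScoringVariant],
    index_map: np.ndarray,
    sign_map: np.ndarray,
    report: HarmonizationReport,
    reference: HarmonizedPanel | None = None,
    center_constant: str = "2p",
) -> HarmonizedPanel:
    """Build the harmonized panel: frequencies, imputation, raw and std PRS.

    In cohort mode (``reference=None``) the frequencies, centering constants,
    ``mean_raw`` and ``sd_raw`` come from this cohort, so ``prs_std`` has
    sample mean 0 and sd 1. In individual mode they come from a reference
    cohort of matching ancestry, and the panel's samples are scored against
    that reference's distribution.
    """
    if center_constant not in ("2p", "p"):
        raise ValueError("center_constant must be '2p' or 'p'")
    scoring_idx = report._scoring_indices  # type: ignore[attr-defined]
    betas = np.array([scoring[i].beta for i in scoring_idx], dtype=float)
    meta = pd.DataFrame(
        {
            "variant_id": [scoring[i].variant_id for i in scoring_idx],
            "chrom": [scoring[i].chrom for i in scoring_idx],
            "pos": [scoring[i].pos for i in scoring_idx],
            "effect_allele": [scoring[i].effect_allele for i in scoring_idx],
        }
    )

    dos = panel.dosage[:, index_map].astype(float)
    miss = dos == MISSING
    # reflect to effect-allele counts where the panel counted the other allele
    dos = np.where(miss, np.nan, np.where(sign_map[None, :] == -1, 2.0 - dos, dos))

    if reference is None:
        obs = ~np.isnan(dos)
        n_obs = obs.sum(axis=0)
        keep = n_obs > 0
        if not keep.all():
            import warnings

            warnings.warn(
                f"dropping {int((~keep).sum())} variant(s) with all calls missing",
                stacklevel=2,
            )
            dos, betas, meta = dos[:, keep], betas[keep], meta.loc[keep].reset_index(drop=True)
            obs = obs[:, keep]
        with np.errstate(invalid="ignore"):
            p_raw = np.nansum(dos, axis=0) / (2.0 * obs.sum(axis=0))
        n = dos.shape[0]
        eps = 1.0 / (2.0 * n + 2.0)
        p_hat = np.clip(p_raw, eps, 1.0 - eps)
    else:
        ref_v = reference.variants.set_index("variant_id")
        keep = meta["variant_id"].isin(ref_v.index).to_numpy()
        dos, betas, meta = dos[:, keep], betas[keep], meta.loc[keep].reset_index(drop=True)
        ref_rows = ref_v.loc[meta["variant_id"]]
        p_raw = ref_rows["p_raw"].to_numpy()
        p_hat = ref_rows["p_hat"].to_numpy()

    # impute missing to the (unclipped) cohort mean: contribution becomes zero
    dos = np.where(np.isnan(dos), 2.0 * p_raw[None, :], dos)
    center = 2.0 * p_raw if center_constant == "2p" else p_raw
    centered = dos - center[None, :]

    prs_raw = dos @ betas
    if reference is None:
        mean_raw = float(betas @ center)
        sd_raw = float(np.std(prs_raw, ddof=1)) if len(prs_raw) > 1 else 0.0
    else:
        mean_raw, sd_raw = reference.mean_raw, reference.sd_raw
    if not sd_raw > 0:
        raise DegeneratePRSError(
            "degenerate PRS: raw score has zero variance "
            "(all betas zero or no polymorphic matched variants)"
        )
    beta_std = betas / sd_raw
    prs_std = centered @ beta_std

    meta = meta.assign(p_raw=p_raw, p_hat=p_hat, beta_raw=betas, beta_std=beta_std)
    return HarmonizedPanel(
        variants=meta,
        dosage_effect=dos,
        dosage_centered=centered,
        sample_ids=list(panel.sample_ids),
        prs_raw=prs_raw,
        prs_std=prs_std,
        mean_raw=mean_raw,
        sd_raw=sd_raw,
        report=report,
        center_constant=center_constant,
    )


def harmonize(
    scoring: list[ScoringVariant],
    panel: GenotypePanel,
    reference: HarmonizedPanel | None = None,
    center_constant: str = "2p",
) -> HarmonizedPanel:
    """Match alleles then standardize; the one-call cohort entry point."""
    index_map, sign_map, report = match_alleles(scoring, panel)
    return standardize(
        panel, scoring, index_map, sign_map, report,
        reference=reference, center_constant=center_constant,
    )
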