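"""Contribution scores, attributed (SHAP) values and their population variances.

With standardized weights ``beta_std_i`` and centered effect-allele dosages
``G'_ij = G_ij - 2 p_i``:

* per-SNP contribution        ``CS_SNP[j,i]  = beta_std_i * G'_ij``
* per-region contribution     ``CS_gene[j,r] = sum_{i in r} CS_SNP[j,i]``
* attributed value            ``A_gene[j,r]  = CS_gene[j,r] - mean_j CS_gene[.,r]``

Because the regions partition the SNPs, contributions add up exactly:
``sum_i CS_SNP = sum_r CS_gene = prs_std`` per sample. The population
variance of each ``CS_gene`` column is the heritability attributable to the
region (under HWE/LE it equals ``sum_i 2 p_i (1-p_i) beta_std_i^2``).

``A_gene`` is the exact Shapley value of the region in the additive game
where the standardized PRS is the payoff and absent regions are replaced by
their population-mean contributions; :func:`shapley_oracle` enumerates all
``2^k`` coalitions to verify this identity on small instances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .harmonize import HarmonizedPanel
from .mapping import Region

__all__ = [
    "AttributionResult",
    "compute_cs_snp",
    "compute_cs_gene",
    "compute_variance",
    "compute_a_gene",
    "shapley_oracle",
    "compute_percentile",
    "attribute",
]


@dataclass
class AttributionResult:
    """Per-individual, per-region attribution plus population summaries.

    All matrices are samples x regions (or samples x variants for
    ``cs_snp``), indexed consistently with ``sample_ids`` / ``region_ids`` /
    ``variant_ids``.
    """

    sample_ids: list[str]
    region_ids: list[str]
    variant_ids: list[str]
    regions: list[Region]
    cs_snp: np.ndarray
    cs_gene: np.ndarray
    cs_gene_mean: np.ndarray
    cs_gene_var: np.ndarray
    a_gene: np.ndarray
    prs_std: np.ndarray
    percentile: np.ndarray

    def population_table(self) -> pd.DataFrame:
        """Regions ranked by contribution-score variance (heritability)."""
        df = pd.DataFrame(
            {
                "region_id": self.region_ids,
                "genes": [",".join(sorted(r.genes)) for r in self.regions],
                "n_snps": [len(r.variant_ids) for r in self.regions],
                "cs_gene_var": self.cs_gene_var,
            }
        )
        df = df.sort_values(
            ["cs_gene_var", "region_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    def individual_table(self, sample_id: str) -> pd.DataFrame:
        """One sample's per-region scores ranked by attributed value."""
        j = self._sample_index(sample_id)
        df = pd.DataFrame(
            {
                "region_id": self.region_ids,
                "cs_gene": self.cs_gene[j],
                "a_gene": self.a_gene[j],
            }
        )
        df = df.sort_values(
            ["a_gene", "region_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    def snp_table(self, sample_id: str) -> pd.DataFrame:
        j = self._sample_index(sample_id)
        region_of = {
            v: r.region_id for r in self.regions for v in r.variant_ids
        }
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "region_id": [region_of[v] for v in self.variant_ids],
                "cs_snp": self.cs_snp[j],
            }
        )

    def _sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(
                f"unknown sample id {sample_id!r}; available: "
                f"{', '.join(self.sample_ids[:10])}"
                + ("..." if len(self.sample_ids) > 10 else "")
            ) from None


def compute_cs_snp(harmonized: HarmonizedPanel) -> np.ndarray:
    """Per-SNP contributions ``beta_std_i * G'_ij`` (samples x variants)."""
    beta_std = harmonized.variants["beta_std"].to_numpy()
    return harmonized.dosage_centered * beta_std[None, :]


def compute_cs_gene(
    cs_snp: np.ndarray,
    variant_ids: list[str],
    regions: list[Region],
) -> tuple[np.ndarray, list[Region]]:
    """Sum per-SNP contributions within each region.

    Regions referencing unknown variants raise; regions with no variants in
    the panel are dropped with a warning. Returns the samples x regions
    matrix and the retained regions in order.
    """
    col = {v: i for i, v in enumerate(variant_ids)}
    kept: list[Region] = []
    cols: list[np.ndarray] = []
    for r in regions:
        unknown = [v for v in r.variant_ids if v not in col]
        if unknown and len(unknown) < len(r.variant_ids):
            raise ValueError(
                f"region {r.region_id} references unknown variant(s): {unknown[:5]}"
            )
        if not r.variant_ids or unknown:
            warnings.warn(f"dropping empty region {r.region_id}", stacklevel=2)
            continue
        idx = sorted(col[v] for v in r.variant_ids)
        cols.append(cs_snp[:, idx].sum(axis=1))
        kept.append(r)
    cs_gene = (
        np.column_stack(cols) if cols else np.zeros((cs_snp.shape[0], 0))
    )
    return cs_gene, kept


def compute_variance(cs_gene: np.ndarray) -> np.ndarray:
    """Sample variance (n-1) of each region column: per-region heritability."""
    if cs_gene.shape[0] < 2:
        raise ValueError(
            "variance needs >= 2 samples; use cohort mode or supply a reference cohort"
        )
    return np.var(cs_gene, axis=0, ddof=1)


def compute_a_gene(
    cs_gene: np.ndarray, cs_gene_mean: np.ndarray | None = None
) -> np.ndarray:
    """Attributed values: contribution minus its population mean.

    In cohort mode the mean is taken over the rows of ``cs_gene``; individual
    mode passes reference-cohort means explicitly.
    """
    if cs_gene_mean is None:
        cs_gene_mean = cs_gene.mean(axis=0)
    return cs_gene - cs_gene_mean[None, :]


def shapley_oracle(x: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Exact Shapley values by full coalition enumeration (validation oracle).

    The game: the prediction is the sum of region contributions; regions
    absent from a coalition S are replaced by their population means, so
    ``v(S) = sum_{r in S} x_r + sum_{r not in S} mu_r``. Returns

        phi_r = sum_{S not containing r} |S|! (k-|S|-1)! / k! * [v(S+r) - v(S)]

    Refuses k > 12 (2^k blowup). For this additive game phi_r collapses to
    ``x_r - mu_r``; the enumeration is kept deliberately independent of that
    shortcut so it can serve as an oracle for it.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    k = x.size
    if k > 12:
        raise ValueError(f"shapley_oracle refuses k={k} > 12 regions (2^k coalitions)")

    def v(coalition: tuple[int, ...]) -> float:
        inside = set(coalition)
        return sum(x[i] if i in inside else mu[i] for i in range(k))

    phi = np.zeros(k)
    others = list(range(k))
    for r in range(k):
        rest = [i for i in others if i != r]
        for size in range(k):
            w = math.factorial(size) * math.factorial(k - size - 1) / math.factorial(k)
            for S in combinations(rest, size):
                phi[r] += w * (v(S + (r,)) - v(S))
    return phi


def compute_percentile(prs_std: np.ndarray, target: float) -> float:
    """Mid-rank percentile of ``target`` within the cohort ``prs_std``.

    rank = #(values < target) + (#(values == target) + 1) / 2, expressed as
    ``100 * rank / (n + 1)``. The highest of 99 distinct values sits at the
    99th percentile; an all-tied cohort puts everyone at the 50th.
    """
    prs_std = np.asarray(prs_std, dtype=float)
    n = prs_std.size
    if n < 10:
        raise ValueError(f"percentile needs a cohort of >= 10, got {n}")
    below = float(np.sum(prs_std < target))
    ties = float(np.sum(prs_std == target))
    rank = below + (ties + 1.0) / 2.0
    return 100.0 * rank / (n + 1.0)


def attribute(
    harmonized: HarmonizedPanel,
    regions: list[Region],
    reference: AttributionResult | None = None,
) -> AttributionResult:
    """Full Step-2 computation for a cohort (or against a reference cohort).

    Cohort mode takes means, variances and the percentile cohort from this
    panel. Individual mode (``reference`` given) borrows the reference's
    per-region means/variances and percentile distribution; regions are taken
    from the reference so columns line up.
    """
    cs_snp = compute_cs_snp(harmonized)
    variant_ids = list(harmonized.variants["variant_id"])
    if reference is None:
        cs_gene, kept = compute_cs_gene(cs_snp, variant_ids, regions)
        cs_gene_mean = cs_gene.mean(axis=0)
        cs_gene_var = compute_variance(cs_gene)
        a_gene = compute_a_gene(cs_gene)
        pct = np.array(
            [compute_percentile(harmonized.prs_std, t) for t in harmonized.prs_std]
        )
    else:
        cs_gene, kept = compute_cs_gene(cs_snp, variant_ids, reference.regions)
        cs_gene_mean = reference.cs_gene_mean
        cs_gene_var = reference.cs_gene_var
        a_gene = compute_a_gene(cs_gene, cs_gene_mean)
        pct = np.array(
            [compute_percentile(reference.prs_std, t) for t in harmonized.prs_std]
        )
    return AttributionResult(
        sample_ids=list(harmonized.sample_ids),
        region_ids=[r.region_id for r in kept],
        variant_ids=variant_ids,
        regions=kept,
        cs_snp=cs_snp,
        cs_gene=cs_gene,
        cs_gene_mean=cs_gene_mean,
        cs_gene_var=cs_gene_var,
        a_gene=a_gene,
        prs_std=harmonized.prs_std,
        percentile=pct,
    )
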