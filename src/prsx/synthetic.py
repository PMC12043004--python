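"""Coherent synthetic fixtures: genotypes, scoring, annotation, GWAS, cS2G.

The generator emulates the pipeline's input triple (plus the two optional
tables) with planted structure so every stage is checkable without external
downloads:

* Genotypes are drawn per SNP as binomial(2, p) independently across SNPs and
  samples — Hardy-Weinberg and linkage equilibrium — which makes per-gene
  variance shares analytically predictable: gene g's theoretical share of
  Var(PRS) is ``sum_{i in g} 2 p_i (1-p_i) beta_i^2`` over the total.
* Raw betas are drawn N(0, 1) per SNP and rescaled per gene so the
  theoretical shares match ``planted_h2_fractions``; any remainder is spread
  over intergenic SNPs.
* A planted subset of SNPs sits outside every positional window and is
  reachable only through the cS2G table, only through a GWAS association, or
  through neither (synthetic locus), exercising all three mapping stages.
* ``truth.json`` records the intended mapping stage per SNP and each gene's
  theoretical variance share.

An optional AR(1) correlation mode induces local genotype correlation to
exercise (not validate) the cross-region covariance reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    Cs2gLink,
    GeneAnnotation,
    GenotypePanel,
    GwasAssociation,
    ScoringVariant,
    write_cs2g,
    write_gene_annotation,
    write_gwas_associations,
    write_plink,
    write_scoring_file,
)

__all__ = ["SimConfig", "SimResult", "simulate", "simulate_to_dir", "default_genes"]

# non-palindromic allele pairs only, so no variant is dropped as ambiguous
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


def default_genes(n: int = 3) -> list[tuple[str, str, int, int]]:
    """Well-separated gene bodies (> 1.5 Mb apart, beyond any default window)."""
    out = []
    for i in range(n):
        chrom = str((i % 4) + 1)
        start = 2_000_000 + (i // 4) * 5_000_000
        out.append((f"GENE{i + 1}", chrom, start, start + 50_000))
    return out


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``planted_h2_fractions`` are per-gene theoretical shares of the PRS
    variance (must sum to <= 1; the remainder goes to intergenic SNPs).
    """

    n_samples: int = 500
    genes: list[tuple[str, str, int, int]] = field(
        default_factory=lambda: default_genes(3)
    )
    snps_per_gene: int = 10
    n_intergenic_snps: int = 9
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    beta_scale: float = 0.1
    # leaves a 0.1 share for the intergenic SNPs
    planted_h2_fractions: list[float] = field(
        default_factory=lambda: [0.5, 0.3, 0.1]
    )
    seed: int = 0
    ar1_rho: float = 0.0  # >0 induces local LD (exercise-only mode)

    def __post_init__(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"allele_freq_range must be inside (0,1), got {lo, hi}")
        if len(self.planted_h2_fractions) != len(self.genes):
            raise ValueError("one planted h2 fraction per gene required")
        total = sum(self.planted_h2_fractions)
        if any(f < 0 for f in self.planted_h2_fractions) or total > 1 + 1e-12:
            raise ValueError(
                f"infeasible h2 fractions (negative or summing to {total} > 1)"
            )
        if total >= 1 - 1e-12 and self.n_intergenic_snps > 0:
            raise ValueError(
                "h2 fractions sum to 1 but intergenic SNPs exist; no variance left"
            )


@dataclass
class SimResult:
    """In-memory fixture: the five inputs plus the planted truth."""

    panel: GenotypePanel
    scoring: list[ScoringVariant]
    annotation: list[GeneAnnotation]
    gwas: list[GwasAssociation]
    cs2g: list[Cs2gLink]
    truth: dict


def _gene_h2(p: np.ndarray, beta: np.ndarray) -> float:
    return float(np.sum(2.0 * p * (1.0 - p) * beta**2))


def simulate(config: SimConfig) -> SimResult:
    """Generate a coherent fixture for the given study conditions."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.allele_freq_range

    rows = []  # variant_id, chrom, pos, gene(None), intended stage
    annotation = [
        GeneAnnotation(sym, str(chrom).removeprefix("chr"), int(s), int(e))
        for sym, chrom, s, e in config.genes
    ]
    idx = 0
    for g in annotation:
        for _ in range(config.snps_per_gene):
            pos = int(rng.integers(g.start, g.end + 1))
            rows.append((f"rs{idx}", g.chrom, pos, g.gene, "positional"))
            idx += 1

    # intergenic SNPs: far from every gene window, cycled over the three
    # non-positional fates (cs2g link, gwas association, synthetic locus)
    gwas: list[GwasAssociation] = []
    cs2g: list[Cs2gLink] = []
    far_chrom = "9"  # no default gene lives here
    fates = ["cs2g", "gwas_fallback", "synthetic_locus"]
    for k in range(config.n_intergenic_snps):
        pos = 5_000_000 + k * 3_000_000  # > 1 Mb apart: no shared fallback genes
        vid = f"rs{idx}"
        fate = fates[k % 3]
        rows.append((vid, far_chrom, pos, None, fate))
        if fate == "cs2g":
            cs2g.append(Cs2gLink(vid, f"CS2G_GENE{k}", float(rng.uniform(0.2, 1.0))))
        elif fate == "gwas_fallback":
            gwas.append(
                GwasAssociation(
                    far_chrom, pos + int(rng.integers(0, 50_000)),
                    f"FBGENE{k}", float(10 ** -rng.uniform(6, 9)),
                )
            )
        idx += 1

    m = len(rows)
    n = config.n_samples
    p = rng.uniform(lo, hi, size=m)

    if config.ar1_rho > 0:
        # Gaussian copula with AR(1) correlation, thresholded to allele counts
        rho = config.ar1_rho
        z = np.empty((n, m, 2))
        for hap in range(2):
            e = rng.standard_normal((n, m))
            z[:, 0, hap] = e[:, 0]
            for i in range(1, m):
                z[:, i, hap] = rho * z[:, i - 1, hap] + np.sqrt(1 - rho**2) * e[:, i]
        from scipy.stats import norm

        thresh = norm.ppf(p)
        dosage = (z < thresh[None, :, None]).sum(axis=2).astype(np.int8)
    else:
        dosage = rng.binomial(2, p[None, :], size=(n, m)).astype(np.int8)

    beta = rng.standard_normal(m) * config.beta_scale
    # rescale per gene so theoretical shares match the planted fractions
    gene_of = np.array([r[3] or "" for r in rows])
    var_terms = 2.0 * p * (1.0 - p)
    inter = gene_of == ""
    resid = 1.0 - sum(config.planted_h2_fractions)
    total_target = 1.0  # arbitrary overall scale; shares are what matter
    for g, frac in zip(annotation, config.planted_h2_fractions):
        mask = gene_of == g.gene
        cur = float(np.sum(var_terms[mask] * beta[mask] ** 2))
        if frac == 0:
            beta[mask] = 0.0
        elif cur > 0:
            beta[mask] *= np.sqrt(frac * total_target / cur)
    if inter.any():
        cur = float(np.sum(var_terms[inter] * beta[inter] ** 2))
        if resid <= 0:
            beta[inter] = 0.0
        elif cur > 0:
            beta[inter] *= np.sqrt(resid * total_target / cur)

    pairs = [_ALLELE_PAIRS[int(i)] for i in rng.integers(0, len(_ALLELE_PAIRS), m)]
    bim = pd.DataFrame(
        {
            "chrom": [r[1] for r in rows],
            "variant_id": [r[0] for r in rows],
            "cm": "0",
            "pos": np.array([r[2] for r in rows], dtype=np.int64),
            "a1": [a for a, _ in pairs],  # counted allele = effect allele
            "a2": [b for _, b in pairs],
        }
    )
    panel = GenotypePanel(
        sample_ids=[f"S{j:04d}" for j in range(n)],
        variant_ids=[r[0] for r in rows],
        bim=bim,
        dosage=dosage,
    )
    scoring = [
        ScoringVariant(r[0], r[1], r[2], pairs[i][0], pairs[i][1], float(beta[i]))
        for i, r in enumerate(rows)
    ]

    shares = {}
    for g in annotation:
        mask = gene_of == g.gene
        shares[g.gene] = _gene_h2(p[mask], beta[mask])
    inter_h2 = _gene_h2(p[inter], beta[inter])
    total = sum(shares.values()) + inter_h2
    truth = {
        "seed": config.seed,
        "n_samples": n,
        "n_snps": m,
        "stage_by_snp": {r[0]: r[4] for r in rows},
        "gene_by_snp": {r[0]: r[3] for r in rows},
        "theoretical_h2_share": {
            g: (v / total if total > 0 else 0.0) for g, v in shares.items()
        },
        "intergenic_h2_share": inter_h2 / total if total > 0 else 0.0,
        "allele_freq": {r[0]: float(p[i]) for i, r in enumerate(rows)},
    }
    return SimResult(panel, scoring, annotation, gwas, cs2g, truth)


def simulate_to_dir(config: SimConfig, out_dir: str | Path) -> Path:
    """Write the fixture as files (the exact formats io_formats reads)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate(config)
    write_plink(sim.panel, out / "geno")
    write_scoring_file(sim.scoring, out / "score.tsv")
    write_gene_annotation(sim.annotation, out / "genes.bed")
    write_gwas_associations(sim.gwas, out / "gwas.tsv")
    write_cs2g(sim.cs2g, out / "cs2g.tsv")
    (out / "truth.json").write_text(json.dumps(sim.truth, indent=2, sort_keys=True))
    return out
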