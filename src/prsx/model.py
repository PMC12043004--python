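"""Model/Results surface tying the pipeline together.

:class:`PRSDecomposition` is built from the input data (a genotype panel, a
scoring model, a GWAS association list, and optional annotation / cS2G
tables); ``fit()`` runs harmonization, the three-stage SNP-to-gene mapping,
regionizing and attribution, and returns a :class:`PRSDecompositionResults`
carrying the per-region contribution scores, their population variances
(heritability partition), the SHAP attributed values, per-SNP contributions
and percentiles, with ``summary()``, plotting and report export hanging off
it.

Typical use::

    model = PRSDecomposition.from_files("geno", "score.tsv", "gwas.tsv",
                                        annotation_path="genes.bed")
    res = model.fit()
    print(res.summary())
    res.save_report("out/", individuals=["S0001"])
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as io
from . import mapping as _mapping
from . import report as _report
from . import scores as _scores
from .harmonize import HarmonizedPanel, harmonize as _run_harmonize

__all__ = ["PRSDecomposition", "PRSDecompositionResults"]


class PRSDecomposition:
    """Decompose a polygenic risk score into region and SNP contributions.

    Parameters
    ----------
    panel : GenotypePanel
        Hard-call genotypes (a cohort, or an individual scored against a
        same-ancestry reference via ``reference``).
    scoring : list of ScoringVariant
        The PRS weights (effect allele + raw beta per variant).
    gwas : list of GwasAssociation
        GWAS-Catalog-style associations used by the mapping fallback.
    annotation : list of GeneAnnotation, optional
        Gene bodies for positional mapping; without it mapping relies on
        cS2G and the GWAS fallback alone.
    cs2g : list of Cs2gLink, optional
        Functional SNP-to-gene links for the second mapping stage.
    window_bp, cs2g_min_score, fallback_max_dist_bp, center_constant
        Mapping / harmonization tuning; defaults are 200 kb, 0, 1 Mb, "2p".
    """

    def __init__(
        self,
        panel: io.GenotypePanel,
        scoring: list[io.ScoringVariant],
        gwas: list[io.GwasAssociation] | None = None,
        annotation: list[io.GeneAnnotation] | None = None,
        cs2g: list[io.Cs2gLink] | None = None,
        window_bp: int = 200_000,
        cs2g_min_score: float = 0.0,
        fallback_max_dist_bp: int = 1_000_000,
        center_constant: str = "2p",
    ) -> None:
        self.panel = panel
        self.scoring = scoring
        self.gwas = gwas or []
        self.annotation = annotation or []
        self.cs2g = cs2g or []
        self.window_bp = window_bp
        self.cs2g_min_score = cs2g_min_score
        self.fallback_max_dist_bp = fallback_max_dist_bp
        self.center_constant = center_constant

    @classmethod
    def from_files(
        cls,
        bfile_prefix: str | Path,
        scoring_path: str | Path,
        gwas_path: str | Path | None = None,
        annotation_path: str | Path | None = None,
        cs2g_path: str | Path | None = None,
        **kwargs,
    ) -> "PRSDecomposition":
        """Build the model straight from the on-disk input files."""
        panel = io.read_plink(bfile_prefix)
        scoring, _ = io.read_scoring_file(scoring_path)
        gwas = io.read_gwas_associations(gwas_path)[0] if gwas_path else []
        annotation = (
            io.read_gene_annotation(annotation_path) if annotation_path else []
        )
        cs2g = io.read_cs2g(cs2g_path) if cs2g_path else []
        return cls(panel, scoring, gwas, annotation, cs2g, **kwargs)

    def fit(
        self, reference: "PRSDecompositionResults | None" = None
    ) -> "PRSDecompositionResults":
        """Harmonize, map, regionize and attribute.

        ``reference`` switches to individual mode: frequencies, the raw-PRS
        mean/sd, per-region means/variances and the percentile cohort all
        come from the reference cohort's results.
        """
        harmonized = _run_harmonize(
            self.scoring,
            self.panel,
            reference=reference.harmonized if reference else None,
            center_constant=self.center_constant,
        )
        variants = harmonized.variants
        if reference is None:
            links = _mapping.map_all(
                variants,
                self.annotation,
                self.cs2g,
                self.gwas,
                window_bp=self.window_bp,
                cs2g_min_score=self.cs2g_min_score,
                fallback_max_dist_bp=self.fallback_max_dist_bp,
            )
            regions = _mapping.regionize(links, variants, self.annotation)
        else:
            links, regions = reference.links, reference.regions
        attribution = _scores.attribute(
            harmonized, regions, reference=reference.attribution if reference else None
        )
        return PRSDecompositionResults(self, harmonized, links, regions, attribution)


@dataclass
class PRSDecompositionResults:
    """Fitted decomposition: estimates, variances and report exports."""

    model: PRSDecomposition
    harmonized: HarmonizedPanel
    links: list[_mapping.SnpGeneLink]
    regions: list[_mapping.Region]
    attribution: _scores.AttributionResult

    # -- convenient views -------------------------------------------------
    @property
    def prs(self) -> pd.DataFrame:
        """sample_id, prs_raw, prs_std, percentile."""
        df = self.harmonized.prs_frame()
        df["percentile"] = self.attribution.percentile
        return df

    @property
    def heritability(self) -> pd.DataFrame:
        """Regions ranked by Var(CS_gene) — the heritability partition."""
        return self.attribution.population_table()

    @property
    def regions_table(self) -> pd.DataFrame:
        return _mapping.regions_frame(self.regions)

    @property
    def links_table(self) -> pd.DataFrame:
        return _mapping.links_frame(self.links)

    def individual(self, sample_id: str) -> pd.DataFrame:
        return self.attribution.individual_table(sample_id)

    def percentile(self, sample_id: str) -> float:
        j = self.attribution._sample_index(sample_id)
        return float(self.attribution.percentile[j])

    def summary(self, top: int = 10) -> str:
        """Human-readable overview of the fitted decomposition."""
        rep = self.harmonized.report
        pop = self.heritability.head(top)
        stage_counts = (
            self.links_table.drop_duplicates("variant_id")["stage"]
            .value_counts()
            .to_dict()
        )
        total_var = float(np.var(self.harmonized.prs_std, ddof=1))
        sum_region_var = float(self.attribution.cs_gene_var.sum())
        lines = [
            "PRS decomposition",
            "=" * 64,
            f"samples: {self.harmonized.n_samples}    "
            f"variants matched: {rep.n_matched} "
            f"(flipped {rep.n_sign_flipped}, unmatched {rep.n_unmatched}, "
            f"palindromic dropped {rep.n_ambiguous_dropped})",
            f"mapping stages: {stage_counts}",
            f"regions: {len(self.regions)}    "
            f"sum of region variances: {sum_region_var:.4f} "
            f"(Var(prs_std) = {total_var:.4f}; difference is 2*cross-region cov)",
            "",
            f"top {len(pop)} regions by Var(CS_gene) [heritability partition]:",
            pop.to_string(index=False),
        ]
        return "\n".join(lines)

    def save_report(
        self,
        out_dir: str | Path,
        individuals: list[str] | None = None,
        max_locus_regions: int = 3,
    ) -> dict:
        """Write the full multilevel report; returns the manifest."""
        return _report.render(
            self.attribution,
            self.regions_table,
            self.harmonized,
            out_dir,
            individuals=individuals,
            annotation=self.model.annotation,
            max_locus_regions=max_locus_regions,
        )

    def save_tables(self, out_dir: str | Path) -> None:
        """Write the analysis tables (no figures): PRS, harmonization,
        mapping, regions, population heritability."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.prs.to_csv(out / "prs.tsv", sep="\t", index=False)
        self.harmonized.report.to_frame().to_csv(
            out / "harmonization.tsv", sep="\t", index=False
        )
        self.links_table.to_csv(out / "mapping.tsv", sep="\t", index=False)
        self.regions_table.to_csv(out / "regions.tsv", sep="\t", index=False)
        self.heritability.to_csv(out / "population.tsv", sep="\t", index=False)
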