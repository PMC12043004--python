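"""Sequential SNP-to-gene mapping and regionizing.

Scoring SNPs are assigned to genes by a three-stage sequential protocol:

1. **positional** — a SNP links to every gene on the same chromosome whose
   body, widened by ``window_bp`` (default 200 kb) on each side, contains it
   (boundary inclusive).
2. **cS2G** — SNPs with no positional link take every functional
   SNP-to-gene link at or above ``min_score`` from a precomputed cS2G table.
3. **GWAS fallback** — SNPs still unlinked go to the gene of the
   smallest-p-value same-chromosome GWAS association within ``max_dist_bp``
   (ties broken by distance, then gene name); SNPs with no association in
   range get a synthetic 1-Mb locus label ``chr<c>:<floor(pos/1Mb)>Mb``, so
   every harmonized SNP ends up mapped.

Because a SNP may link to several genes, genes whose SNP sets overlap are
then consolidated: connected components of the shared-SNP gene graph become
**regions**, the disjoint attribution units over which contributions add up
to the PRS exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import Cs2gLink, GeneAnnotation, GwasAssociation

__all__ = [
    "Stage",
    "SnpGeneLink",
    "Region",
    "map_positional",
    "map_cs2g",
    "map_fallback",
    "map_all",
    "regionize",
    "links_frame",
    "regions_frame",
]


class Stage(str, Enum):
    POSITIONAL = "positional"
    CS2G = "cs2g"
    GWAS_FALLBACK = "gwas_fallback"


@dataclass(frozen=True)
class SnpGeneLink:
    """One SNP -> gene assignment and the stage that produced it.

    ``detail`` is stage-dependent: bp distance to the gene body (0 inside)
    for positional links, the cS2G score for functional links, and the
    per-SNP heritability ``2 p (1-p) beta_std^2`` for fallback links.
    """

    variant_id: str
    gene: str
    stage: Stage
    detail: float


@dataclass(frozen=True)
class Region:
    """A disjoint attribution unit: a set of genes plus their SNPs."""

    region_id: str
    genes: frozenset[str]
    variant_ids: frozenset[str]
    chrom: str
    span: tuple[int, int]


def map_positional(
    variants: pd.DataFrame,
    annotation: list[GeneAnnotation],
    window_bp: int = 200_000,
) -> list[SnpGeneLink]:
    """Window-based positional links (stage 1).

    ``variants`` needs columns variant_id, chrom, pos. A variant links to
    gene g iff same chromosome and ``g.start - window_bp <= pos <=
    g.end + window_bp`` (inclusive). ``detail`` is 0 inside the gene body,
    otherwise the distance to the nearest gene edge.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    links: list[SnpGeneLink] = []
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    for row in variants.itertuples(index=False):
        for g in by_chrom.get(str(row.chrom), ()):
            if g.start - window_bp <= row.pos <= g.end + window_bp:
                if g.start <= row.pos <= g.end:
                    dist = 0
                else:
                    dist = min(abs(row.pos - g.start), abs(row.pos - g.end))
                links.append(
                    SnpGeneLink(str(row.variant_id), g.gene, Stage.POSITIONAL, float(dist))
                )
    return links


def map_cs2g(
    variants: pd.DataFrame,
    cs2g: list[Cs2gLink],
    min_score: float = 0.0,
) -> list[SnpGeneLink]:
    """Functional cS2G links (stage 2) for variants the caller left unlinked."""
    wanted = set(variants["variant_id"].astype(str))
    return [
        SnpGeneLink(l.variant_id, l.gene, Stage.CS2G, l.score)
        for l in cs2g
        if l.variant_id in wanted and l.score >= min_score
    ]


def snp_heritability(p_hat: np.ndarray, beta_std: np.ndarray) -> np.ndarray:
    """Per-SNP heritability under HWE: ``2 p (1-p) beta_std^2``."""
    return 2.0 * p_hat * (1.0 - p_hat) * beta_std**2


def synthetic_locus_label(chrom: str, pos: int) -> str:
    return f"chr{chrom}:{pos // 1_000_000}Mb"


def map_fallback(
    variants: pd.DataFrame,
    gwas: list[GwasAssociation],
    max_dist_bp: int = 1_000_000,
) -> list[SnpGeneLink]:
    """GWAS p-value fallback (stage 3); guarantees every variant a link.

    ``variants`` needs columns variant_id, chrom, pos, p_hat, beta_std. Each
    variant goes to the gene of the same-chromosome association with the
    smallest p-value within ``max_dist_bp``; ties break by distance then
    lexical gene order. With nothing in range the variant is assigned to a
    synthetic 1-Mb locus. ``detail`` records the per-SNP heritability.
    """
    by_chrom: dict[str, list[GwasAssociation]] = {}
    for a in gwas:
        by_chrom.setdefault(a.chrom, []).append(a)
    links: list[SnpGeneLink] = []
    for row in variants.itertuples(index=False):
        h2 = float(2.0 * row.p_hat * (1.0 - row.p_hat) * row.beta_std**2)
        best: tuple[float, int, str] | None = None
        for a in by_chrom.get(str(row.chrom), ()):
            dist = abs(a.pos - row.pos)
            if dist > max_dist_bp:
                continue
            cand = (a.p_value, dist, a.mapped_gene)
            if best is None or cand < best:
                best = cand
        gene = best[2] if best else synthetic_locus_label(str(row.chrom), int(row.pos))
        links.append(SnpGeneLink(str(row.variant_id), gene, Stage.GWAS_FALLBACK, h2))
    return links


def map_all(
    variants: pd.DataFrame,
    annotation: list[GeneAnnotation],
    cs2g: list[Cs2gLink],
    gwas: list[GwasAssociation],
    window_bp: int = 200_000,
    cs2g_min_score: float = 0.0,
    fallback_max_dist_bp: int = 1_000_000,
) -> list[SnpGeneLink]:
    """Run the three stages sequentially; later stages see only leftovers."""
    links = map_positional(variants, annotation, window_bp)
    linked = {l.variant_id for l in links}
    rest = variants[~variants["variant_id"].astype(str).isin(linked)]
    links += map_cs2g(rest, cs2g, cs2g_min_score)
    linked = {l.variant_id for l in links}
    rest = variants[~variants["variant_id"].astype(str).isin(linked)]
    links += map_fallback(rest, gwas, fallback_max_dist_bp)
    return links


def _region_id(genes: list[str], gene_start: dict[str, int]) -> str:
    ordered = sorted(genes, key=lambda g: (gene_start.get(g, 0), g))
    if len(ordered) <= 3:
        return "+".join(ordered)
    return "+".join(ordered[:3]) + f"+{len(ordered) - 3} more"


def regionize(
    links: list[SnpGeneLink],
    variants: pd.DataFrame,
    annotation: list[GeneAnnotation] | None = None,
) -> list[Region]:
    """Consolidate genes sharing SNPs into disjoint regions.

    Builds the gene-gene graph with an edge whenever two genes share a linked
    SNP; each connected component becomes one region holding the union of its
    genes' SNPs. Region ids are the component's gene symbols ordered by
    genomic start (annotation start where known, else the gene's first SNP
    position), joined with ``+`` and truncated past three names. The regions
    partition the linked variant set, and the output order is deterministic
    (by chromosome then span).
    """
    pos_of = {
        str(r.variant_id): (str(r.chrom), int(r.pos))
        for r in variants.itertuples(index=False)
    }
    gene_snps: dict[str, set[str]] = {}
    for l in links:
        gene_snps.setdefault(l.gene, set()).add(l.variant_id)

    graph = nx.Graph()
    graph.add_nodes_from(gene_snps)
    snp_genes: dict[str, list[str]] = {}
    for gene, snps in gene_snps.items():
        for s in snps:
            snp_genes.setdefault(s, []).append(gene)
    for genes in snp_genes.values():
        for a, b in zip(genes, genes[1:]):
            graph.add_edge(a, b)

    gene_start: dict[str, int] = {}
    if annotation:
        gene_start.update({g.gene: g.start for g in annotation})
    for gene, snps in gene_snps.items():
        if gene not in gene_start:
            gene_start[gene] = min(pos_of[s][1] for s in snps)

    regions: list[Region] = []
    for comp in nx.connected_components(graph):
        genes = sorted(comp)
        snps: set[str] = set().union(*(gene_snps[g] for g in genes))
        chroms = {pos_of[s][0] for s in snps}
        chrom = min(chroms) if len(chroms) == 1 else "+".join(sorted(chroms))
        positions = [pos_of[s][1] for s in snps]
        regions.append(
            Region(
                region_id=_region_id(genes, gene_start),
                genes=frozenset(genes),
                variant_ids=frozenset(snps),
                chrom=chrom,
                span=(min(positions), max(positions)),
            )
        )
    regions.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.span, r.region_id))
    return regions


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (10**6, chrom)


def links_frame(links: list[SnpGeneLink]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [l.variant_id for l in links],
            "gene": [l.gene for l in links],
            "stage": [l.stage.value for l in links],
            "detail": [l.detail for l in links],
        }
    )


def regions_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "genes": [",".join(sorted(r.genes)) for r in regions],
            "n_snps": [len(r.variant_ids) for r in regions],
            "chrom": [r.chrom for r in regions],
            "span_start": [r.span[0] for r in regions],
            "span_end": [r.span[1] for r in regions],
        }
    )
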