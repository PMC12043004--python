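"""Multilevel report tables and rendered figures.

Population level: a gene/region Manhattan plot whose y-axis is the variance
of the region contribution score (the per-region heritability), ranked with
the top 10 regions highlighted in red. Individual level: a Manhattan plot of
attributed values (top 10 red, bottom 10 blue), a density plot locating the
individual's standardized PRS within the population, and LocusZoom-like
per-region SNP tracks.

Every figure is a pure function of its emitted TSV table: delete the images,
re-render from the TSVs, and you get the same bytes back. No timestamps or
other run-dependent state enter the outputs.
"""

from __future__ import annotations

import base64
import io
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .scores import AttributionResult, compute_percentile

__all__ = [
    "population_manhattan",
    "individual_manhattan",
    "individual_density",
    "locus_track",
    "render",
]

_PNG_META = {"Software": "prsx"}  # fixed metadata keeps PNG bytes reproducible

HIGHLIGHT_TOP = "top_red"
HIGHLIGHT_BOTTOM = "bottom_blue"
HIGHLIGHT_NONE = "none"


def _chrom_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (10**6, chrom)


def _cumulative_positions(df: pd.DataFrame) -> pd.DataFrame:
    """Add a cumulative-chromosome x coordinate at each region's midpoint."""
    df = df.copy()
    df["midpoint_pos"] = (df["span_start"] + df["span_end"]) // 2
    chroms = sorted(df["chrom"].unique(), key=_chrom_key)
    offset, offsets = 0, {}
    for c in chroms:
        offsets[c] = offset
        offset += int(df.loc[df["chrom"] == c, "span_end"].max()) + 1_000_000
    df["x_cum"] = df.apply(lambda r: offsets[r["chrom"]] + r["midpoint_pos"], axis=1)
    return df


def population_manhattan(population_table: pd.DataFrame,
                         regions_table: pd.DataFrame) -> pd.DataFrame:
    """Population Manhattan rows: y = cs_gene_var, top-10 regions flagged red.

    Regions are ranked by variance descending (ties by region_id); no fixed
    significance threshold is applied — the ranking itself is the output.
    """
    df = population_table.merge(
        regions_table[["region_id", "chrom", "span_start", "span_end"]],
        on="region_id",
    )
    df = df.sort_values(
        ["cs_gene_var", "region_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["y_value"] = df["cs_gene_var"]
    df["highlight"] = np.where(df["rank"] <= 10, HIGHLIGHT_TOP, HIGHLIGHT_NONE)
    df = _cumulative_positions(df)
    return df[
        ["region_id", "chrom", "midpoint_pos", "x_cum", "y_value", "highlight", "rank"]
    ]


def individual_manhattan(individual_table: pd.DataFrame,
                         regions_table: pd.DataFrame) -> pd.DataFrame:
    """Individual Manhattan rows: y = a_gene, top-10 red / bottom-10 blue.

    A region is never flagged both ways; when fewer than 20 regions exist
    red wins the overlap, so exactly min(10, n) regions are red and only the
    remaining bottom ranks are blue.
    """
    df = individual_table.merge(
        regions_table[["region_id", "chrom", "span_start", "span_end"]],
        on="region_id",
    )
    df = df.sort_values(
        ["a_gene", "region_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    n = len(df)
    top = set(df.loc[df["rank"] <= 10, "region_id"])
    # red wins on overlap: always exactly min(10, n) red rows, blue only on
    # what remains at the bottom
    bottom = set(df.loc[df["rank"] > n - 10, "region_id"]) - top
    df["y_value"] = df["a_gene"]
    df["highlight"] = [
        HIGHLIGHT_TOP if r in top else HIGHLIGHT_BOTTOM if r in bottom else HIGHLIGHT_NONE
        for r in df["region_id"]
    ]
    df = _cumulative_positions(df)
    return df[
        ["region_id", "chrom", "midpoint_pos", "x_cum", "y_value", "highlight", "rank"]
    ]


def individual_density(
    prs_std: np.ndarray, target: float, n_grid: int = 256
) -> pd.DataFrame:
    """Gaussian KDE of the cohort PRS over a 256-point grid, plus the target.

    Bandwidth follows Silverman's rule. The returned table carries the grid,
    the density, and (as repeated columns for TSV flatness) the target's
    standardized PRS and its mid-rank percentile.
    """
    prs_std = np.asarray(prs_std, dtype=float)
    kde = gaussian_kde(prs_std, bw_method="silverman")
    lo = min(prs_std.min(), target)
    hi = max(prs_std.max(), target)
    pad = 0.15 * (hi - lo if hi > lo else 1.0)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    pct = compute_percentile(prs_std, target)
    return pd.DataFrame(
        {
            "grid": grid,
            "density": kde(grid),
            "target_prs_std": target,
            "target_percentile": pct,
        }
    )


def locus_track(
    region_id: str,
    snp_table: pd.DataFrame,
    harmonized_variants: pd.DataFrame,
    dosage: pd.Series | None = None,
    gene_bodies: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-SNP rows for one region, sorted by position, with gene-body flags.

    ``dosage`` maps variant_id to the individual's effect-allele count. Both
    ``cs_snp`` and ``abs_cs_snp`` are emitted so either can drive the y-axis.
    """
    df = snp_table.loc[snp_table["region_id"] == region_id].merge(
        harmonized_variants[["variant_id", "pos", "beta_std"]], on="variant_id"
    )
    df["dosage"] = (
        df["variant_id"].map(dosage) if dosage is not None else np.nan
    )
    df["in_gene_body"] = [
        any(s <= p <= e for s, e in (gene_bodies or [])) for p in df["pos"]
    ]
    df["abs_cs_snp"] = df["cs_snp"].abs()
    df = df.sort_values(["pos", "variant_id"], kind="mergesort").reset_index(drop=True)
    return df[
        ["variant_id", "pos", "beta_std", "dosage", "cs_snp", "abs_cs_snp",
         "in_gene_body", "region_id"]
    ]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_COLORS = {HIGHLIGHT_TOP: "#d62728", HIGHLIGHT_BOTTOM: "#1f77b4",
           HIGHLIGHT_NONE: "#7f7f7f"}


def _plot_manhattan(df: pd.DataFrame, ylabel: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 3.2))
    for hl, sub in df.groupby("highlight"):
        ax.scatter(sub["x_cum"], sub["y_value"], s=18, c=_COLORS[hl], label=hl,
                   zorder=3 if hl != HIGHLIGHT_NONE else 2)
    for _, row in df[df["highlight"] != HIGHLIGHT_NONE].iterrows():
        ax.annotate(row["region_id"], (row["x_cum"], row["y_value"]),
                    fontsize=5, rotation=45, ha="left")
    ax.set_xlabel("cumulative genomic position")
    ax.set_ylabel(ylabel)
    ax.margins(x=0.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata=_PNG_META)
    plt.close(fig)


def _plot_density(df: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.fill_between(df["grid"], df["density"], alpha=0.4, color="#7f7f7f")
    ax.plot(df["grid"], df["density"], color="#444444")
    t = float(df["target_prs_std"].iloc[0])
    pct = float(df["target_percentile"].iloc[0])
    ax.axvline(t, color="#d62728")
    ax.set_title(f"PRS = {t:.3f} ({pct:.1f}th percentile)", fontsize=9)
    ax.set_xlabel("standardized PRS")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata=_PNG_META)
    plt.close(fig)


def _plot_locus(df: pd.DataFrame, region_id: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.2))
    colors = np.where(df["cs_snp"] >= 0, "#d62728", "#1f77b4")
    ax.vlines(df["pos"], 0, df["cs_snp"], color=colors, lw=1)
    ax.scatter(df["pos"], df["cs_snp"], s=14, c=colors, zorder=3)
    ax.axhline(0, color="black", lw=0.6)
    ax.set_xlabel(f"position ({region_id})")
    ax.set_ylabel("SNP contribution")
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata=_PNG_META)
    plt.close(fig)


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in name)[:80]


def _html_table(df: pd.DataFrame, max_rows: int = 25) -> str:
    return df.head(max_rows).to_html(index=False, border=0, float_format="%.4g")


def _embed_png(path: Path) -> str:
    data = base64.b64encode(path.read_bytes()).decode()
    return f'<img src="data:image/png;base64,{data}" style="max-width:100%"/>'


def render(
    result: AttributionResult,
    regions_table: pd.DataFrame,
    harmonized,
    out_dir: str | Path,
    individuals: list[str] | None = None,
    annotation: list | None = None,
    max_locus_regions: int = 3,
) -> dict:
    """Write all report tables, images and HTML; return the manifest.

    Layout: ``population_manhattan.tsv/.png``, ``region_table.tsv``, and per
    individual ``<ID>/manhattan.tsv/.png``, ``<ID>/density.tsv/.png``,
    ``<ID>/locus_<region>.tsv/.png`` (that individual's top regions by
    |a_gene|, up to ``max_locus_regions``) plus ``<ID>/report.html``;
    ``manifest.json`` lists every file with its row count (``null`` for
    images/HTML). Rendering is a pure function of the emitted tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}}
    gene_bodies = {
        g.gene: (g.start, g.end) for g in (annotation or [])
    }
    region_genes = {
        r["region_id"]: r["genes"].split(",") for _, r in regions_table.iterrows()
    } if "genes" in regions_table.columns else {}

    def emit(df: pd.DataFrame, rel: str) -> Path:
        p = out / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(p, sep="\t", index=False)
        manifest["files"][rel] = len(df)
        return p

    pop = result.population_table()
    emit(pop, "region_table.tsv")
    pop_man = population_manhattan(pop, regions_table)
    emit(pop_man, "population_manhattan.tsv")
    _plot_manhattan(pop_man, "Var(CS_gene)  [heritability]",
                    out / "population_manhattan.png")
    manifest["files"]["population_manhattan.png"] = None

    for sid in individuals or []:
        j = result._sample_index(sid)  # raises with available ids if unknown
        d = _slug(sid)
        ind = result.individual_table(sid)
        man = individual_manhattan(ind, regions_table)
        emit(man, f"{d}/manhattan.tsv")
        _plot_manhattan(man, "A_gene (attributed value)", out / d / "manhattan.png")
        manifest["files"][f"{d}/manhattan.png"] = None

        dens = individual_density(result.prs_std, float(result.prs_std[j]))
        emit(dens, f"{d}/density.tsv")
        _plot_density(dens, out / d / "density.png")
        manifest["files"][f"{d}/density.png"] = None

        snp = result.snp_table(sid)
        top_regions = (
            ind.assign(mag=ind["a_gene"].abs())
            .sort_values(["mag", "region_id"], ascending=[False, True],
                         kind="mergesort")["region_id"]
            .head(max_locus_regions)
            .tolist()
        )
        dos = pd.Series(
            harmonized.dosage_effect[j], index=harmonized.variants["variant_id"]
        )
        locus_html = []
        for rid in top_regions:
            bodies = [gene_bodies[g] for g in region_genes.get(rid, [])
                      if g in gene_bodies]
            track = locus_track(rid, snp, harmonized.variants, dos, bodies)
            rel = f"{d}/locus_{_slug(rid)}.tsv"
            emit(track, rel)
            png = out / d / f"locus_{_slug(rid)}.png"
            _plot_locus(track, rid, png)
            manifest["files"][f"{d}/locus_{_slug(rid)}.png"] = None
            locus_html.append(f"<h3>{rid}</h3>" + _embed_png(png))

        (out / d / "report.html").write_text(
            "<html><head><meta charset='utf-8'><title>PRS report "
            f"{sid}</title></head><body><h1>PRS decomposition: {sid}</h1>"
            f"<p>Standardized PRS {result.prs_std[j]:.4f}, percentile "
            f"{result.percentile[j]:.1f}.</p>"
            + _embed_png(out / d / "manhattan.png")
            + _embed_png(out / d / "density.png")
            + "<h2>Per-region attributed values</h2>"
            + _html_table(ind)
            + "<h2>Locus views</h2>"
            + "".join(locus_html)
            + "<p style='font-size:small'>Top/bottom-10 overlap (under 20 "
            "regions) is resolved in favor of the red top set.</p></body></html>"
        )
        manifest["files"][f"{d}/report.html"] = None

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
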