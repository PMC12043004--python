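"""Readers and writers for every external file format the pipeline touches.

All parsing dialect decisions live here:

* PLINK 1 binary genotypes (``.bed``/``.bim``/``.fam``, SNP-major v1.00).
* PGS-Catalog-style scoring TSV (``rsID`` or ``chr_name``/``chr_position`` keyed).
* GWAS-Catalog-style association TSV (``CHR_ID``, ``CHR_POS``, ``MAPPED_GENE``,
  ``P-VALUE``; multi-gene cells are split).
* BED4 gene annotation (0-based half-open on disk, converted to the internal
  1-based inclusive convention on read).
* cS2G SNP-to-gene link TSV (variant key, gene, score).

The internal coordinate convention is 1-based inclusive throughout (matching
BIM and the GWAS Catalog); only BED input/output is shifted. Every TSV reader
tolerates gzip via pandas' transparent decompression. Writers are exact
inverses of readers on valid data, and parsers never silently drop rows: each
reader that can drop rows returns a skip report whose counts plus the parsed
count equal the number of data rows seen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "ScoringVariant",
    "GenotypePanel",
    "GwasAssociation",
    "GeneAnnotation",
    "Cs2gLink",
    "SkipReport",
    "FormatError",
    "read_scoring_file",
    "write_scoring_file",
    "read_plink",
    "write_plink",
    "read_gwas_associations",
    "write_gwas_associations",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_cs2g",
    "write_cs2g",
]

#: Sentinel for a missing hard-call genotype in dosage matrices.
MISSING: int = -1

_VALID_ALLELE = re.compile(r"^[ACGT]$")


class FormatError(ValueError):
    """An input file violates the format contract (bad magic, missing column...)."""


@dataclass(frozen=True)
class ScoringVariant:
    """One weighted variant from a PRS scoring model.

    ``beta`` is the per-effect-allele weight on the raw PRS scale.
    """

    variant_id: str
    chrom: str
    pos: int  # 1-based bp
    effect_allele: str
    other_allele: str
    beta: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect allele equals other allele")
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.variant_id}: beta is not finite")


@dataclass
class GenotypePanel:
    """Hard-call genotype matrix read from PLINK binary files.

    ``dosage`` is samples x variants and counts the *counted allele* of each
    variant — the BIM A1 allele — with :data:`MISSING` for no-calls. Missing
    handling is deliberately not done here; the harmonizer owns imputation.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    bim: pd.DataFrame  # columns: chrom, variant_id, cm, pos, a1, a2
    dosage: np.ndarray  # int8, samples x variants, values in {0,1,2,MISSING}

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, missing}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


@dataclass(frozen=True)
class GwasAssociation:
    """One gene mapped to a significant GWAS variant."""

    chrom: str
    pos: int
    mapped_gene: str
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene body coordinates, 1-based inclusive."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class Cs2gLink:
    """A functional SNP-to-gene link with its combined evidence score."""

    variant_id: str
    gene: str
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"{self.variant_id}->{self.gene}: negative cS2G score")


@dataclass
class SkipReport:
    """Rows a reader dropped, by reason. parsed + skipped == data rows seen."""

    n_rows: int = 0
    skipped: dict[str, int] = field(default_factory=dict)

    def count(self, reason: str, k: int = 1) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + k

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())


# ---------------------------------------------------------------------------
# PGS-Catalog-style scoring files
# ---------------------------------------------------------------------------

_SCORING_COLS = {
    "variant_id": ("rsID", "rsid", "variant_id"),
    "chrom": ("chr_name", "chrom", "chr"),
    "pos": ("chr_position", "pos", "position"),
    "effect_allele": ("effect_allele",),
    "other_allele": ("other_allele", "reference_allele", "hm_inferOtherAllele"),
    "beta": ("effect_weight", "beta"),
}


def _resolve_columns(columns: list[str], spec: dict[str, tuple[str, ...]],
                     required: tuple[str, ...]) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    out: dict[str, str] = {}
    for canon, aliases in spec.items():
        for alias in aliases:
            if alias.lower() in lower:
                out[canon] = lower[alias.lower()]
                break
    missing = [c for c in required if c not in out]
    if missing:
        raise FormatError(
            "missing mandatory column(s): "
            + ", ".join(f"{c} (accepted: {'/'.join(spec[c])})" for c in missing)
        )
    return out


def read_scoring_file(path: str | Path) -> tuple[list[ScoringVariant], SkipReport]:
    """Read a PGS-Catalog-style scoring TSV.

    Comment lines starting with ``#`` are allowed (PGS Catalog header block).
    Both ``rsID``-keyed and ``chr_name``/``chr_position``-keyed files are
    accepted; files lacking rsIDs get synthesized ``chrom:pos`` ids so the
    harmonizer can choose the join key. Rows with a missing/non-numeric beta
    or malformed alleles are dropped and counted in the returned skip report.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = _resolve_columns(list(df.columns), _SCORING_COLS,
                            required=("effect_allele", "beta"))
    if "variant_id" not in cols and not ("chrom" in cols and "pos" in cols):
        raise FormatError("missing mandatory column(s): rsID or chr_name+chr_position")

    report = SkipReport(n_rows=len(df))
    variants: list[ScoringVariant] = []
    for rec in df.to_dict("records"):
        get = lambda canon: rec.get(cols[canon]) if canon in cols else None
        beta_s = get("beta")
        try:
            beta = float(beta_s)
            if not np.isfinite(beta):
                raise ValueError
        except (TypeError, ValueError):
            report.count("missing_or_bad_beta")
            continue
        ea, oa = get("effect_allele"), get("other_allele")
        ea = (ea or "").strip().upper()
        oa = (oa or "").strip().upper()
        if not _VALID_ALLELE.match(ea) or not _VALID_ALLELE.match(oa) or ea == oa:
            report.count("malformed_alleles")
            continue
        chrom = str(get("chrom") or "0").removeprefix("chr")
        try:
            pos = int(float(get("pos") or 0))
        except ValueError:
            report.count("bad_position")
            continue
        vid = get("variant_id") or f"{chrom}:{pos}"
        if pos < 1:
            report.count("bad_position")
            continue
        variants.append(ScoringVariant(str(vid), chrom, pos, ea, oa, beta))
    return variants, report


def write_scoring_file(variants: list[ScoringVariant], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "rsID": [v.variant_id for v in variants],
            "chr_name": [v.chrom for v in variants],
            "chr_position": [v.pos for v in variants],
            "effect_allele": [v.effect_allele for v in variants],
            "other_allele": [v.other_allele for v in variants],
            "effect_weight": [repr(v.beta) for v in variants],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK 1 binary (.bed/.bim/.fam), SNP-major v1.00
# ---------------------------------------------------------------------------
# .bed layout: 3 magic bytes 0x6c 0x1b 0x01, then per variant ceil(n/4) bytes,
# two bits per sample, least-significant pair first:
#   00 -> homozygous A1 (2 copies of the counted allele)
#   01 -> missing
#   10 -> heterozygous (1 copy)
#   11 -> homozygous A2 (0 copies)

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
# 2-bit code -> counted-allele dosage
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK 1 binary fileset. Dosages count the BIM A1 allele."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None, dtype=str,
        names=["chrom", "variant_id", "cm", "pos", "a1", "a2"],
    )
    bim["pos"] = bim["pos"].astype(np.int64)
    n, m = len(fam), len(bim)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"{prefix}.bed: bad magic bytes {raw[:3]!r} (expected SNP-major v1.00)"
        )
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_variant * m:
        raise FormatError(
            f"{prefix}.bed: body is {body.size} bytes but .bim/.fam imply "
            f"{bytes_per_variant * m} ({m} variants x {bytes_per_variant} bytes)"
        )
    if n == 0 or m == 0:
        dosage = np.zeros((n, m), dtype=np.int8)
    else:
        blocks = body.reshape(m, bytes_per_variant)
        # expand each byte into its 4 two-bit codes, sample-index order
        shifts = np.arange(4, dtype=np.uint8) * 2
        codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
        codes = codes.reshape(m, bytes_per_variant * 4)[:, :n]
        dosage = _CODE_TO_DOSAGE[codes].T.copy()  # samples x variants
    return GenotypePanel(
        sample_ids=list(fam["iid"]),
        variant_ids=list(bim["variant_id"]),
        bim=bim,
        dosage=dosage,
    )


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as a PLINK 1 SNP-major fileset (exact inverse of read_plink)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = panel.dosage.shape
    fam = pd.DataFrame(
        {
            "fid": panel.sample_ids, "iid": panel.sample_ids,
            "father": "0", "mother": "0", "sex": "0", "pheno": "-9",
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    panel.bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    bytes_per_variant = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        if n and m:
            codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
            codes[:] = 0b00  # pad slots are zeroed (PLINK convention); ignored on read
            dos = panel.dosage.T  # variants x samples
            var_codes = np.where(
                dos == MISSING, 0b01,
                np.where(dos == 2, 0b00, np.where(dos == 1, 0b10, 0b11)),
            ).astype(np.uint8)
            codes[:, :n] = var_codes
            shifts = np.arange(4, dtype=np.uint8) * 2
            packed = (codes.reshape(m, bytes_per_variant, 4) << shifts).sum(
                axis=2, dtype=np.uint16
            ).astype(np.uint8)
            fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# GWAS-Catalog-style association files
# ---------------------------------------------------------------------------

_GWAS_COLS = {
    "chrom": ("CHR_ID", "chrom", "chr"),
    "pos": ("CHR_POS", "pos", "position"),
    "mapped_gene": ("MAPPED_GENE", "mapped_gene", "gene"),
    "p_value": ("P-VALUE", "p_value", "pvalue", "p"),
}
_GENE_SPLIT = re.compile(r"\s*(?:,|;| - )\s*")


def read_gwas_associations(
    path: str | Path,
) -> tuple[list[GwasAssociation], SkipReport]:
    """Read a GWAS-Catalog-style TSV; multi-gene cells become one record per gene.

    Gene cells may list several genes separated by commas, semicolons, or the
    Catalog's `` - `` intergenic notation; each named gene yields its own
    record. Rows with an unparseable p-value or position are dropped and
    counted in the skip report.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = _resolve_columns(
        list(df.columns), _GWAS_COLS,
        required=("chrom", "pos", "mapped_gene", "p_value"),
    )
    report = SkipReport(n_rows=len(df))
    out: list[GwasAssociation] = []
    for rec in df.to_dict("records"):
        try:
            p = float(rec[cols["p_value"]])
            if not (0.0 < p <= 1.0):
                raise ValueError
        except (TypeError, ValueError):
            report.count("bad_p_value")
            continue
        try:
            pos = int(float(rec[cols["pos"]]))
        except (TypeError, ValueError):
            report.count("bad_position")
            continue
        chrom = str(rec[cols["chrom"]]).removeprefix("chr")
        genes = [g for g in _GENE_SPLIT.split(str(rec[cols["mapped_gene"]] or "")) if g]
        if not genes:
            report.count("no_gene")
            continue
        for g in genes:
            out.append(GwasAssociation(chrom, pos, g, p))
    return out, report


def write_gwas_associations(assocs: list[GwasAssociation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "CHR_ID": [a.chrom for a in assocs],
            "CHR_POS": [a.pos for a in assocs],
            "MAPPED_GENE": [a.mapped_gene for a in assocs],
            "P-VALUE": [repr(a.p_value) for a in assocs],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED4 gene annotation and cS2G links
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED4 gene table (chrom, start, end, gene; 0-based half-open).

    Coordinates are converted to the internal 1-based inclusive convention:
    start + 1, end unchanged. Duplicate gene symbols are an error.
    """
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#", dtype=str,
        names=["chrom", "start", "end", "gene"],
    )
    genes = [
        GeneAnnotation(
            gene=str(r.gene),
            chrom=str(r.chrom).removeprefix("chr"),
            start=int(r.start) + 1,
            end=int(r.end),
        )
        for r in df.itertuples(index=False)
    ]
    seen: dict[str, int] = {}
    for g in genes:
        seen[g.gene] = seen.get(g.gene, 0) + 1
    dups = sorted(g for g, k in seen.items() if k > 1)
    if dups:
        raise FormatError(f"duplicate gene symbols in annotation: {', '.join(dups)}")
    return genes


def write_gene_annotation(genes: list[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": [f"chr{g.chrom}" for g in genes],
            "start": [g.start - 1 for g in genes],
            "end": [g.end for g in genes],
            "gene": [g.gene for g in genes],
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def read_cs2g(path: str | Path) -> list[Cs2gLink]:
    """Read a cS2G link TSV (variant key, gene, combined score >= 0)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = _resolve_columns(
        list(df.columns),
        {"variant_id": ("SNP", "variant_id", "variant_key", "rsID"),
         "gene": ("GENE", "gene"),
         "score": ("cS2G", "score", "value")},
        required=("variant_id", "gene", "score"),
    )
    return [
        Cs2gLink(str(r[cols["variant_id"]]), str(r[cols["gene"]]),
                 float(r[cols["score"]]))
        for r in df.to_dict("records")
    ]


def write_cs2g(links: list[Cs2gLink], path: str | Path) -> None:
    pd.DataFrame(
        {
            "SNP": [l.variant_id for l in links],
            "GENE": [l.gene for l in links],
            "cS2G": [repr(l.score) for l in links],
        }
    ).to_csv(path, sep="\t", index=False)
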