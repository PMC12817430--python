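"""VCF genotype I/O, the site/individual QC cascade, LD thinning, and
replicate-based genotyping error rates.

Dosage coding: 0/1/2 alt-allele copies, -1 (``MISSING``) for uncalled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

MISSING: int = -1


class EmptyCohortError(ValueError):
    """All individuals were removed by a filter."""


class UndefinedRateError(ValueError):
    """No co-called sites available to estimate an error rate."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci dosage matrix with site annotations."""

    dosages: np.ndarray  # int8, individuals x loci, MISSING for no-call
    individual_ids: list[str]
    scaffolds: np.ndarray  # object, per locus
    positions: np.ndarray  # int64, 1-based, per locus
    ref: np.ndarray
    alt: np.ndarray
    site_annotations: dict[str, np.ndarray] = field(default_factory=dict)
    genotype_depth: np.ndarray | None = None  # individuals x loci or None

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep].copy(),
            individual_ids=list(self.individual_ids),
            scaffolds=self.scaffolds[keep].copy(),
            positions=self.positions[keep].copy(),
            ref=self.ref[keep].copy(),
            alt=self.alt[keep].copy(),
            site_annotations={
                k: v[keep].copy() for k, v in self.site_annotations.items()
            },
            genotype_depth=(
                None if self.genotype_depth is None else self.genotype_depth[:, keep].copy()
            ),
        )

    def subset_individuals(self, keep) -> "GenotypeMatrix":
        keep = list(keep)
        idx = np.asarray(keep)
        return GenotypeMatrix(
            dosages=self.dosages[idx].copy(),
            individual_ids=[self.individual_ids[i] for i in keep],
            scaffolds=self.scaffolds.copy(),
            positions=self.positions.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            site_annotations={k: v.copy() for k, v in self.site_annotations.items()},
            genotype_depth=(
                None if self.genotype_depth is None else self.genotype_depth[idx].copy()
            ),
        )

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with NaN at missing entries."""
        out = self.dosages.astype(float)
        out[self.dosages == MISSING] = np.nan
        return out


@dataclass
class FilterConfig:
    """QC thresholds.  Defaults follow the study's published cascade:
    minor allele count >= 1, genotype depth >= 2, mean site depth in [5, 30],
    het allele balance in (0.2, 0.8), hom allele balance outside (0.01, 0.9),
    ref/alt mapping-quality ratio in (0.25, 1.75), quality/depth > 0.2,
    site missingness <= 10%, individual missingness <= 55%.
    """

    min_minor_allele_count: int = 1
    min_genotype_depth: int = 2
    min_mean_site_depth: float = 5.0
    max_mean_site_depth: float = 30.0
    het_allele_balance: tuple[float, float] = (0.2, 0.8)
    hom_allele_balance: tuple[float, float] = (0.01, 0.9)
    mapq_ratio: tuple[float, float] = (0.25, 1.75)
    min_quality_per_depth: float = 0.2
    max_site_missingness: float = 0.10
    max_individual_missingness: float = 0.55
    hom_keep_inside: bool = False  # ambiguous wording; default keep-if-outside

    def __post_init__(self) -> None:
        for name in ("max_site_missingness", "max_individual_missingness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        for name in ("het_allele_balance", "hom_allele_balance", "mapq_ratio"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: low must be < high")


@dataclass
class ErrorRates:
    """Replicate-pair genotyping error rates, in percent."""

    global_rate: float
    homozygous: float
    heterozygous: float
    n_pairs: int
    n_sites_compared: int


# ---------------------------------------------------------------------------
# VCF I/O


def _fmt(v: float) -> str:
    return f"{v:.6g}"


def write_vcf(G: GenotypeMatrix, path: str | Path) -> Path:
    """Write a VCF v4.2 with GT:DP genotypes and AB/QD/MQR/MEAN_DP INFO."""
    path = Path(path)
    ann_keys = sorted(G.site_annotations)
    lines = ["##fileformat=VCFv4.2", "##source=seedtrace"]
    for contig in dict.fromkeys(G.scaffolds):
        lines.append(f"##contig=<ID={contig}>")
    for key in ann_keys:
        lines.append(
            f'##INFO=<ID={key},Number=1,Type=Float,Description="Site annotation {key}">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(G.individual_ids)
    lines.append("\t".join(header))

    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for j in range(G.n_loci):
            info = ";".join(
                f"{k}={_fmt(float(G.site_annotations[k][j]))}" for k in ann_keys
            )
            row = [
                str(G.scaffolds[j]),
                str(int(G.positions[j])),
                ".",
                str(G.ref[j]),
                str(G.alt[j]),
                ".",
                "PASS",
                info or ".",
                "GT:DP",
            ]
            for i in range(G.n_individuals):
                g = gt_map[int(G.dosages[i, j])]
                dp = (
                    "."
                    if G.genotype_depth is None
                    else str(int(G.genotype_depth[i, j]))
                )
                row.append(f"{g}:{dp}")
            fh.write("\t".join(row) + "\n")
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix.

    Multi-allelic and non-SNP records are excluded (count logged).  Missing
    genotypes map to ``MISSING``.  Float INFO fields become site annotations;
    per-genotype DP is kept when present.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    ids = list(vcf.samples)

    dosage_rows: list[np.ndarray] = []
    scaffolds: list[str] = []
    positions: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    ann: dict[str, list[float]] = {}
    depths: list[np.ndarray] = []
    have_depth = True
    n_excluded = 0

    ann_keys = []
    for h in vcf.header_iter():
        try:
            info = h.info()
        except Exception:
            continue
        if info.get("HeaderType") == "INFO" and info.get("Type") in ("Float", "Integer"):
            ann_keys.append(info["ID"])

    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_excluded += 1
            continue
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types
        row = np.full(len(ids), MISSING, dtype=np.int8)
        row[gt == 0] = 0
        row[gt == 1] = 1
        row[gt == 3] = 2
        dosage_rows.append(row)
        scaffolds.append(var.CHROM)
        positions.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        for key in ann_keys:
            val = var.INFO.get(key)
            ann.setdefault(key, []).append(np.nan if val is None else float(val))
        if have_depth:
            try:
                fmt = var.format("DP")
                if fmt is None:
                    have_depth = False
                else:
                    d = np.asarray(fmt, dtype=np.int32).reshape(-1)
                    d[d < 0] = 0
                    depths.append(d)
            except Exception:
                have_depth = False
    if n_excluded:
        log.info("read_vcf: excluded %d multi-allelic/non-SNP records", n_excluded)

    n_loci = len(dosage_rows)
    dosages = (
        np.vstack(dosage_rows).T.astype(np.int8)
        if n_loci
        else np.empty((len(ids), 0), dtype=np.int8)
    )
    G = GenotypeMatrix(
        dosages=dosages,
        individual_ids=ids,
        scaffolds=np.asarray(scaffolds, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        site_annotations={k: np.asarray(v, dtype=float) for k, v in ann.items()},
        genotype_depth=(
            np.vstack(depths).T.astype(np.int32) if have_depth and depths else None
        ),
    )
    G.n_excluded_records = n_excluded  # type: ignore[attr-defined]
    return G


# ---------------------------------------------------------------------------
# QC cascade


def _site_missingness(dosages: np.ndarray) -> np.ndarray:
    return (dosages == MISSING).mean(axis=0)


def _minor_allele_count(dosages: np.ndarray) -> np.ndarray:
    called = dosages != MISSING
    alt_copies = np.where(called, dosages, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    return np.minimum(alt_copies, total - alt_copies)


def apply_site_filters(
    G: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, list[tuple[str, int]]]:
    """Apply the site QC cascade in its published order.

    Genotypes below ``min_genotype_depth`` are set missing first, then site
    rules are applied sequentially; the report lists sites removed per rule.
    Annotation-based rules are skipped (with a warning) when the annotation
    is absent.
    """
    cfg = cfg or FilterConfig()
    G = G.subset_sites(np.arange(G.n_loci))  # copy
    report: list[tuple[str, int]] = []

    if G.genotype_depth is not None and cfg.min_genotype_depth > 0:
        low = (G.genotype_depth < cfg.min_genotype_depth) & (G.dosages != MISSING)
        G.dosages[low] = MISSING
        report.append(("genotype_depth_masked", int(low.sum())))
    elif G.genotype_depth is None and cfg.min_genotype_depth > 0:
        warnings.warn("no per-genotype depth; min_genotype_depth rule skipped")
        report.append(("genotype_depth_masked", 0))

    def drop(rule: str, keep: np.ndarray) -> None:
        nonlocal G
        removed = int((~keep).sum())
        report.append((rule, removed))
        if removed:
            G = G.subset_sites(np.flatnonzero(keep))

    def ann(key: str) -> np.ndarray | None:
        arr = G.site_annotations.get(key)
        if arr is None:
            warnings.warn(f"annotation {key!r} absent; rule skipped")
        return arr

    drop("minor_allele_count", _minor_allele_count(G.dosages) >= cfg.min_minor_allele_count)

    arr = ann("MEAN_DP")
    if arr is not None:
        drop("min_mean_site_depth", ~(arr < cfg.min_mean_site_depth))

    arr = ann("AB")
    if arr is not None:
        lo, hi = cfg.het_allele_balance
        # Allele balance annotated per site for heterozygote calls; sites with
        # no heterozygote (AB NaN or 0) pass.
        with np.errstate(invalid="ignore"):
            bad = (arr > 0) & ((arr <= lo) | (arr >= hi))
        drop("het_allele_balance", ~np.nan_to_num(bad, nan=False))

    arr = ann("HOM_AB") if "HOM_AB" in G.site_annotations else None
    if arr is not None:
        lo_max, hi_min = cfg.hom_allele_balance
        inside = (arr >= lo_max) & (arr <= hi_min)
        keep = inside if cfg.hom_keep_inside else ~inside
        drop("hom_allele_balance", keep)

    arr = ann("MQR")
    if arr is not None:
        lo, hi = cfg.mapq_ratio
        with np.errstate(invalid="ignore"):
            keep = (arr > lo) & (arr < hi)
        drop("mapq_ratio", np.nan_to_num(keep, nan=True))

    arr = ann("QD")
    if arr is not None:
        with np.errstate(invalid="ignore"):
            keep = arr > cfg.min_quality_per_depth
        drop("quality_per_depth", np.nan_to_num(keep, nan=True))

    arr = ann("MEAN_DP")
    if arr is not None:
        drop("max_mean_site_depth", ~(arr > cfg.max_mean_site_depth))

    drop(
        "site_missingness",
        ~(_site_missingness(G.dosages) > cfg.max_site_missingness),
    )
    return G, report


def filter_individuals(G: GenotypeMatrix, max_missing: float = 0.55) -> GenotypeMatrix:
    """Drop individuals with missing fraction strictly greater than the cap."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0,1]")
    frac = G.missing_mask().mean(axis=1) if G.n_loci else np.zeros(G.n_individuals)
    keep = np.flatnonzero(~(frac > max_missing))
    if keep.size == 0:
        raise EmptyCohortError("all individuals exceed the missingness cap")
    if keep.size == G.n_individuals:
        return G
    return G.subset_individuals(keep.tolist())


def ld_thin(G: GenotypeMatrix, window_bp: int = 5000) -> GenotypeMatrix:
    """Greedy per-scaffold thinning: keep the first site, then any site at
    least ``window_bp`` from the last kept site."""
    order = np.lexsort((G.positions, G.scaffolds.astype(str)))
    if not np.array_equal(order, np.arange(G.n_loci)):
        log.warning("ld_thin: input not sorted; sorting by (scaffold, position)")
        G = G.subset_sites(order)
    keep: list[int] = []
    last_scaffold = None
    last_pos = None
    for j in range(G.n_loci):
        s, p = G.scaffolds[j], int(G.positions[j])
        if s != last_scaffold or p - last_pos >= window_bp:
            keep.append(j)
            last_scaffold, last_pos = s, p
    return G.subset_sites(np.asarray(keep, dtype=int))


# ---------------------------------------------------------------------------
# Replicate error rates


def replicate_error_rates(
    pairs: list[tuple[np.ndarray, np.ndarray]],
) -> ErrorRates:
    """Genotyping error rates (%) from technical replicate pairs.

    Only sites called in both members count.  The global rate is pooled
    discordance.  Class-conditional rates condition on the genotype class
    (homozygous: dosage 0 or 2; heterozygous: dosage 1) of one replicate and
    average the two orderings, making the result symmetric in pair order.
    """
    disc = 0
    total = 0
    hom_disc = hom_total = 0
    het_disc = het_total = 0
    for a, b in pairs:
        a = np.asarray(a)
        b = np.asarray(b)
        if a.shape != b.shape:
            raise ValueError("replicate pair members must share loci")
        co = (a != MISSING) & (b != MISSING)
        mism = co & (a != b)
        disc += int(mism.sum())
        total += int(co.sum())
        for first, second in ((a, b), (b, a)):
            hom = co & ((first == 0) | (first == 2))
            het = co & (first == 1)
            hom_total += int(hom.sum())
            hom_disc += int((hom & (first != second)).sum())
            het_total += int(het.sum())
            het_disc += int((het & (first != second)).sum())
    if total == 0:
        raise UndefinedRateError("no co-called sites across replicate pairs")
    return ErrorRates(
        global_rate=100.0 * disc / total,
        homozygous=100.0 * hom_disc / hom_total if hom_total else float("nan"),
        heterozygous=100.0 * het_disc / het_total if het_total else float("nan"),
        n_pairs=len(pairs),
        n_sites_compared=total,
    )


def write_filter_report(report: list[tuple[str, int]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("rule\tsites_removed\n")
        for rule, removed in report:
            fh.write(f"{rule}\t{removed}\n")
    return path
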