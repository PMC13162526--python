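"""Marker and clone quality control, imputation and genotype/phenotype matching.

Filters follow the usual dosage-panel conventions: markers are removed when
minor allele frequency < ``maf_min`` or call rate < ``call_rate_min``
(retention therefore uses >=), clones when their missing fraction is strictly
greater than ``clone_missing_max``. Filtering is a single pass — markers
(MAF before call rate) and then clones — with a removal count per reason.
Residual missing calls are mean-imputed (2p), which preserves each marker's
allele frequency, and the centered matrix Z = dosage - 2p feeds the GRM and
all whole-genome regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import GenotypeTable, HcngpError, ValidationError, logger


@dataclass
class QCReport:
    """Per-filter accounting; retained + removed always equals the input."""
    n_markers_in: int
    n_clones_in: int
    removed_markers_maf: int = 0
    removed_markers_callrate: int = 0
    removed_clones: int = 0
    n_markers_out: int = 0
    n_clones_out: int = 0
    marker_stats: pd.DataFrame | None = None
    clone_missing: pd.Series | None = None

    def to_json_dict(self) -> dict:
        return {
            "n_markers_in": self.n_markers_in,
            "n_clones_in": self.n_clones_in,
            "removed_markers_maf": self.removed_markers_maf,
            "removed_markers_callrate": self.removed_markers_callrate,
            "removed_clones": self.removed_clones,
            "n_markers_out": self.n_markers_out,
            "n_clones_out": self.n_clones_out,
        }


def compute_marker_stats(geno: GenotypeTable) -> pd.DataFrame:
    """Per-marker MAF and call rate.

    call_rate = fraction of non-missing calls; p = mean(dosage)/2 over
    non-missing; MAF = min(p, 1-p). A marker with zero calls gets call_rate 0
    and MAF NaN (it fails both filters).
    """
    if geno.n_clones == 0:
        raise ValidationError("genotype table has no clones")
    X = geno.dosage
    n_called = (~np.isnan(X)).sum(axis=0)
    call_rate = n_called / geno.n_clones
    with np.errstate(invalid="ignore"):
        p = np.where(n_called > 0, np.nansum(X, axis=0) / (2.0 * np.maximum(n_called, 1)), np.nan)
    maf = np.minimum(p, 1.0 - p)
    return pd.DataFrame({"maf": maf, "call_rate": call_rate, "p": p},
                        index=geno.marker_ids)


def clone_missing_fraction(geno: GenotypeTable) -> pd.Series:
    frac = np.isnan(geno.dosage).mean(axis=1)
    return pd.Series(frac, index=geno.clone_ids, name="missing_fraction")


def filter_markers(geno: GenotypeTable, maf_min: float = 0.05,
                   call_rate_min: float = 0.80) -> tuple[GenotypeTable, QCReport]:
    """Keep markers with MAF >= maf_min AND call rate >= call_rate_min.

    When a marker fails both thresholds it is counted under MAF (the first
    filter applied). Markers with no calls fail both and count under MAF.
    """
    stats = compute_marker_stats(geno)
    maf = stats["maf"].to_numpy()
    cr = stats["call_rate"].to_numpy()
    fail_maf = ~(maf >= maf_min)          # NaN MAF fails
    fail_cr = cr < call_rate_min
    keep = ~fail_maf & ~fail_cr
    report = QCReport(
        n_markers_in=geno.n_markers, n_clones_in=geno.n_clones,
        removed_markers_maf=int(fail_maf.sum()),
        removed_markers_callrate=int((fail_cr & ~fail_maf).sum()),
        marker_stats=stats,
    )
    if not keep.any():
        raise HcngpError("no markers survive the MAF/call-rate filters")
    kept_ids = [m for m, k in zip(geno.marker_ids, keep) if k]
    out = geno.subset(markers=kept_ids)
    report.n_markers_out = out.n_markers
    report.n_clones_out = out.n_clones
    logger.info("marker QC: %d -> %d (MAF removed %d, call-rate removed %d)",
                geno.n_markers, out.n_markers,
                report.removed_markers_maf, report.removed_markers_callrate)
    return out, report


def filter_clones(geno: GenotypeTable,
                  missing_max: float = 0.20) -> tuple[GenotypeTable, QCReport]:
    """Drop clones whose missing fraction is strictly greater than missing_max
    (a clone at exactly the threshold is retained)."""
    frac = clone_missing_fraction(geno)
    keep = frac.to_numpy() <= missing_max
    if not keep.any():
        raise HcngpError("no clones survive the missingness filter")
    kept_ids = [c for c, k in zip(geno.clone_ids, keep) if k]
    out = geno.subset(clones=kept_ids)
    report = QCReport(
        n_markers_in=geno.n_markers, n_clones_in=geno.n_clones,
        removed_clones=int((~keep).sum()),
        n_markers_out=out.n_markers, n_clones_out=out.n_clones,
        clone_missing=frac,
    )
    logger.info("clone QC: %d -> %d (removed %d with missing > %.0f%%)",
                geno.n_clones, out.n_clones, report.removed_clones,
                100 * missing_max)
    return out, report


def run_qc(geno: GenotypeTable, maf_min: float = 0.05,
           call_rate_min: float = 0.80,
           clone_missing_max: float = 0.20) -> tuple[GenotypeTable, QCReport]:
    """Single-pass QC: markers (MAF, then call rate), then clones."""
    g1, rep_m = filter_markers(geno, maf_min, call_rate_min)
    g2, rep_c = filter_clones(g1, clone_missing_max)
    report = QCReport(
        n_markers_in=geno.n_markers, n_clones_in=geno.n_clones,
        removed_markers_maf=rep_m.removed_markers_maf,
        removed_markers_callrate=rep_m.removed_markers_callrate,
        removed_clones=rep_c.removed_clones,
        n_markers_out=g2.n_markers, n_clones_out=g2.n_clones,
        marker_stats=rep_m.marker_stats, clone_missing=rep_c.clone_missing,
    )
    return g2, report


@dataclass
class CenteredGenotypes:
    """Mean-imputed, column-centered dosages ready for GRM and regression."""
    clone_ids: list[str]
    marker_ids: list[str]
    Z: np.ndarray                 # dosage - 2p, no missing values
    p: np.ndarray                 # allele frequency per marker
    dosage_imputed: np.ndarray    # dosage with missing replaced by 2p

    def rows(self, clones: list[str]) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.clone_ids)}
        return self.Z[[idx[c] for c in clones]]


def impute_and_center(geno: GenotypeTable) -> CenteredGenotypes:
    """Replace residual missing calls by the marker mean dosage 2p and center.

    Column means of Z are exactly zero because imputation happens first.
    """
    X = geno.dosage.copy()
    n_called = (~np.isnan(X)).sum(axis=0)
    if (n_called == 0).any():
        raise ValidationError("cannot impute a marker with zero calls; "
                              "run the call-rate filter first")
    p = np.nansum(X, axis=0) / (2.0 * n_called)
    fill = 2.0 * p
    idx = np.where(np.isnan(X))
    X[idx] = fill[idx[1]]
    Z = X - fill[np.newaxis, :]
    return CenteredGenotypes(list(geno.clone_ids), list(geno.marker_ids),
                             Z, p, X)


def match_geno_pheno(geno: GenotypeTable,
                     blues: pd.DataFrame) -> tuple[GenotypeTable, pd.DataFrame]:
    """Intersect genotypes and per-clone BLUEs on clone id.

    Output order is canonical: the genotype table's clone order. Counts
    dropped from each side are logged.
    """
    pheno_ids = set(blues["clone_id"].astype(str))
    shared = [c for c in geno.clone_ids if c in pheno_ids]
    if not shared:
        raise HcngpError("no clones shared between genotypes and phenotypes")
    dropped_g = geno.n_clones - len(shared)
    dropped_p = len(pheno_ids) - len(shared)
    logger.info("matched %d clones (dropped %d genotyped-only, %d phenotyped-only)",
                len(shared), dropped_g, dropped_p)
    aligned_blues = (blues.set_index(blues["clone_id"].astype(str))
                     .loc[shared].reset_index(drop=True))
    return geno.subset(clones=shared), aligned_blues
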