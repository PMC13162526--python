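"""File formats, run configuration and shared domain types.

The pipeline works on three plain-text formats:

* a dosage CSV (rows = clones, columns = markers, cells in {0,1,2,empty}),
  optionally imported from VCF v4.2 (biallelic SNPs only);
* a plot-level phenotype CSV (clone, location, year, block, check flag and up
  to six ordinal subsample scores on the 1-9 picrate scale);
* square relationship-matrix CSVs and per-clone BLUE CSVs written downstream.

Dosages count copies of the alternate allele. All models downstream are
invariant to polarity flips given matching allele frequencies, so the choice
is a convention, not a modelling decision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("hcngp")

SCORE_MIN, SCORE_MAX = 1, 9
SCORE_COLS = [f"score_{i}" for i in range(1, 7)]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class HcngpError(Exception):
    """Base class for all pipeline errors."""


class ParseError(HcngpError):
    """A file could not be parsed; the message names the offending cell."""


class ValidationError(HcngpError):
    """Input violated a structural invariant (duplicate ids, bad range...)."""


class ConfigError(HcngpError):
    """Run configuration is inconsistent or contains unknown keys."""


class DesignError(HcngpError):
    """A trial design request cannot be satisfied."""


class SimulationError(HcngpError):
    """A simulation target is unattainable with the given genotypes."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class QcConfig:
    """Marker/clone filter thresholds (retention uses MAF >= maf_min and
    call rate >= call_rate_min; clones removed when missing > clone_missing_max)."""
    maf_min: float = 0.05
    call_rate_min: float = 0.80
    clone_missing_max: float = 0.20

    def validate(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ConfigError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        for name in ("call_rate_min", "clone_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass
class McmcConfig:
    """Sampler settings shared by the Bayesian alphabet and RKHS fits.

    ``s0`` is the residual scaled-inverse-chi-square prior scale. ``None``
    derives it from the response variance (prior mode at half the phenotypic
    variance); a number is used literally.
    """
    n_iter: int = 6000
    burn_in: int = 700
    df0: float = 5.0
    s0: Optional[float] = None

    def validate(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ConfigError(
                f"burn_in ({self.burn_in}) must be < n_iter ({self.n_iter})")
        if self.df0 <= 0:
            raise ConfigError("df0 must be > 0")
        if self.s0 is not None and self.s0 <= 0:
            raise ConfigError("s0 must be > 0 when given")


@dataclass
class CvConfig:
    k: int = 5
    reps: int = 5
    seed: int = 2026

    def validate(self) -> None:
        if self.k < 2:
            raise ConfigError("cv k must be >= 2")
        if self.reps < 1:
            raise ConfigError("cv reps must be >= 1")


@dataclass
class RkhsConfig:
    theta: float = 1.0
    distance: str = "squared_euclidean_mean"

    def validate(self) -> None:
        if self.theta <= 0:
            raise ConfigError("rkhs theta must be > 0")
        if self.distance not in ("squared_euclidean_mean", "euclidean"):
            raise ConfigError(f"unknown rkhs distance {self.distance!r}")


@dataclass
class RunConfig:
    qc: QcConfig = field(default_factory=QcConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    cv: CvConfig = field(default_factory=CvConfig)
    rkhs: RkhsConfig = field(default_factory=RkhsConfig)
    # simulation block is a SimConfig; typed loosely to avoid an import cycle
    simulation: Optional[object] = None

    def validate(self) -> "RunConfig":
        self.qc.validate()
        self.mcmc.validate()
        self.cv.validate()
        self.rkhs.validate()
        if self.simulation is not None:
            self.simulation.validate()
        return self

    def config_hash(self) -> str:
        """Stable short hash of the configuration, logged with every run."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _from_mapping(cls, mapping: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in config section '{section}'")
    return cls(**mapping)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config with flat sections qc / mcmc / cv / rkhs / simulation.

    Unknown keys anywhere are errors, so typos fail loudly instead of
    silently falling back to defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw)}")
    known = {"qc", "mcmc", "cv", "rkhs", "simulation"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    from .synthetic_data import SimConfig  # local import: avoid cycle
    cfg = RunConfig(
        qc=_from_mapping(QcConfig, raw.get("qc", {}), "qc"),
        mcmc=_from_mapping(McmcConfig, raw.get("mcmc", {}), "mcmc"),
        cv=_from_mapping(CvConfig, raw.get("cv", {}), "cv"),
        rkhs=_from_mapping(RkhsConfig, raw.get("rkhs", {}), "rkhs"),
        simulation=(_from_mapping(SimConfig, raw["simulation"], "simulation")
                    if "simulation" in raw else None),
    )
    return cfg.validate()


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Clone x marker alternate-allele dosages with optional marker map.

    ``dosage`` is float64 with values in {0, 1, 2} and NaN for missing calls.
    ``marker_meta`` (optional) is a DataFrame indexed like ``marker_ids`` with
    columns ``chrom`` (free-form label) and ``pos`` (1-based integer).
    """
    clone_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray
    marker_meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.clone_ids), len(self.marker_ids)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.clone_ids)} clones x {len(self.marker_ids)} markers")
        if len(set(self.clone_ids)) != len(self.clone_ids):
            raise ValidationError("duplicate clone ids in genotype table")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValidationError("duplicate marker ids in genotype table")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValidationError(f"dosage values must be 0/1/2/missing, found {bad}")
        if self.marker_meta is not None:
            missing = set(self.marker_ids) - set(self.marker_meta.index)
            if missing:
                raise ValidationError(
                    f"marker_meta lacks {len(missing)} marker ids")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset(self, clones: Optional[Sequence[str]] = None,
               markers: Optional[Sequence[str]] = None) -> "GenotypeTable":
        """Row/column subset preserving the order given in the arguments."""
        ci = {c: i for i, c in enumerate(self.clone_ids)}
        mi = {m: i for i, m in enumerate(self.marker_ids)}
        rows = [ci[c] for c in clones] if clones is not None else range(self.n_clones)
        cols = [mi[m] for m in markers] if markers is not None else range(self.n_markers)
        meta = None
        if self.marker_meta is not None:
            keep = list(markers) if markers is not None else self.marker_ids
            meta = self.marker_meta.loc[keep]
        return GenotypeTable(
            clone_ids=[self.clone_ids[i] for i in rows],
            marker_ids=[self.marker_ids[j] for j in cols],
            dosage=self.dosage[np.ix_(list(rows), list(cols))],
            marker_meta=meta,
        )


def read_genotypes(path: str | Path, format: str = "dosage_csv") -> GenotypeTable:
    """Read genotypes from a dosage CSV or a (biallelic) VCF.

    Dosage CSV layout: header row = marker ids with first column the clone id
    column; cells are 0/1/2 or empty (missing). VCF import converts biallelic
    genotypes to alternate-allele dosage; multi-allelic sites are dropped with
    a logged count.
    """
    if format == "dosage_csv":
        return _read_dosage_csv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ConfigError(f"unknown genotype format {format!r}")


def _read_dosage_csv(path: str | Path) -> GenotypeTable:
    df = pd.read_csv(path, index_col=0, dtype=str)
    clone_ids = [str(c) for c in df.index]
    marker_ids = [str(m) for m in df.columns]
    dosage = np.full(df.shape, np.nan)
    arr = df.to_numpy()
    for j in range(arr.shape[1]):
        for i in range(arr.shape[0]):
            cell = arr[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            s = str(cell).strip()
            if s == "" or s.lower() == "nan":
                continue
            if s not in ("0", "1", "2", "0.0", "1.0", "2.0"):
                raise ParseError(
                    f"invalid dosage {s!r} at row {clone_ids[i]!r}, "
                    f"column {marker_ids[j]!r} in {path}")
            dosage[i, j] = float(s)
    return GenotypeTable(clone_ids, marker_ids, dosage)


def _read_vcf(path: str | Path) -> GenotypeTable:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise HcngpError("VCF import requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    clone_ids = list(vcf.samples)
    marker_ids: list[str] = []
    rows = []
    chroms, poss = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        mid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(v.gt_types)
        dos = np.full(gt.shape, np.nan)
        dos[gt == 0] = 0.0
        dos[gt == 1] = 1.0
        dos[gt == 3] = 2.0
        marker_ids.append(mid)
        rows.append(dos)
        chroms.append(v.CHROM)
        poss.append(v.POS)
    if n_multi:
        logger.info("VCF import: dropped %d multi-allelic site(s)", n_multi)
    if not marker_ids:
        raise ValidationError(f"no biallelic SNPs found in {path}")
    meta = pd.DataFrame({"chrom": chroms, "pos": poss}, index=marker_ids)
    return GenotypeTable(clone_ids, marker_ids, np.column_stack(rows), meta)


def write_genotypes(geno: GenotypeTable, path: str | Path) -> None:
    """Write a dosage CSV; missing calls become empty cells.

    Round-trips bit-exactly through :func:`read_genotypes` (dosages are
    small integers, written as such).
    """
    df = pd.DataFrame(geno.dosage, index=geno.clone_ids, columns=geno.marker_ids)
    txt = df.map(lambda v: "" if np.isnan(v) else str(int(v)))
    txt.index.name = "clone_id"
    txt.to_csv(path)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeSet:
    """Plot-level trial records.

    ``data`` columns: clone_id, location, year, block_id, is_check,
    score_1..score_6 (NaN where fewer than six subsamples), plot_mean.
    """
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["clone_id", "location", "year", "block_id", "is_check"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"phenotype table lacks column(s) {missing}")
        scores = self.data[[c for c in SCORE_COLS if c in self.data.columns]]
        if scores.shape[1] == 0:
            raise ValidationError("phenotype table has no score columns")
        vals = scores.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and ((finite < SCORE_MIN) | (finite > SCORE_MAX)).any():
            bad = finite[(finite < SCORE_MIN) | (finite > SCORE_MAX)][0]
            raise ValidationError(
                f"HCN score {bad} outside the ordinal range [1, 9]")
        n_scores = (~np.isnan(vals)).sum(axis=1)
        if (n_scores == 0).any():
            row = int(np.nonzero(n_scores == 0)[0][0])
            raise ValidationError(f"phenotype row {row} has no scores")
        means = np.nanmean(vals, axis=1)
        if "plot_mean" in self.data.columns:
            given = self.data["plot_mean"].to_numpy(dtype=float)
            if not np.allclose(given, means, atol=1e-8, equal_nan=False):
                raise ValidationError(
                    "plot_mean column inconsistent with the mean of scores")
        self.data = self.data.assign(plot_mean=means)

    @property
    def clone_ids(self) -> list[str]:
        return list(pd.unique(self.data["clone_id"]))

    def __len__(self) -> int:
        return len(self.data)


def read_phenotypes(path: str | Path) -> PhenotypeSet:
    df = pd.read_csv(path)
    df["clone_id"] = df["clone_id"].astype(str)
    return PhenotypeSet(df.drop(columns=["plot_mean"], errors="ignore"))


def write_phenotypes(pheno: PhenotypeSet, path: str | Path) -> None:
    pheno.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Matrices and per-clone tables
# ---------------------------------------------------------------------------

def write_square_matrix(ids: Sequence[str], values: np.ndarray,
                        path: str | Path) -> None:
    """Square CSV with header = ids (used for GRM and kernel matrices)."""
    pd.DataFrame(values, index=list(ids), columns=list(ids)).to_csv(path)


def read_square_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return [str(i) for i in df.index], df.to_numpy(dtype=float)


def write_blues(blues: pd.DataFrame, path: str | Path) -> None:
    """BLUEs CSV: clone_id, blue, se."""
    blues.to_csv(path, index=False)


def read_blues(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["clone_id"] = df["clone_id"].astype(str)
    return df


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
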