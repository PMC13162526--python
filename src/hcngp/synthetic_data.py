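"""Synthetic cassava genomic-selection data with the structure the analysis assumes.

The generator emulates a clonal evaluation population: a modest founder set,
full-sib families (half-sib across shared sires) produced by gene-dropping at
independent markers, an oligogenic trait with two major QTL (on chr14 and
chr16, explaining ~7% and ~30% of phenotypic variance by default) plus a
small polygenic tail and optional dominance at the QTL, and multi-location
augmented trials: blocks of 15 plots containing 2 repeated check clones,
clone-by-location and block noise, and six ordinal 1-9 subsample scores per
plot obtained by rounding a latent Gaussian plot value at half-integer cut
points.

Markers are simulated in linkage equilibrium; family structure alone supplies
marker-QTL correlation. This is sufficient to exercise every estimator
downstream but does not reproduce LD decay along chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_config import (ConfigError, DesignError, GenotypeTable, PhenotypeSet,
                        SimulationError, logger)

#: number of subsample picrate readings per plot
N_SUBSAMPLES = 6


@dataclass
class SimConfig:
    """Study conditions for the simulated population and trials.

    Defaults describe a family-structured clonal population of 29 full-sib
    families x 13 offspring (= 377 test clones, filling exactly 29 blocks of
    15 plots with 2 checks each per location), genotyped at 2,000 markers on
    18 chromosomes, with an oligogenic HCN-like trait (QTL on chr16 and chr14
    at 30% and 7% of phenotypic variance, 3% polygenic tail, 15% of genetic
    variance as dominance) scored at three locations on the 1-9 scale around
    a grand mean of 6.1.
    """
    n_founders: int = 40
    n_families: int = 29
    family_size: int = 13
    n_markers: int = 2000
    n_chromosomes: int = 18
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.03
    qtl_spec: tuple[tuple[str, float], ...] = (("chr14", 0.07), ("chr16", 0.30))
    polygenic_h2: float = 0.03
    dominance_fraction: float = 0.15
    n_locations: int = 3
    mu: float = 6.1
    location_effects: tuple[float, ...] = (-0.8, 0.3, 0.5)
    blocks_per_trial: int = 29
    plots_per_block: int = 15
    checks_per_block: int = 2
    var_clone_location: float = 0.6
    var_block: float = 0.2
    var_residual: float = 1.3
    var_subsample: float = 0.5
    seed: int = 2026

    def validate(self) -> "SimConfig":
        if self.n_founders < 2:
            raise ConfigError("n_founders must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        fracs = [f for _, f in self.qtl_spec] + [self.polygenic_h2,
                                                 self.dominance_fraction,
                                                 self.missing_rate]
        for f in fracs:
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"fraction {f} outside [0, 1]")
        if sum(f for _, f in self.qtl_spec) + self.polygenic_h2 > 1.0:
            raise ConfigError("QTL variance fractions + polygenic_h2 exceed 1")
        if self.checks_per_block >= self.plots_per_block:
            raise ConfigError("checks_per_block must be < plots_per_block")
        for v in (self.var_clone_location, self.var_block, self.var_residual,
                  self.var_subsample):
            if v < 0:
                raise ConfigError("variances must be >= 0")
        return self

    @property
    def additive_fraction(self) -> float:
        """Additive fraction of phenotypic variance (QTL + polygenic)."""
        return sum(f for _, f in self.qtl_spec) + self.polygenic_h2

    @property
    def phenotypic_variance(self) -> float:
        """Latent plot-level phenotypic variance implied by the fractions.

        sigma2_P = A + D + var_cl + var_e with A = f_a * sigma2_P and
        D = A * d/(1-d); solving gives the closed form below.
        """
        c = self.var_clone_location + self.var_residual
        d = self.dominance_fraction
        denom = 1.0 - self.additive_fraction / (1.0 - d) if d < 1 else np.nan
        if not denom > 0:
            raise ConfigError("variance fractions leave no room for noise terms")
        return c / denom


@dataclass
class SimTruth:
    """Ground truth attached to a simulated population."""
    clone_ids: list[str]
    true_breeding_values: pd.Series          # additive genetic values, centered
    total_genetic_values: pd.Series          # additive + dominance, centered
    qtl_marker_ids: list[str]
    qtl_effects: list[float]
    realized_variances: dict                 # additive / dominance / residual
    pedigree: dict                           # clone -> (sire, dam) or (None, None)
    check_ids: list[str]
    test_ids: list[str]

    def to_json_dict(self) -> dict:
        return {
            "true_breeding_values": self.true_breeding_values.round(6).to_dict(),
            "qtl_marker_ids": self.qtl_marker_ids,
            "qtl_effects": self.qtl_effects,
            "realized_variances": self.realized_variances,
            "check_ids": self.check_ids,
        }


def _marker_map(cfg: SimConfig) -> pd.DataFrame:
    """Assign markers to chromosomes in contiguous blocks with 1-based positions."""
    ids = [f"S{j + 1}" for j in range(cfg.n_markers)]
    per = int(math.ceil(cfg.n_markers / cfg.n_chromosomes))
    chroms, poss = [], []
    for j in range(cfg.n_markers):
        c = j // per + 1
        chroms.append(f"chr{c}")
        poss.append((j % per) * 1000 + 1)
    return pd.DataFrame({"chrom": chroms, "pos": poss}, index=ids)


def simulate_genotypes(cfg: SimConfig, seed: Optional[int] = None,
                       founder_dosage: Optional[np.ndarray] = None,
                       ) -> tuple[GenotypeTable, dict]:
    """Gene-drop a family-structured population from HWE founders.

    Founders are drawn with per-marker allele frequencies uniform in
    ``maf_range``; each full-sib family shares a sire and a dam (sires drawn
    from one half of the founders, dams from the other, both with
    replacement, so shared sires create half-sib ties across families). Each
    parent transmits one allele per marker independently. The returned table
    holds founders, two check clones and all offspring; missing calls are
    masked uniformly at ``missing_rate``.

    ``founder_dosage`` (n_founders x n_markers, values in {0,1,2}) overrides
    the random founders — useful for controlled crosses.
    """
    cfg.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 0]))
    m = cfg.n_markers
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    founder_ids = [f"F{i + 1:03d}" for i in range(cfg.n_founders)]
    if founder_dosage is not None:
        founders = np.asarray(founder_dosage, dtype=float)
        if founders.shape != (cfg.n_founders, m):
            raise ConfigError(
                f"founder_dosage shape {founders.shape} does not match "
                f"{cfg.n_founders} founders x {m} markers")
    else:
        founders = rng.binomial(2, freqs, size=(cfg.n_founders, m)).astype(float)

    half = max(1, cfg.n_founders // 2)
    sires = rng.integers(0, half, size=cfg.n_families)
    dams = rng.integers(half, cfg.n_founders, size=cfg.n_families)

    n_off = cfg.n_families * cfg.family_size
    offspring = np.empty((n_off, m))
    pedigree: dict = {f: (None, None) for f in founder_ids}
    offspring_ids = []
    k = 0
    for fam in range(cfg.n_families):
        s, d = int(sires[fam]), int(dams[fam])
        for _ in range(cfg.family_size):
            oid = f"C{k + 1:04d}"
            offspring_ids.append(oid)
            pedigree[oid] = (founder_ids[s], founder_ids[d])
            gs = rng.binomial(1, founders[s] / 2.0)
            gd = rng.binomial(1, founders[d] / 2.0)
            offspring[k] = gs + gd
            k += 1

    check_ids = ["CK1", "CK2"]
    checks = rng.binomial(2, freqs, size=(2, m)).astype(float)
    for c in check_ids:
        pedigree[c] = (None, None)

    clone_ids = founder_ids + check_ids + offspring_ids
    dosage = np.vstack([founders, checks, offspring])
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage = dosage.copy()
        dosage[mask] = np.nan
    geno = GenotypeTable(clone_ids, list(_marker_map(cfg).index), dosage,
                         marker_meta=_marker_map(cfg))
    logger.info("simulated %d clones x %d markers (%d families of %d)",
                geno.n_clones, geno.n_markers, cfg.n_families, cfg.family_size)
    return geno, pedigree


def _complete_dosage(geno: GenotypeTable) -> np.ndarray:
    """Marker-mean fill of residual missing calls (used only to define truth)."""
    X = geno.dosage.copy()
    means = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = means[idx[1]]
    return X


def simulate_trait(geno: GenotypeTable, cfg: SimConfig,
                   pedigree: Optional[dict] = None,
                   seed: Optional[int] = None) -> SimTruth:
    """Assign QTL, polygenic and dominance effects matching the target fractions.

    One QTL per ``qtl_spec`` entry: the highest-MAF marker on the stated
    chromosome (deterministic given the table). Additive effects are scaled so
    each QTL's realized variance fraction (of the latent phenotypic variance)
    hits its target on this population; the polygenic tail is a sum of small
    Gaussian effects on the remaining markers scaled to ``polygenic_h2``; the
    dominance deviation (a heterozygote effect at each QTL) is scaled to
    ``dominance_fraction`` of the total genetic variance.
    """
    cfg.validate()
    if geno.marker_meta is None:
        raise SimulationError("genotype table lacks marker chromosome labels")
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 1]))
    X = _complete_dosage(geno)
    n = geno.n_clones
    var_p = cfg.phenotypic_variance
    p_hat = X.mean(axis=0) / 2.0
    maf = np.minimum(p_hat, 1 - p_hat)
    marker_idx = {mk: j for j, mk in enumerate(geno.marker_ids)}

    qtl_ids, qtl_effects, qtl_cols = [], [], []
    additive = np.zeros(n)
    for chrom, frac in cfg.qtl_spec:
        on_chrom = geno.marker_meta.index[geno.marker_meta["chrom"] == chrom]
        if len(on_chrom) == 0:
            raise SimulationError(f"no markers on QTL chromosome {chrom!r}")
        cand = [marker_idx[mk] for mk in on_chrom]
        j = cand[int(np.argmax(maf[cand]))]
        x = X[:, j]
        vx = x.var()
        if vx <= 0:
            raise SimulationError(
                f"QTL chromosome {chrom!r} is monomorphic; variance fraction "
                f"{frac} unattainable")
        a = math.sqrt(frac * var_p / vx)
        qtl_ids.append(geno.marker_ids[j])
        qtl_effects.append(a)
        qtl_cols.append(j)
        additive = additive + a * x

    other = [j for j in range(geno.n_markers) if j not in qtl_cols]
    if cfg.polygenic_h2 > 0 and other:
        beta = rng.standard_normal(len(other))
        score = X[:, other] @ beta
        vs = score.var()
        if vs <= 0:
            raise SimulationError("polygenic background is monomorphic")
        additive = additive + score * math.sqrt(cfg.polygenic_h2 * var_p / vs)

    tbv = additive - additive.mean()

    dom = np.zeros(n)
    if cfg.dominance_fraction > 0 and qtl_cols:
        target_d = (tbv.var() * cfg.dominance_fraction
                    / (1.0 - cfg.dominance_fraction))
        raw = np.zeros(n)
        for j in qtl_cols:
            het = (X[:, j] == 1).astype(float)
            raw = raw + (het - het.mean())
        vr = raw.var()
        if vr > 0:
            dom = raw * math.sqrt(target_d / vr)
    total = tbv + dom
    total = total - total.mean()

    ped = pedigree or {c: (None, None) for c in geno.clone_ids}
    check_ids = [c for c in geno.clone_ids if c.startswith("CK")]
    test_ids = [c for c in geno.clone_ids
                if ped.get(c, (None, None))[0] is not None]
    if not test_ids:  # e.g. a hand-built table: everything is a test clone
        test_ids = [c for c in geno.clone_ids if c not in check_ids]
    realized = {
        "additive": float(tbv.var()),
        "dominance": float(dom.var()),
        "residual": float(cfg.var_clone_location + cfg.var_residual),
        "phenotypic_target": float(var_p),
    }
    return SimTruth(
        clone_ids=list(geno.clone_ids),
        true_breeding_values=pd.Series(tbv, index=geno.clone_ids),
        total_genetic_values=pd.Series(total, index=geno.clone_ids),
        qtl_marker_ids=qtl_ids,
        qtl_effects=[float(a) for a in qtl_effects],
        realized_variances=realized,
        pedigree=ped,
        check_ids=check_ids,
        test_ids=test_ids,
    )


def _ordinal_score(latent: np.ndarray) -> np.ndarray:
    """Map latent values onto the 1-9 scale with cut points at half-integers:
    score s iff latent in [s-0.5, s+0.5), clamped at the extremes."""
    return np.clip(np.floor(latent + 0.5), 1, 9)


def simulate_trials(truth: SimTruth, cfg: SimConfig,
                    seed: Optional[int] = None) -> PhenotypeSet:
    """Lay out multi-location augmented trials and score six subsamples per plot.

    Every test clone appears once per location; each block holds
    ``plots_per_block`` plots of which ``checks_per_block`` are the repeated
    check clones. The latent plot value is mu + location effect + total
    genetic value + block effect + clone-by-location effect + plot residual;
    the six subsample scores add independent subsample noise before ordinal
    rounding.
    """
    cfg.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 2]))
    test = list(truth.test_ids)
    checks = list(truth.check_ids)[:cfg.checks_per_block]
    entries_per_block = cfg.plots_per_block - len(checks)
    capacity = cfg.blocks_per_trial * entries_per_block
    if len(test) > capacity:
        raise DesignError(
            f"{len(test)} clones exceed the trial capacity of "
            f"{cfg.blocks_per_trial} blocks x {entries_per_block} entries "
            f"(= {capacity}) without clone reuse")
    n_blocks = max(1, math.ceil(len(test) / entries_per_block))

    g = truth.total_genetic_values
    loc_eff = list(cfg.location_effects)[:cfg.n_locations]
    loc_eff += [0.0] * (cfg.n_locations - len(loc_eff))
    rows = []
    for li in range(cfg.n_locations):
        loc = f"L{li + 1}"
        year = 2019 + li
        order = list(rng.permutation(test))
        cl_eff = {c: rng.normal(0.0, math.sqrt(cfg.var_clone_location))
                  for c in sorted(set(test) | set(checks))}
        for b in range(n_blocks):
            block_id = f"{loc}_B{b + 1:02d}"
            b_eff = rng.normal(0.0, math.sqrt(cfg.var_block))
            entries = order[b * entries_per_block:(b + 1) * entries_per_block]
            for clone in checks + entries:
                latent = (cfg.mu + loc_eff[li] + g[clone] + b_eff
                          + cl_eff[clone]
                          + rng.normal(0.0, math.sqrt(cfg.var_residual)))
                sub = latent + rng.normal(0.0, math.sqrt(cfg.var_subsample),
                                          size=N_SUBSAMPLES)
                scores = _ordinal_score(sub)
                rows.append({
                    "clone_id": clone, "location": loc, "year": year,
                    "block_id": block_id, "is_check": clone in checks,
                    **{f"score_{i + 1}": scores[i] for i in range(N_SUBSAMPLES)},
                })
    return PhenotypeSet(pd.DataFrame(rows))


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeTable, SimTruth, PhenotypeSet]:
    """Genotypes, trait truth and trial phenotypes in one deterministic call."""
    geno, ped = simulate_genotypes(cfg)
    truth = simulate_trait(geno, cfg, pedigree=ped)
    pheno = simulate_trials(truth, cfg)
    return geno, truth, pheno
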