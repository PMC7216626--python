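"""mtDNA copy-number estimation from read depth and petite classification.

Per-haploid copy number is the ratio of the mean of the median depths of
three intron-less marker CDSs (ATP6, COX2, COX3) to the nuclear depth
(median over chromosomes of the per-chromosome median); the total copy
number is that ratio times the ploidy. Coverage tables are assumed to be
pre-filtered upstream (e.g. mapping quality); no GC correction is applied.

A gene is called retained when its per-haploid depth ratio reaches
``presence_threshold`` x the population-median per-haploid copy number:
all eight retained = rho+, none = rho0, otherwise rho- with the retained
set reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CoverageTable
from .sim import CANONICAL_GENES

DEFAULT_CN_GENES = ("ATP6", "COX2", "COX3")


class CoverageError(ValueError):
    pass


@dataclass
class CopyNumberEstimate:
    isolate: str
    per_haploid_cn: float
    total_cn: float
    ploidy: int
    mito_depths: dict[str, float]
    nuclear_depth: float
    flagged_missing: tuple[str, ...] = ()


@dataclass
class PetiteCall:
    isolate: str
    status: str                 # rho_plus / rho_minus / rho_zero
    retained_genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.status == "rho_zero" and self.retained_genes:
            raise ValueError("rho_zero call with retained genes")
        if self.status == "rho_plus" and len(self.retained_genes) != len(CANONICAL_GENES):
            raise ValueError("rho_plus call without all genes retained")


def _nuclear_depth(cov: CoverageTable, isolate: str) -> float:
    sub = cov.nuclear[cov.nuclear["isolate"] == isolate]
    if sub.empty:
        raise CoverageError(f"{isolate}: no nuclear coverage rows")
    med = float(sub["median_depth"].median())
    if med <= 0:
        raise CoverageError(f"{isolate}: nuclear depth is zero")
    return med


def estimate_cn(cov: CoverageTable, isolate: str,
                genes: tuple[str, ...] = DEFAULT_CN_GENES) -> CopyNumberEstimate:
    """Estimate per-haploid and total mtDNA copy number for one isolate."""
    if isolate not in cov.ploidy:
        raise CoverageError(f"{isolate}: ploidy unknown")
    sub = cov.mito[cov.mito["isolate"] == isolate]
    depths = dict(zip(sub["feature"], sub["median_depth"].astype(float)))
    have = [g for g in genes if g in depths]
    missing = tuple(g for g in genes if g not in depths)
    if not have:
        raise CoverageError(f"{isolate}: none of {genes} has coverage")
    nuc = _nuclear_depth(cov, isolate)
    per_haploid = float(np.mean([depths[g] for g in have])) / nuc
    ploidy = int(cov.ploidy[isolate])
    return CopyNumberEstimate(
        isolate=isolate, per_haploid_cn=per_haploid,
        total_cn=per_haploid * ploidy, ploidy=ploidy,
        mito_depths={g: depths[g] for g in have}, nuclear_depth=nuc,
        flagged_missing=missing)


def population_median_cn(cov: CoverageTable,
                         genes: tuple[str, ...] = DEFAULT_CN_GENES) -> float:
    """Median per-haploid copy number across all isolates in a table."""
    vals = [estimate_cn(cov, iso, genes).per_haploid_cn
            for iso in cov.isolates()]
    return float(np.median(vals))


def classify_petite(cov: CoverageTable, isolate: str,
                    presence_threshold: float = 0.05,
                    population_cn: float | None = None) -> PetiteCall:
    """Classify rho status from the per-gene depth ratios of one isolate."""
    if population_cn is None:
        population_cn = population_median_cn(cov)
    nuc = _nuclear_depth(cov, isolate)
    sub = cov.mito[cov.mito["isolate"] == isolate]
    depths = dict(zip(sub["feature"], sub["median_depth"].astype(float)))
    cutoff = presence_threshold * population_cn
    retained = frozenset(g for g in CANONICAL_GENES
                         if depths.get(g, 0.0) / nuc >= cutoff)
    if len(retained) == len(CANONICAL_GENES):
        status = "rho_plus"
    elif not retained:
        status = "rho_zero"
    else:
        status = "rho_minus"
    return PetiteCall(isolate=isolate, status=status, retained_genes=retained)


def ploidy_scaling_report(estimates: list[CopyNumberEstimate],
                          petite_calls: dict[str, PetiteCall] | None = None
                          ) -> tuple[pd.DataFrame, float]:
    """Per-ploidy-class medians and the through-origin slope of total copy
    number vs ploidy. Isolates flagged petite are excluded from the fit."""
    rows = []
    for e in estimates:
        if petite_calls is not None:
            call = petite_calls.get(e.isolate)
            if call is not None and call.status != "rho_plus":
                continue
        rows.append((e.isolate, e.ploidy, e.per_haploid_cn, e.total_cn))
    df = pd.DataFrame(rows, columns=["isolate", "ploidy", "per_haploid_cn",
                                     "total_cn"])
    classes = df.groupby("ploidy").agg(
        n=("isolate", "size"),
        median_total_cn=("total_cn", "median"),
        median_per_haploid_cn=("per_haploid_cn", "median")).reset_index()
    if classes.shape[0] < 2:
        raise CoverageError("need at least 2 ploidy classes for the scaling fit")
    p = df["ploidy"].to_numpy(float)
    t = df["total_cn"].to_numpy(float)
    slope = float((p * t).sum() / (p * p).sum())
    return classes, slope
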