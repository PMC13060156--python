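"""Relative quantification arithmetic for qPCR and ddPCR data.

Implements the delta-Cq method (fold-change = 2^-dCq with dCq the
difference of mean triplicate quantification cycles between target and
reference), summation of per-variant prophage fold-changes before any log
transform, and spike-in normalization of ddPCR transcript concentrations.
All operations are deterministic; missing data (all-undetermined triplicates,
zero target concentrations) are flagged rather than imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DensityValue",
    "MissingDataError",
    "cq_to_fold",
    "sum_wovirus_variants",
    "spikein_abundance",
    "densities_from_cq",
    "abundance_table_from_ddpcr",
]

log = logging.getLogger("citherm.relquant")

METRICS = ("wolbachia_per_host", "wovirus_per_wolbachia", "wovirus_per_host")


class MissingDataError(ValueError):
    """Raised when a quantity cannot be computed from the available wells."""


@dataclass(frozen=True)
class DensityValue:
    """A relative density: fold-change and its log2, for one sample."""

    sample_id: str
    metric: str
    fold: float
    log2_fold: float

    def __post_init__(self):
        if not math.isclose(self.log2_fold, math.log2(self.fold),
                            rel_tol=0, abs_tol=1e-12):
            raise ValueError("log2_fold inconsistent with fold")


def _triplet_mean(cq, what):
    vals = [v for v in cq if np.isfinite(v)]
    if not vals:
        raise MissingDataError(f"all-undetermined triplet for {what}")
    return float(np.mean(vals))


def cq_to_fold(cq_target, cq_reference, sample_id: str = "",
               metric: str = "wolbachia_per_host") -> DensityValue:
    """Fold-change 2^-dCq from target and reference Cq triplicates.

    dCq = mean(target Cq) - mean(reference Cq); undetermined wells (NaN)
    are dropped from the mean, and a fully undetermined triplet raises
    :class:`MissingDataError` (the sample is excluded with a log entry).
    """
    try:
        d_cq = (_triplet_mean(cq_target, f"{sample_id} target")
                - _triplet_mean(cq_reference, f"{sample_id} reference"))
    except MissingDataError:
        log.info("sample %s excluded: all-undetermined Cq triplet", sample_id)
        raise
    fold = 2.0 ** (-d_cq)
    return DensityValue(sample_id=sample_id, metric=metric, fold=fold,
                        log2_fold=math.log2(fold))


def sum_wovirus_variants(per_variant_folds) -> float:
    """Total prophage density: arithmetic sum of per-variant fold-changes.

    Summation happens on the fold scale, before any log transform.
    """
    folds = list(per_variant_folds)
    if not folds:
        raise MissingDataError("no detected variants to sum")
    if any(f <= 0 for f in folds):
        raise ValueError("fold-changes must be positive")
    return float(sum(folds))


def spikein_abundance(conc_target: float, conc_spike: float) -> float:
    """Transcript abundance: target concentration over spike-in concentration.

    A zero target concentration returns 0.0 with a log entry; such values
    cannot be log2-transformed and are excluded from log-scale models
    downstream.
    """
    if conc_spike <= 0:
        raise ValueError("conc_spike must be positive")
    if conc_target < 0:
        raise ValueError("conc_target must be nonnegative")
    if conc_target == 0:
        log.info("zero target concentration; abundance 0 flagged as missing "
                 "for log-scale analyses")
        return 0.0
    return conc_target / conc_spike


# ---------------------------------------------------------------------------
# Table-level drivers
# ---------------------------------------------------------------------------

def densities_from_cq(cq_table: pd.DataFrame,
                      wolbachia_gene: str = "ftsZ",
                      host_gene: str = "host_reference",
                      wovirus_prefix: str = "sr") -> pd.DataFrame:
    """Per-sample relative densities from a tidy Cq table.

    Expects columns sample_id, strain, temperature_c, target, cq1..cq3.
    Produces one row per sample x metric: Wolbachia per host
    (wolbachia_gene vs host_gene), Wovirus per Wolbachia (summed
    serine-recombinase variants vs wolbachia_gene) and Wovirus per host.
    Samples with missing pieces are skipped with a log entry.
    """
    rows = []
    for sid, group in cq_table.groupby("sample_id", sort=True):
        triplets = {r.target: (r.cq1, r.cq2, r.cq3)
                    for r in group.itertuples()}
        meta = group.iloc[0]
        if wolbachia_gene in triplets and host_gene in triplets:
            try:
                dv = cq_to_fold(triplets[wolbachia_gene], triplets[host_gene],
                                sid, "wolbachia_per_host")
                rows.append(_density_row(dv, meta))
            except MissingDataError:
                pass
        variant_folds = []
        for target, trip in triplets.items():
            if target.startswith(wovirus_prefix) and wolbachia_gene in triplets:
                try:
                    dv = cq_to_fold(trip, triplets[wolbachia_gene], sid,
                                    "wovirus_per_wolbachia")
                    variant_folds.append(dv.fold)
                except MissingDataError:
                    pass
        if variant_folds:
            total = sum_wovirus_variants(variant_folds)
            rows.append(_density_row(
                DensityValue(sid, "wovirus_per_wolbachia", total,
                             math.log2(total)), meta))
            # per host = per Wolbachia x Wolbachia per host
            woh = [r for r in rows
                   if r["sample_id"] == sid and r["metric"] == "wolbachia_per_host"]
            if woh:
                per_host = total * woh[0]["fold"]
                rows.append(_density_row(
                    DensityValue(sid, "wovirus_per_host", per_host,
                                 math.log2(per_host)), meta))
    return pd.DataFrame(rows)


def _density_row(dv: DensityValue, meta):
    return dict(sample_id=dv.sample_id, strain=meta.strain,
                temperature_c=float(meta.temperature_c), metric=dv.metric,
                fold=dv.fold, log2_fold=dv.log2_fold)


def abundance_table_from_ddpcr(ddpcr_table: pd.DataFrame) -> pd.DataFrame:
    """Spike-in-normalized log2 transcript abundances from a ddPCR table.

    Expects columns variant, treatment, conc_target, conc_spike.  Wells with
    zero target concentration are excluded (logged), since their abundance
    has no log2 transform.
    """
    rows = []
    for i, r in enumerate(ddpcr_table.itertuples()):
        ab = spikein_abundance(r.conc_target, r.conc_spike)
        if ab == 0.0:
            log.info("ddPCR well %d (%s, %s) excluded: zero target",
                     i, r.variant, r.treatment)
            continue
        rows.append(dict(variant=r.variant, treatment=r.treatment,
                         abundance=ab, value_log2=math.log2(ab)))
    return pd.DataFrame(rows)
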