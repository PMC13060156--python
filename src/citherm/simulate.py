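"""Synthetic data generators for the temperature-sensitive CI pipeline.

Every downstream analysis stage (hatch-count modelling, development-time
permutation inference, qPCR/ddPCR relative quantification, concordance and
phylogenetic regression) consumes tables produced here, so the whole pipeline
is testable without any laboratory data.  The generators draw from the same
stochastic structure the analyses assume:

* hatch counts — zero-inflated binomial with a logit-scale observation-level
  Gaussian deviate (one per egg-lay replicate) absorbing overdispersion;
* development times — a linear thermal trend plus cytotype shift, snapped up
  to an every-other-day monitoring grid;
* qPCR — triplicate Cq values with additive Gaussian noise around a
  sample-level value, the target displaced from the host reference by the
  true log2 density;
* ddPCR — lognormal spike-in and target concentrations whose ratio carries
  the true log2 transcript abundance;
* chronogram — a random ultrametric strain tree with relative root height 1.

A single master seed is expanded into independent per-generator child seeds
via ``numpy.random.SeedSequence`` spawn keys, so adding one generator never
perturbs the streams of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

__all__ = [
    "ExperimentDesign",
    "SimParams",
    "CrossRecord",
    "DevTimeRecord",
    "CqRecord",
    "DdpcrRecord",
    "ConfigurationError",
    "build_design",
    "default_cell_logits",
    "simulate_crosses",
    "simulate_devtimes",
    "simulate_cq",
    "simulate_ddpcr",
    "simulate_chronogram",
    "crosses_frame",
    "devtimes_frame",
    "cq_frame",
    "ddpcr_frame",
]

CROSS_TYPES = ("compatible", "ci", "rescue")

# Fixed spawn keys: one independent child stream per generator.
_STREAMS = {"crosses": 0, "devtimes": 1, "cq": 2, "ddpcr": 3, "chronogram": 4}


class ConfigurationError(ValueError):
    """Raised when a design or parameter set is internally inconsistent."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossRecord:
    """One egg-lay replicate of a strain x temperature x cross-type cell."""

    strain: str
    temperature: float
    cross_type: str
    eggs_total: int
    eggs_hatched: int
    replicate_id: str

    def __post_init__(self):
        if not (0 <= self.eggs_hatched <= self.eggs_total):
            raise ValueError(
                f"{self.replicate_id}: eggs_hatched={self.eggs_hatched} outside "
                f"[0, eggs_total={self.eggs_total}]"
            )


@dataclass(frozen=True)
class DevTimeRecord:
    """Days from egg transfer to first adult emergence in one vial."""

    strain: str
    cytotype: str  # "aposymbiotic" | "symbiotic"
    temperature: float
    emergence_day: int

    def __post_init__(self):
        if self.emergence_day < 1:
            raise ValueError("emergence_day must be >= 1")


@dataclass(frozen=True)
class CqRecord:
    """Triplicate qPCR quantification cycles for one sample x target."""

    sample_id: str
    strain: str
    temperature: float
    target: str
    cq: tuple  # three floats; NaN marks an undetermined well

    def __post_init__(self):
        if len(self.cq) != 3:
            raise ValueError("cq must hold exactly three values")


@dataclass(frozen=True)
class DdpcrRecord:
    """ddPCR target and spike-in concentrations (copies/uL) for one well."""

    variant: str
    treatment: str  # "cool" | "warm"
    conc_target: float
    conc_spike: float

    def __post_init__(self):
        if self.conc_spike <= 0:
            raise ValueError("conc_spike must be positive")
        if self.conc_target < 0:
            raise ValueError("conc_target must be nonnegative")


# ---------------------------------------------------------------------------
# Design and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout of the crossing experiment.

    ``available_cells`` lists the (strain, temperature) pairs actually
    reared; some hosts cannot be reared at every temperature, so the design
    is allowed to be incomplete.
    """

    strains: tuple
    temperatures: tuple
    cross_types: tuple
    replicates_per_cell: int
    available_cells: frozenset  # of (strain, temperature)

    @property
    def cells(self):
        """All available strain x temperature x cross cells, sorted."""
        return [
            (s, t, c)
            for s in self.strains
            for t in self.temperatures
            for c in self.cross_types
            if (s, t) in self.available_cells
        ]

    def strain_temp_cells(self):
        return [
            (s, t)
            for s in self.strains
            for t in self.temperatures
            if (s, t) in self.available_cells
        ]


def build_design(config: dict) -> ExperimentDesign:
    """Validate a design mapping and return an :class:`ExperimentDesign`.

    ``config`` keys: ``strains``, ``temperatures``, ``cross_types``
    (optional, defaults to all three), ``replicates_per_cell`` (optional,
    default 14), ``unavailable_cells`` (optional list of [strain, temp]).
    """
    strains = list(config.get("strains", []))
    temps = [float(t) for t in config.get("temperatures", [])]
    crosses = tuple(config.get("cross_types", CROSS_TYPES))
    reps = int(config.get("replicates_per_cell", 14))

    for name, values in (("strains", strains), ("temperatures", temps),
                         ("cross_types", crosses)):
        if len(values) == 0:
            raise ConfigurationError(f"{name} must be non-empty")
        if len(set(values)) != len(values):
            raise ConfigurationError(f"duplicate labels in {name}")
    unknown = set(crosses) - set(CROSS_TYPES)
    if unknown:
        raise ConfigurationError(f"unknown cross types: {sorted(unknown)}")
    if reps < 1:
        raise ConfigurationError("replicates_per_cell must be >= 1")

    removed = {(s, float(t)) for s, t in config.get("unavailable_cells", [])}
    all_cells = {(s, t) for s in strains for t in temps}
    stray = removed - all_cells
    if stray:
        raise ConfigurationError(f"unavailable_cells not in design: {sorted(stray)}")
    available = frozenset(all_cells - removed)
    if not available:
        raise ConfigurationError("all cells removed; nothing to simulate")
    return ExperimentDesign(
        strains=tuple(strains),
        temperatures=tuple(temps),
        cross_types=crosses,
        replicates_per_cell=reps,
        available_cells=available,
    )


@dataclass
class SimParams:
    """Generating parameters for all five synthetic inputs.

    ``cell_logit_mean`` maps (strain, temperature, cross) to the logit-scale
    hatch probability; ``olre_sigma`` is the SD of the per-replicate
    observation-level deviate and ``zi_prob`` the structural-zero
    probability shared across cells (the hatch model's sigma and pi).
    Egg counts per replicate are negative binomial (mean, dispersion)
    truncated at >= 1.  Development-time, Cq and ddPCR parameters are
    documented in their generators.
    """

    cell_logit_mean: dict = field(default_factory=dict)
    olre_sigma: float = 0.8
    zi_prob: float = 0.05
    egg_count_mean: float = 24.4
    egg_count_dispersion: float = 5.0
    devtime_base: float = 13.0          # days at the 23 C reference
    devtime_temp_slope: float = -1.5    # days per degree C
    devtime_cyto_effect: float = -0.5   # symbiotic minus aposymbiotic, days
    devtime_sd: float = 1.0
    devtime_grid_phase: int = 0         # monitoring-grid day offset
    cq_ref_mean: float = 22.0
    cq_noise_sd: float = 0.2
    ddpcr_log_mean: float = 5.0         # natural-log mean of spike-in conc
    ddpcr_log_sd: float = 0.3
    seed: int = 0

    def validate(self):
        if self.olre_sigma < 0:
            raise ConfigurationError("olre_sigma must be >= 0")
        if not (0.0 <= self.zi_prob <= 1.0):
            raise ConfigurationError("zi_prob must lie in [0, 1]")
        for name in ("egg_count_mean", "egg_count_dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("devtime_sd", "cq_noise_sd", "ddpcr_log_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        return self

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimParams":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown SimParams fields: {sorted(unknown)}")
        params = cls(**mapping)
        params.cell_logit_mean = {
            (s, float(t), c): float(v)
            for (s, t, c), v in params.cell_logit_mean.items()
        } if params.cell_logit_mean else {}
        return params.validate()


def _logit(p):
    return math.log(p / (1.0 - p))


def default_cell_logits(design: ExperimentDesign,
                        ci_profile: dict | None = None) -> dict:
    """Logit hatch probabilities emulating the study conditions.

    Compatible and rescue crosses hatch well (~85%); CI crosses hatch
    according to a per-strain thermal profile: half the strains are
    temperature-sensitive (CI strength shifts by several logits across
    rearing temperatures) and half are temperature-resistant.  ``ci_profile``
    may override the per-strain map (strain -> {temperature: logit}).
    """
    base_comp = _logit(0.85)
    profiles = {}
    temps = sorted(design.temperatures)
    for i, s in enumerate(design.strains):
        if ci_profile and s in ci_profile:
            profiles[s] = {float(t): v for t, v in ci_profile[s].items()}
        elif i % 2 == 0:  # temperature-sensitive: weak CI at warm extreme
            profiles[s] = {
                t: -5.0 + 4.5 * j / max(1, len(temps) - 1)
                for j, t in enumerate(temps)
            }
        else:             # temperature-resistant: uniformly strong CI
            profiles[s] = {t: -4.0 for t in temps}
    out = {}
    for s, t, c in design.cells:
        if c == "compatible":
            out[(s, t, c)] = base_comp
        elif c == "rescue":
            out[(s, t, c)] = base_comp - 0.1
        else:
            out[(s, t, c)] = profiles[s][t]
    return out


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _truncated_negbin(rng, mean, dispersion, size):
    """Negative binomial (mean/dispersion parameterized) truncated at >= 1."""
    p = dispersion / (dispersion + mean)
    draws = rng.negative_binomial(dispersion, p, size=size)
    while True:
        zero = draws == 0
        if not zero.any():
            return draws
        draws[zero] = rng.negative_binomial(dispersion, p, size=int(zero.sum()))


def simulate_crosses(design: ExperimentDesign, params: SimParams) -> list:
    """Draw zero-inflated overdispersed hatch counts for every replicate.

    For each replicate: eggs_total ~ truncated NegBin; with probability pi
    the replicate is a structural zero; otherwise a per-replicate deviate
    u ~ Normal(0, sigma^2) shifts the cell's logit mean and hatched eggs are
    binomial at the resulting probability.
    """
    params.validate()
    rng = _rng(params.seed, "crosses")
    missing = [cell for cell in design.cells if cell not in params.cell_logit_mean]
    if missing:
        raise ConfigurationError(
            f"cell_logit_mean missing for {len(missing)} cells, e.g. {missing[:3]}"
        )
    records = []
    for s, t, c in design.cells:
        eta0 = params.cell_logit_mean[(s, t, c)]
        n_rep = design.replicates_per_cell
        totals = _truncated_negbin(rng, params.egg_count_mean,
                                   params.egg_count_dispersion, n_rep)
        zeros = rng.random(n_rep) < params.zi_prob
        u = rng.normal(0.0, params.olre_sigma, n_rep)
        probs = 1.0 / (1.0 + np.exp(-(eta0 + u)))
        hatched = rng.binomial(totals, probs)
        hatched[zeros] = 0
        for r in range(n_rep):
            records.append(CrossRecord(
                strain=s, temperature=t, cross_type=c,
                eggs_total=int(totals[r]), eggs_hatched=int(hatched[r]),
                replicate_id=f"{s}_{t:g}_{c}_{r + 1}",
            ))
    return records


def _snap_up(latent, phase):
    """Snap a latent emergence time UP to the every-other-day check grid."""
    day = phase + 2.0 * np.ceil((latent - phase) / 2.0)
    return np.maximum(day, max(1, phase if phase >= 1 else phase + 2)).astype(int)


def simulate_devtimes(design: ExperimentDesign, params: SimParams,
                      vials_per_cell: int = 8) -> list:
    """Draw first-emergence days for both cytotypes of every reared cell.

    Latent time = base + slope*(T - 23) + cyto_effect*[symbiotic] + noise,
    snapped up to the next monitored day (vials checked every other day).
    """
    params.validate()
    rng = _rng(params.seed, "devtimes")
    ref = 23.0
    records = []
    for s, t in design.strain_temp_cells():
        for cyto in ("aposymbiotic", "symbiotic"):
            mu = (params.devtime_base
                  + params.devtime_temp_slope * (t - ref)
                  + (params.devtime_cyto_effect if cyto == "symbiotic" else 0.0))
            latent = mu + rng.normal(0.0, params.devtime_sd, vials_per_cell)
            days = _snap_up(latent, params.devtime_grid_phase)
            for d in days:
                records.append(DevTimeRecord(
                    strain=s, cytotype=cyto, temperature=t,
                    emergence_day=int(max(1, d)),
                ))
    return records


def simulate_cq(design: ExperimentDesign, params: SimParams,
                true_log2: dict, samples_per_cell: int = 3,
                undetermined_above: float | None = None) -> list:
    """Draw triplicate Cq values for the host reference and each target.

    ``true_log2`` maps (strain, temperature, target) to the true log2
    density of that target relative to the host reference.  Per sample the
    reference Cq is Normal(cq_ref_mean, cq_noise_sd^2); each target's
    sample-level Cq is the reference minus its true log2 density plus the
    same noise; the three replicate wells add independent noise around the
    sample value.  Wells above ``undetermined_above`` (if set) are flagged
    undetermined (NaN).
    """
    params.validate()
    rng = _rng(params.seed, "cq")
    targets = sorted({k[2] for k in true_log2})
    records = []
    for s, t in design.strain_temp_cells():
        cell_targets = [g for g in targets if (s, t, g) in true_log2]
        if not cell_targets:
            continue
        for i in range(samples_per_cell):
            sid = f"{s}_{t:g}_s{i + 1}"
            ref_cq = rng.normal(params.cq_ref_mean, params.cq_noise_sd)
            trip = ref_cq + rng.normal(0.0, params.cq_noise_sd, 3)
            records.append(CqRecord(sid, s, t, "host_reference",
                                    tuple(_censor(trip, undetermined_above))))
            for g in cell_targets:
                mu = ref_cq - true_log2[(s, t, g)] \
                    + rng.normal(0.0, params.cq_noise_sd)
                trip = mu + rng.normal(0.0, params.cq_noise_sd, 3)
                records.append(CqRecord(sid, s, t, g,
                                        tuple(_censor(trip, undetermined_above))))
    return records


def _censor(values, cutoff):
    if cutoff is None:
        return [float(v) for v in values]
    return [float("nan") if v > cutoff else float(v) for v in values]


def simulate_ddpcr(design: ExperimentDesign, params: SimParams,
                   true_log2: dict, replicates: int = 10) -> list:
    """Draw ddPCR target/spike-in concentration pairs per variant x treatment.

    ``true_log2`` maps (variant, treatment) to the true log2 abundance of
    the target relative to the spike-in.  Spike-in concentrations are
    lognormal; the target multiplies the spike-in by 2^abundance and an
    independent lognormal noise factor.
    """
    params.validate()
    rng = _rng(params.seed, "ddpcr")
    records = []
    for (variant, treatment), ab in sorted(true_log2.items()):
        spikes = rng.lognormal(params.ddpcr_log_mean, params.ddpcr_log_sd,
                               replicates)
        noise = rng.lognormal(0.0, params.ddpcr_log_sd, replicates)
        targets = spikes * (2.0 ** ab) * noise
        for k in range(replicates):
            records.append(DdpcrRecord(variant, treatment,
                                       float(targets[k]), float(spikes[k])))
    return records


def simulate_chronogram(strains, seed: int) -> str:
    """Random ultrametric strain tree, relative root height 1, as newick.

    Built by a coalescent-style sequence of random pairwise merges with
    increasing node heights, then rescaled so every root-to-tip path is
    exactly 1.
    """
    strains = list(strains)
    if len(strains) < 2:
        raise ConfigurationError("need at least 2 strains for a chronogram")
    if len(set(strains)) != len(strains):
        raise ConfigurationError("duplicate strain labels")
    rng = _rng(seed, "chronogram")
    # Each lineage: (newick fragment, height of its root above the tips).
    lineages = [(s, 0.0) for s in strains]
    height = 0.0
    while len(lineages) > 1:
        height += rng.exponential(1.0 / len(lineages))
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (nwk_j, h_j) = lineages.pop(j)
        (nwk_i, h_i) = lineages.pop(i)
        merged = f"({nwk_i}:{height - h_i:.10f},{nwk_j}:{height - h_j:.10f})"
        lineages.append((merged, height))
    nwk, root_h = lineages[0]
    # Rescale all branch lengths so the root height is exactly 1.
    import re
    def _scale(match):
        return f":{float(match.group(1)) / root_h:.10f}"
    return re.sub(r":([0-9.eE+-]+)", _scale, nwk) + ";"


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def crosses_frame(records) -> pd.DataFrame:
    return pd.DataFrame([
        dict(strain=r.strain, temperature_c=r.temperature,
             cross_type=r.cross_type, eggs_total=r.eggs_total,
             eggs_hatched=r.eggs_hatched, replicate_id=r.replicate_id)
        for r in records
    ])


def devtimes_frame(records) -> pd.DataFrame:
    return pd.DataFrame([
        dict(strain=r.strain, cytotype=r.cytotype,
             temperature_c=r.temperature, emergence_day=r.emergence_day)
        for r in records
    ])


def cq_frame(records) -> pd.DataFrame:
    return pd.DataFrame([
        dict(sample_id=r.sample_id, strain=r.strain,
             temperature_c=r.temperature, target=r.target,
             cq1=r.cq[0], cq2=r.cq[1], cq3=r.cq[2])
        for r in records
    ])


def ddpcr_frame(records) -> pd.DataFrame:
    return pd.DataFrame([
        dict(variant=r.variant, treatment=r.treatment,
             conc_target=r.conc_target, conc_spike=r.conc_spike)
        for r in records
    ])
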