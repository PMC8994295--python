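"""Synthetic cohorts with somatic repeat mosaicism, stutter and dilution.

The generator emulates the data-generating process behind a somatic
tandem-repeat instability study of an expanded hexameric (6 bp) repeat:

* individuals inherit a repeat length (default ~N(41.6, 3.9) rounded,
  clipped to 30-55 units) and an age at onset that falls linearly with
  repeat length plus Gaussian noise;
* each tissue has an expansion propensity that grows linearly with the
  inherited length above a reference of 30 units, producing per-cell length
  changes drawn from a point mass at zero, geometric expansion and
  contraction tails, and a rare large-jump component (|delta| >= 20 units);
* bulk PCR + capillary electrophoresis convolves the cell-level allele
  distribution with a geometric stutter ladder (mostly one unit short), a
  short-allele amplification advantage, and multiplicative log-normal
  peak-height noise, on a 6 bp/repeat size ladder;
* small-pool PCR wells draw a Poisson number of template molecules; wells
  with none are product-negative, and no-DNA controls are always negative.

All randomness flows through explicit seeds or numpy Generators; identical
seeds give identical outputs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml

from .traceio import (
    AlleleDistribution,
    PeakTable,
    SizeCalibration,
    default_calibration,
)
from .smolecule import Plate, PlateSet, Well

__all__ = [
    "TissueProfile",
    "StutterModel",
    "Individual",
    "CohortConfig",
    "REFERENCE_REPEAT",
    "default_tissue_profiles",
    "simulate_cohort",
    "simulate_somatic_distribution",
    "simulate_trace",
    "simulate_dilution_series",
    "noise_sd_for_r_squared",
    "write_cohort_csv",
    "write_ground_truth_yaml",
]

#: repeat length below which no length-dependent expansion occurs
REFERENCE_REPEAT = 30

#: minimum credible age at onset (years) for truncation
MIN_AAO_YEARS = 12.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TissueProfile:
    """Tissue-specific somatic mutation propensities.

    ``expansion_rate_per_unit`` is the per-cell probability of carrying an
    expanded allele *per repeat unit of inherited length above the reference
    of 30 units* — length dependence is linear in (inherited - 30).
    ``contraction_rate`` is a length-independent per-cell contraction
    probability.  Tail parameters are geometric decay factors in (0, 1) for
    the magnitude of the change (decay q means P(|delta| = k) ~ q^(k-1)).
    ``rare_large_event_rate`` is the per-cell probability of a jump of 20 or
    more units; such jumps are expansion-biased (see
    ``rare_expansion_share``).  ``block`` tags the anatomical class
    ("cortical" / "subcortical" / "blood") used for correlated
    individual-level effects.
    """

    tissue_name: str
    expansion_rate_per_unit: float
    contraction_rate: float
    expansion_tail: float = 0.55
    contraction_tail: float = 0.40
    rare_large_event_rate: float = 0.0
    rare_expansion_share: float = 0.7
    block: str = ""

    def __post_init__(self) -> None:
        for name in ("expansion_rate_per_unit", "contraction_rate",
                     "rare_large_event_rate", "rare_expansion_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("expansion_tail", "contraction_tail"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    def expansion_probability(self, inherited_repeat: int) -> float:
        """Per-cell expansion probability at a given inherited length."""
        p = self.expansion_rate_per_unit * (inherited_repeat - REFERENCE_REPEAT)
        if p < 0:
            warnings.warn(
                f"{self.tissue_name}: inherited repeat {inherited_repeat} below the "
                f"reference of {REFERENCE_REPEAT}; expansion probability clamped to 0",
                stacklevel=2,
            )
            return 0.0
        return min(p, 1.0)

    def scaled(self, factor: float) -> "TissueProfile":
        """Profile with the expansion propensity multiplied by ``factor``
        (used for per-individual random effects)."""
        return TissueProfile(
            tissue_name=self.tissue_name,
            expansion_rate_per_unit=min(self.expansion_rate_per_unit * factor, 1.0),
            contraction_rate=self.contraction_rate,
            expansion_tail=self.expansion_tail,
            contraction_tail=self.contraction_tail,
            rare_large_event_rate=self.rare_large_event_rate,
            rare_expansion_share=self.rare_expansion_share,
            block=self.block,
        )


@dataclass(frozen=True)
class StutterModel:
    """PCR slippage model for the electropherogram simulator.

    Each template allele seeds a geometric ladder: the peak k units below it
    has relative height ``minus_stutter_rate ** k`` (slippage is mostly
    contraction-biased), and k units above ``plus_stutter_rate ** k``.
    ``short_allele_amplification_bias`` >= 1 is the multiplicative PCR
    efficiency gain per repeat unit *shorter* than the modal allele — shorter
    templates amplify better, the bulk-PCR contraction bias.
    """

    minus_stutter_rate: float = 0.15
    plus_stutter_rate: float = 0.02
    short_allele_amplification_bias: float = 1.02

    def __post_init__(self) -> None:
        for name in ("minus_stutter_rate", "plus_stutter_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.short_allele_amplification_bias < 1.0:
            raise ValueError("short_allele_amplification_bias must be >= 1 "
                             "(shorter templates amplify at least as well)")


@dataclass(frozen=True)
class Individual:
    """A simulated subject with ground-truth somatic allele distributions."""

    individual_id: str
    inherited_repeat: int
    aao: float
    aad: float | None
    tissue_distributions: Mapping[str, AlleleDistribution] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.aad is not None and self.aad < self.aao:
            raise ValueError("age at death must be >= age at onset")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator settings.

    Defaults encode the study conditions the generator emulates: AAO falls by
    1.4 years per inherited repeat unit from an intercept of 100 years with
    6 years of Gaussian noise (about 45% of AAO variance explained at a
    repeat SD of 3.9), inherited repeats are drawn around 41.6 +/- 3.9 units
    clipped to 30-55, onset is truncated at 12 years, and disease duration is
    drawn independently of repeat length (mean 9, SD 4 years).
    ``individual_effect_cv`` / ``block_effect_cv`` set log-normal
    multiplicative random effects on expansion propensity shared across all
    tissues of an individual and across tissues of one anatomical block,
    respectively.
    """

    n_individuals: int
    seed: int
    aao_intercept: float = 100.0
    aao_slope: float = -1.4
    aao_noise_sd: float = 6.0
    repeat_range: tuple[int, int] = (30, 55)
    repeat_mean: float = 41.6
    repeat_sd: float = 3.9
    min_aao: float = MIN_AAO_YEARS
    duration_mean: float = 9.0
    duration_sd: float = 4.0
    n_cells: int = 300
    individual_effect_cv: float = 0.25
    block_effect_cv: float = 0.25

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.aao_slope >= 0:
            raise ValueError("aao_slope must be negative (longer repeat, earlier onset)")
        if self.aao_noise_sd < 0:
            raise ValueError("aao_noise_sd must be non-negative")
        lo, hi = self.repeat_range
        if lo >= hi:
            raise ValueError("repeat_range must be (low, high) with low < high")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def noise_sd_for_r_squared(slope: float, predictor_sd: float, r_squared: float) -> float:
    """Residual SD giving a population R^2 for a simple linear model.

    R^2 = b^2 s_x^2 / (b^2 s_x^2 + sigma^2)  =>  sigma = |b| s_x sqrt((1-R^2)/R^2).
    """
    if not 0.0 < r_squared < 1.0:
        raise ValueError("r_squared must be in (0, 1)")
    return abs(slope) * predictor_sd * np.sqrt((1.0 - r_squared) / r_squared)


def default_tissue_profiles() -> list[TissueProfile]:
    """Default tissue panel ordered by expansion propensity.

    Blood is the most stable tissue, cerebellum the most stable brain region,
    and cortical regions (cingulate gyrus, frontal BA9, occipital cortex) the
    least stable, mirroring the tissue ordering seen in somatic-instability
    surveys of expanded repeats.  Rates are per-cell probabilities per
    repeat unit above 30 (see :class:`TissueProfile`).
    """
    return [
        TissueProfile("blood", 0.016, 0.05, 0.45, 0.40, 0.0005, block="blood"),
        TissueProfile("cerebellum", 0.036, 0.10, 0.62, 0.40, 0.002, block="subcortical"),
        TissueProfile("caudate", 0.040, 0.12, 0.65, 0.40, 0.004, block="subcortical"),
        TissueProfile("putamen", 0.042, 0.12, 0.66, 0.40, 0.004, block="subcortical"),
        TissueProfile("hippocampus", 0.043, 0.12, 0.67, 0.40, 0.004, block="subcortical"),
        TissueProfile("cingulate_gyrus", 0.044, 0.12, 0.69, 0.40, 0.005, block="cortical"),
        TissueProfile("frontal_ba9", 0.045, 0.12, 0.70, 0.40, 0.005, block="cortical"),
        TissueProfile("occipital_cortex", 0.047, 0.12, 0.73, 0.40, 0.006, block="cortical"),
    ]


def simulate_somatic_distribution(
    inherited: int,
    profile: TissueProfile,
    n_cells: int,
    seed,
    locus: str = "XDP",
) -> AlleleDistribution:
    """Draw per-cell repeat lengths for one tissue of one individual.

    Each cell's change from the inherited allele is 0, +Geom, -Geom, or a
    rare large jump (|delta| >= 20, expansion-biased).  Counts sum to
    ``n_cells``; repeats are floored at 1 unit.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = _as_rng(seed)
    p_exp = profile.expansion_probability(inherited)
    p_con = profile.contraction_rate
    p_rare = profile.rare_large_event_rate
    # linear length dependence saturates once every cell carries a change
    p_exp = min(p_exp, 1.0 - p_con - p_rare)
    total = p_exp + p_con + p_rare
    n_rare, n_exp, n_con, n_stay = rng.multinomial(
        n_cells, [p_rare, p_exp, p_con, 1.0 - total]
    )
    deltas = np.zeros(n_cells, dtype=np.int64)
    i = 0
    if n_rare:
        mags = 20 + rng.geometric(0.04, size=n_rare) - 1
        signs = np.where(rng.random(n_rare) < profile.rare_expansion_share, 1, -1)
        deltas[i:i + n_rare] = signs * mags
        i += n_rare
    if n_exp:
        deltas[i:i + n_exp] = rng.geometric(1.0 - profile.expansion_tail, size=n_exp)
        i += n_exp
    if n_con:
        deltas[i:i + n_con] = -rng.geometric(1.0 - profile.contraction_tail, size=n_con)
        i += n_con
    repeats = np.maximum(inherited + deltas, 1)
    values, counts = np.unique(repeats, return_counts=True)
    entries = {int(v): float(c) for v, c in zip(values, counts)}
    return AlleleDistribution.from_entries(locus, entries)


def simulate_trace(
    dist: AlleleDistribution,
    stutter: StutterModel,
    calib: SizeCalibration | None = None,
    seed=None,
    sample_id: str = "sim",
    height_cv: float = 0.1,
    modal_height: float = 8000.0,
    min_rel_height: float = 1e-4,
) -> PeakTable:
    """Render a cell-level allele distribution as an electropherogram.

    Every true allele contributes a geometric stutter ladder; ladders are
    summed across alleles, scaled by the short-allele amplification
    advantage, jittered with multiplicative log-normal noise of coefficient
    of variation ``height_cv``, and placed on the calibration's bp ladder so
    adjacent single-unit peaks sit exactly one repeat unit (6 bp) apart.
    Peaks below ``min_rel_height`` of the maximum are dropped.
    """
    if not dist.entries:
        raise ValueError("empty allele distribution")
    calib = calib or default_calibration()
    rng = _as_rng(seed)
    bias = stutter.short_allele_amplification_bias
    heights: dict[int, float] = {}
    # ladder extent: far enough that the geometric tail is below the floor
    def _extent(rate: float) -> int:
        if rate <= 0.0:
            return 0
        return max(1, int(np.ceil(np.log(min_rel_height) / np.log(rate))))

    k_minus = _extent(stutter.minus_stutter_rate)
    k_plus = _extent(stutter.plus_stutter_rate)
    for allele, weight in dist.entries.items():
        w = weight * bias ** (dist.modal_repeat - allele)
        heights[allele] = heights.get(allele, 0.0) + w
        for k in range(1, k_minus + 1):
            r = allele - k
            if r < 1:
                break
            heights[r] = heights.get(r, 0.0) + w * stutter.minus_stutter_rate ** k
        for k in range(1, k_plus + 1):
            heights[allele + k] = heights.get(allele + k, 0.0) + w * stutter.plus_stutter_rate ** k
    repeats = np.array(sorted(heights), dtype=int)
    h = np.array([heights[r] for r in repeats], dtype=float)
    if height_cv > 0:
        sigma = np.sqrt(np.log1p(height_cv**2))
        h = h * rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=h.size)
    h = h * (modal_height / h.max())
    keep = h >= min_rel_height * h.max()
    repeats, h = repeats[keep], h[keep]
    peaks = tuple(
        (calib.repeats_to_bp(int(r)), float(height)) for r, height in zip(repeats, h)
    )
    return PeakTable(sample_id=sample_id, locus=dist.locus, peaks=peaks)


def simulate_cohort(
    config: CohortConfig, profiles: Sequence[TissueProfile]
) -> list[Individual]:
    """Simulate a cohort of individuals with ground-truth tissue distributions.

    AAO = intercept + slope * inherited_repeat + N(0, noise_sd), truncated at
    ``config.min_aao``; AAD = AAO + an independently drawn duration.  Each
    tissue's cell-level allele distribution is generated under the tissue
    profile scaled by per-individual and per-block log-normal random
    effects.  Deterministic given ``config.seed``.
    """
    if not profiles:
        raise ValueError("need at least one tissue profile")
    names = [p.tissue_name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("tissue names must be unique")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.repeat_range

    def _lognormal_factor(cv: float) -> float:
        if cv <= 0:
            return 1.0
        sigma = np.sqrt(np.log1p(cv**2))
        return float(rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma))

    individuals = []
    blocks = sorted({p.block for p in profiles})
    for i in range(config.n_individuals):
        repeat = int(np.clip(round(rng.normal(config.repeat_mean, config.repeat_sd)), lo, hi))
        aao = config.aao_intercept + config.aao_slope * repeat
        if config.aao_noise_sd > 0:
            aao += rng.normal(0.0, config.aao_noise_sd)
        aao = max(aao, config.min_aao)
        duration = max(rng.normal(config.duration_mean, config.duration_sd), 0.5)
        aad = aao + duration
        g_i = _lognormal_factor(config.individual_effect_cv)
        b_i = {b: _lognormal_factor(config.block_effect_cv) for b in blocks}
        dists = {}
        for prof in profiles:
            scaled = prof.scaled(g_i * b_i[prof.block])
            dists[prof.tissue_name] = simulate_somatic_distribution(
                repeat, scaled, config.n_cells, rng
            )
        individuals.append(
            Individual(
                individual_id=f"sim-{i + 1:03d}",
                inherited_repeat=repeat,
                aao=float(aao),
                aad=float(aad),
                tissue_distributions=dists,
            )
        )
    return individuals


def simulate_dilution_series(
    dist: AlleleDistribution,
    mean_molecules_per_well: Sequence[float],
    wells_per_dilution: int = 72,
    seed=None,
    n_no_dna: int = 18,
    sizing_standards: Sequence[int] = (37, 44, 50),
    positive_height_mean: float = 1500.0,
    positive_height_cv: float = 0.3,
    sample_id: str = "",
    tissue: str = "",
) -> PlateSet:
    """Simulate a Poisson titration series of SP-PCR plates.

    One plate per mean in ``mean_molecules_per_well``; each DNA well draws
    Poisson(mean) template molecules from ``dist`` (weights as sampling
    probabilities).  Empty wells are product-negative; wells with several
    molecules report the shortest one (short templates win the amplification
    race).  Each plate also carries ``n_no_dna`` always-negative controls,
    the repeat sizing standards, and one empty machine-control well.
    """
    if wells_per_dilution <= 0:
        raise ValueError("wells_per_dilution must be positive")
    means = [float(m) for m in mean_molecules_per_well]
    if not means:
        raise ValueError("need at least one dilution mean")
    if any(m <= 0 for m in means):
        raise ValueError("mean molecules per well must be > 0")
    rng = _as_rng(seed)
    alleles = np.array(sorted(dist.entries), dtype=int)
    weights = np.array([dist.entries[a] for a in alleles], dtype=float)
    probs = weights / weights.sum()
    hsigma = np.sqrt(np.log1p(positive_height_cv**2))
    plates = []
    for d, mean in enumerate(means):
        wells = []
        n_mol = rng.poisson(mean, size=wells_per_dilution)
        for j, k in enumerate(n_mol):
            wid = f"D{d + 1}-{j + 1:02d}"
            if k == 0:
                wells.append(Well(wid, "dna"))
                continue
            drawn = tuple(int(a) for a in rng.choice(alleles, size=int(k), p=probs))
            called = min(drawn)
            height = float(positive_height_mean * rng.lognormal(-hsigma**2 / 2.0, hsigma))
            height = max(height, 150.0)
            wells.append(Well(wid, "dna", called, height, true_molecules=drawn))
        for j in range(n_no_dna):
            wells.append(Well(f"D{d + 1}-N{j + 1:02d}", "no_dna_control"))
        for s in sizing_standards:
            wells.append(Well(f"D{d + 1}-S{s}", "sizing_standard", int(s), 3000.0))
        wells.append(Well(f"D{d + 1}-MC", "machine_control"))
        plates.append(
            Plate(
                plate_id=f"plate-{d + 1}",
                dilution_id=f"d{d + 1}",
                wells=tuple(wells),
                mean_molecules=mean,
            )
        )
    return PlateSet(tuple(plates), sample_id=sample_id, tissue=tissue)


# ---------------------------------------------------------------------------
# fixture writers
# ---------------------------------------------------------------------------

def write_cohort_csv(individuals: Sequence[Individual], path) -> None:
    """Cohort metadata CSV: individual_id, tissue, inherited repeat, AAO, AAD."""
    import pandas as pd

    rows = []
    for ind in individuals:
        tissues = ind.tissue_distributions or {"": None}
        for tissue in tissues:
            rows.append(
                {
                    "individual_id": ind.individual_id,
                    "tissue": tissue,
                    "inherited_repeat": ind.inherited_repeat,
                    "aao": ind.aao,
                    "aad": "" if ind.aad is None else ind.aad,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ground_truth_yaml(
    config: CohortConfig,
    profiles: Sequence[TissueProfile],
    path,
    stutter: StutterModel | None = None,
) -> None:
    """Sidecar with every generator parameter, for provenance of fixtures."""
    payload = {
        "cohort_config": asdict(config),
        "tissue_profiles": [asdict(p) for p in profiles],
    }
    payload["cohort_config"]["repeat_range"] = list(config.repeat_range)
    if stutter is not None:
        payload["stutter_model"] = asdict(stutter)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
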