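"""Single-molecule small-pool PCR (SP-PCR) analytics.

At limiting dilution the number of amplifiable template molecules per well is
Poisson distributed, so the fraction of product-negative wells estimates the
mean input: lambda = -ln(P(no product)).  Titration targets ~1/3 negative
wells (lambda ~ ln 3 ~ 1.1), at which point most positive wells contain a
single molecule and each sized product reports one cell's repeat length.

This module estimates lambda with a Clopper-Pearson interval, selects the
single-molecule dilution from a titration series, applies plate QC (clean
no-DNA controls, >= 1/3 negative DNA wells, minimum sized-peak height),
classifies sized alleles against the modal repeat, and compares
contracted/modal/expanded class counts across tissues with a Pearson
chi-square test.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .traceio import SizeCalibration, modal_allele

__all__ = [
    "Well",
    "Plate",
    "PlateSet",
    "MoleculeCountEstimate",
    "ClassCounts",
    "QCResult",
    "Chi2Result",
    "SampleSummary",
    "INPUT_CLASSES",
    "estimate_lambda",
    "estimate_lambda_from_plate",
    "select_single_molecule_dilution",
    "qc_plate",
    "tabulate_alleles",
    "chi_square_independence",
    "compare_class_counts",
    "summarize_sample",
    "read_plate_csv",
    "write_plate_csv",
]

INPUT_CLASSES = ("dna", "no_dna_control", "sizing_standard", "machine_control")

#: minimum peak height (RFU) for a well's product to be sized
MIN_SIZED_HEIGHT = 150.0

#: titration target: fraction of DNA wells with no product
TARGET_NEGATIVE_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class Well:
    """One PCR well: input class, called repeat length (None = no product)."""

    well_id: str
    input_class: str
    repeat: int | None = None
    height: float | None = None
    true_molecules: tuple[int, ...] = ()  # ground truth when simulated

    def __post_init__(self) -> None:
        if self.input_class not in INPUT_CLASSES:
            raise ValueError(f"unknown input_class {self.input_class!r}")

    @property
    def is_positive(self) -> bool:
        return self.repeat is not None


@dataclass(frozen=True)
class Plate:
    """One 96-well SP-PCR plate at a single dilution."""

    plate_id: str
    dilution_id: str
    wells: tuple[Well, ...]
    mean_molecules: float | None = None  # ground truth when simulated

    def wells_of(self, input_class: str) -> list[Well]:
        return [w for w in self.wells if w.input_class == input_class]

    @property
    def dna_wells(self) -> list[Well]:
        return self.wells_of("dna")

    @property
    def n_negative_dna(self) -> int:
        return sum(1 for w in self.dna_wells if not w.is_positive)

    def sized_repeats(self) -> list[int]:
        return [w.repeat for w in self.dna_wells if w.repeat is not None]


@dataclass(frozen=True)
class PlateSet:
    """A titration series / replicate set of SP-PCR plates for one sample."""

    plates: tuple[Plate, ...]
    sample_id: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        if not self.plates:
            raise ValueError("PlateSet requires at least one plate")

    def by_dilution(self) -> dict[str, list[Plate]]:
        out: dict[str, list[Plate]] = {}
        for p in self.plates:
            out.setdefault(p.dilution_id, []).append(p)
        return out

    def sized_repeats(self) -> list[int]:
        return [r for p in self.plates for r in p.sized_repeats()]


@dataclass(frozen=True)
class MoleculeCountEstimate:
    """Poisson estimate of mean amplifiable molecules per well."""

    lambda_hat: float | None
    ci_low: float
    ci_high: float
    n_wells: int
    n_negative: int
    too_concentrated: bool = False

    def covers(self, true_lambda: float) -> bool:
        return (not self.too_concentrated) and self.ci_low <= true_lambda <= self.ci_high


def estimate_lambda(n_wells: int, n_negative: int, confidence: float = 0.95) -> MoleculeCountEstimate:
    """Poisson titration estimate: lambda_hat = -ln(n_negative / n_wells).

    The confidence interval is a Clopper-Pearson (exact binomial) interval on
    the negative-well probability, transformed through -ln.  With zero
    negative wells the input is too concentrated for single-molecule work and
    the estimate is flagged rather than reported as a number.
    """
    if n_wells <= 0:
        raise ValueError("n_wells must be positive")
    if not 0 <= n_negative <= n_wells:
        raise ValueError("n_negative must lie in [0, n_wells]")
    alpha = 1.0 - confidence
    k, n = n_negative, n_wells
    # Clopper-Pearson bounds on P(no product)
    p_low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    p_high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    lam_low = -math.log(p_high)
    lam_high = math.inf if p_low == 0.0 else -math.log(p_low)
    if k == 0:
        return MoleculeCountEstimate(
            lambda_hat=None, ci_low=lam_low, ci_high=lam_high,
            n_wells=n, n_negative=k, too_concentrated=True,
        )
    return MoleculeCountEstimate(
        lambda_hat=-math.log(k / n), ci_low=lam_low, ci_high=lam_high,
        n_wells=n, n_negative=k,
    )


def estimate_lambda_from_plate(plate: Plate, confidence: float = 0.95) -> MoleculeCountEstimate:
    dna = plate.dna_wells
    if not dna:
        raise ValueError(f"plate {plate.plate_id} has no DNA wells")
    return estimate_lambda(len(dna), plate.n_negative_dna, confidence)


def select_single_molecule_dilution(
    series: PlateSet, target_fraction: float = TARGET_NEGATIVE_FRACTION
) -> str:
    """Pick the dilution whose negative-well fraction is nearest the target.

    Requires at least two dilutions with DNA wells.  Ties go to the more
    dilute member (higher negative fraction).  If every dilution is fully
    positive or fully negative the titration failed.
    """
    fractions: dict[str, float] = {}
    for dil, plates in series.by_dilution().items():
        n = sum(len(p.dna_wells) for p in plates)
        if n == 0:
            continue
        neg = sum(p.n_negative_dna for p in plates)
        fractions[dil] = neg / n
    if len(fractions) < 2:
        raise ValueError("need at least 2 dilutions with DNA wells to titrate")
    usable = {d: f for d, f in fractions.items() if 0.0 < f < 1.0}
    if not usable:
        raise ValueError(
            "titration failed: every dilution is fully positive or fully negative"
        )
    # nearest to target; tie -> more dilute (higher negative fraction).
    # distances rounded so equal-by-construction fractions tie despite
    # floating-point representation
    return min(usable, key=lambda d: (round(abs(usable[d] - target_fraction), 12),
                                      -usable[d]))


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: tuple[str, ...] = ()


def qc_plate(
    plate: Plate,
    min_negative_fraction: float = TARGET_NEGATIVE_FRACTION,
    min_height: float = MIN_SIZED_HEIGHT,
) -> QCResult:
    """Plate QC: clean no-DNA controls, enough negative DNA wells, height rule.

    Never raises; failures are enumerated as reasons: ``control_positive``
    (a no-DNA well amplified), ``too_concentrated`` (fewer than 1/3 of DNA
    wells negative, so multi-molecule wells are likely), ``low_peak_height``
    (a sized well below the minimum height).
    """
    reasons: list[str] = []
    if any(w.is_positive for w in plate.wells_of("no_dna_control")):
        reasons.append("control_positive")
    dna = plate.dna_wells
    if dna and plate.n_negative_dna < min_negative_fraction * len(dna):
        reasons.append("too_concentrated")
    for w in dna:
        if w.is_positive and w.height is not None and w.height < min_height:
            reasons.append("low_peak_height")
            break
    return QCResult(passed=not reasons, reasons=tuple(reasons))


@dataclass(frozen=True)
class ClassCounts:
    """Counts of sized single-molecule alleles classified against a modal
    reference, with magnitude bins (|delta| in 1-4, >=5, >=20) on each side.

    The >=20 bin is a subset of the >=5 bin; class counts sum to n_total.
    """

    modal_reference: int
    n_contracted: int
    n_modal: int
    n_expanded: int
    expanded_1_4: int
    expanded_ge5: int
    expanded_ge20: int
    contracted_1_4: int
    contracted_ge5: int
    contracted_ge20: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_expanded != self.expanded_1_4 + self.expanded_ge5:
            raise ValueError("expansion magnitude bins do not sum to n_expanded")
        if self.n_contracted != self.contracted_1_4 + self.contracted_ge5:
            raise ValueError("contraction magnitude bins do not sum to n_contracted")
        if self.expanded_ge20 > self.expanded_ge5 or self.contracted_ge20 > self.contracted_ge5:
            raise ValueError(">=20 bin must nest within >=5 bin")

    @property
    def n_total(self) -> int:
        return self.n_contracted + self.n_modal + self.n_expanded

    @property
    def fraction_deviating(self) -> float:
        return (self.n_contracted + self.n_expanded) / self.n_total

    def as_row(self) -> list[int]:
        """(contracted, modal, expanded) row for contingency analysis."""
        return [self.n_contracted, self.n_modal, self.n_expanded]


def tabulate_alleles(
    plates: PlateSet | Plate | Sequence[int],
    modal_reference: int | None = None,
    label: str = "",
) -> ClassCounts:
    """Classify sized single-molecule alleles against the modal repeat.

    ``modal_reference`` defaults to the SP-PCR modal allele (most frequent
    sized length, ties to the smaller); pass the bulk-genotyping modal to use
    that convention instead.
    """
    if isinstance(plates, Plate):
        repeats = plates.sized_repeats()
    elif isinstance(plates, PlateSet):
        repeats = plates.sized_repeats()
    else:
        repeats = [int(r) for r in plates]
    if not repeats:
        raise ValueError("no sized wells to tabulate")
    if modal_reference is None:
        counts: dict[int, float] = {}
        for r in repeats:
            counts[r] = counts.get(r, 0) + 1
        modal_reference = modal_allele(counts)
    deltas = [r - modal_reference for r in repeats]

    def side(d_list: list[int]) -> tuple[int, int, int, int]:
        n = len(d_list)
        ge5 = sum(1 for d in d_list if d >= 5)
        ge20 = sum(1 for d in d_list if d >= 20)
        return n, n - ge5, ge5, ge20

    exp = side([d for d in deltas if d > 0])
    con = side([-d for d in deltas if d < 0])
    return ClassCounts(
        modal_reference=modal_reference,
        n_contracted=con[0],
        n_modal=sum(1 for d in deltas if d == 0),
        n_expanded=exp[0],
        expanded_1_4=exp[1],
        expanded_ge5=exp[2],
        expanded_ge20=exp[3],
        contracted_1_4=con[1],
        contracted_ge5=con[2],
        contracted_ge20=con[3],
        label=label,
    )


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    low_expected_cells: int


def chi_square_independence(table: np.ndarray | Sequence[Sequence[float]]) -> Chi2Result:
    """Pearson chi-square test of independence (no continuity correction).

    Warns when any expected cell is below 5, the usual validity guideline.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero-margin row or column")
    stat, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    low = int((expected < 5).sum())
    if low:
        warnings.warn(
            f"{low} expected cell(s) < 5; chi-square approximation may be poor",
            stacklevel=2,
        )
    return Chi2Result(float(stat), int(dof), float(p), expected, low)


def compare_class_counts(
    tables: Sequence[ClassCounts], labels: Sequence[str] | None = None
) -> Chi2Result:
    """Chi-square comparison of (contracted, modal, expanded) counts across
    samples/tissues; df = (R - 1) * 2 for R samples."""
    if len(tables) < 2:
        raise ValueError("need at least 2 class-count tables to compare")
    obs = np.array([t.as_row() for t in tables], dtype=float)
    return chi_square_independence(obs)


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample single-molecule summary: n sized, mean/modal, extremes."""

    n_alleles: int
    mean_repeat: float
    modal_repeat: int
    highest_repeat: int
    lowest_repeat: int

    def as_dict(self) -> dict:
        return {
            "n_alleles": self.n_alleles,
            "mean_repeat": self.mean_repeat,
            "modal_repeat": self.modal_repeat,
            "highest_repeat": self.highest_repeat,
            "lowest_repeat": self.lowest_repeat,
        }


def summarize_sample(plates: PlateSet | Plate | Sequence[int], ndigits: int = 1) -> SampleSummary:
    """Table-style per-sample summary of sized single-molecule alleles."""
    if isinstance(plates, (Plate, PlateSet)):
        repeats = plates.sized_repeats()
    else:
        repeats = [int(r) for r in plates]
    if not repeats:
        raise ValueError("no sized wells to summarize")
    counts: dict[int, float] = {}
    for r in repeats:
        counts[r] = counts.get(r, 0) + 1
    return SampleSummary(
        n_alleles=len(repeats),
        mean_repeat=round(float(np.mean(repeats)), ndigits),
        modal_repeat=modal_allele(counts),
        highest_repeat=max(repeats),
        lowest_repeat=min(repeats),
    )


# ---------------------------------------------------------------------------
# Plate CSV dialect: plate_id, well, input_class, size_bp ("NEG" for no
# product), height (optional).  Sizes are fragment sizes in bp; repeats are
# recovered through a SizeCalibration on read.
# ---------------------------------------------------------------------------

def write_plate_csv(plates: PlateSet, calib: SizeCalibration, path) -> None:
    rows = []
    for p in plates.plates:
        for w in p.wells:
            size = "NEG" if w.repeat is None else f"{calib.repeats_to_bp(w.repeat):.1f}"
            rows.append(
                {
                    "plate_id": p.plate_id,
                    "dilution_id": p.dilution_id,
                    "well": w.well_id,
                    "input_class": w.input_class,
                    "size_bp": size,
                    "height": "" if w.height is None else f"{w.height:.1f}",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plate_csv(path, calib: SizeCalibration, sample_id: str = "", tissue: str = "") -> PlateSet:
    df = pd.read_csv(path, dtype={"size_bp": str})
    required = {"plate_id", "well", "input_class", "size_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing plate CSV column(s) {sorted(missing)}")
    plates = []
    group_cols = ["plate_id"] + (["dilution_id"] if "dilution_id" in df.columns else [])
    for key, group in df.groupby(group_cols, sort=True):
        plate_id = key[0] if isinstance(key, tuple) else key
        dilution_id = key[1] if isinstance(key, tuple) and len(key) > 1 else str(plate_id)
        wells = []
        for _, row in group.iterrows():
            size = str(row["size_bp"]).strip()
            if size.upper() in ("NEG", "NA", "", "NAN"):
                repeat = None
            else:
                repeat, _ = calib.bp_to_repeats(float(size))
            height = None
            if "height" in group.columns and not pd.isna(row["height"]) and str(row["height"]).strip():
                height = float(row["height"])
            wells.append(
                Well(str(row["well"]), str(row["input_class"]), repeat, height)
            )
        plates.append(
            Plate(str(plate_id), str(dilution_id), tuple(wells))
        )
    return PlateSet(tuple(plates), sample_id=sample_id, tissue=tissue)
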