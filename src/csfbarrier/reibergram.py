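"""Quotient diagrams (Reibergrams) for CSF/serum protein quotients.

The CSF/serum concentration quotient ``Q = c_CSF / c_serum`` of a
blood-derived protein rises with the albumin quotient ``Q_Alb``, the
reference measure of blood-CSF barrier function.  Across a large reference
population the relation between an immunoglobulin quotient ``Q_IgX`` and
``Q_Alb`` is described by hyperbolic curves

    Q_IgX(Q_Alb) = (a/b) * sqrt(Q_Alb**2 + b**2) - c

with an upper and a lower discrimination curve enclosing 99% of patients
and a mean curve between them.  Values above the upper curve indicate
intrathecal immunoglobulin synthesis (CNS-internal antibody production);
values below the lower curve are equally abnormal and usually point to
pre-analytical problems.

All quotients handled here are absolute dimensionless fractions (a typical
normal ``Q_Alb`` is 0.002-0.008); the conventional "x10^-3" display scaling
is applied only at I/O boundaries.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Optional

import numpy as np

__all__ = [
    "HyperbolicParams",
    "ReibergramFamily",
    "VariationGrid",
    "PatientRecord",
    "Band",
    "ClassificationResult",
    "hyperbolic_q",
    "variation_coefficient",
    "classify",
    "classify_record",
    "load_default_families",
    "load_default_variation_grid",
    "plot_reibergram",
]

ANALYTES = ("IgG", "IgA", "IgM")


@dataclass(frozen=True)
class HyperbolicParams:
    """Parameters (a/b, b^2, c) of one hyperbolic discrimination curve.

    Stored as absolute dimensionless numbers; the published tables print
    b^2 in units of 1e-6 and c in units of 1e-3.
    """

    a_over_b: float
    b_sq: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a_over_b > 0):
            raise ValueError(f"a_over_b must be > 0, got {self.a_over_b}")
        if not (self.b_sq > 0):
            raise ValueError(f"b_sq must be > 0, got {self.b_sq}")
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")

    def __call__(self, q_alb):
        return hyperbolic_q(q_alb, self)


def hyperbolic_q(q_alb, params: HyperbolicParams):
    """Evaluate a hyperbolic quotient curve at ``q_alb``.

    Returns ``(a/b) * sqrt(q_alb**2 + b**2) - c``.  Accepts scalars or
    arrays.  The lower-limit curves may legitimately return small negative
    values at very small ``q_alb``; callers clamp for display only.
    """
    q = np.asarray(q_alb, dtype=float)
    if np.any(q < 0):
        raise ValueError("q_alb must be >= 0")
    out = params.a_over_b * np.sqrt(q * q + params.b_sq) - params.c
    if np.isscalar(q_alb) or out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class ReibergramFamily:
    """Upper/mean/lower hyperbolic curves for one immunoglobulin."""

    analyte: str
    upper: HyperbolicParams
    mean: HyperbolicParams
    lower: HyperbolicParams
    q_alb_range: tuple[float, float] = (2e-3, 0.15)

    def __post_init__(self) -> None:
        lo, hi = self.q_alb_range
        if not (0 <= lo < hi):
            raise ValueError(f"invalid q_alb_range {self.q_alb_range}")
        # ordering invariant on a probe grid across the validity window
        probe = np.geomspace(max(lo, 1e-6), hi, 32)
        up = hyperbolic_q(probe, self.upper)
        mid = hyperbolic_q(probe, self.mean)
        low = hyperbolic_q(probe, self.lower)
        if not (np.all(up > mid) and np.all(mid > low)):
            raise ValueError(
                f"{self.analyte}: curves must satisfy upper > mean > lower "
                "over the validity window"
            )


@dataclass(frozen=True)
class VariationGrid:
    """Published population variation coefficients on a Q_Alb grid.

    The population variation coefficient at a given ``Q_Alb`` is
    ``(upper - lower) / mean``, the relative spread of the reference
    population.  Entries may be ``None`` where the source prints none.
    """

    q_alb_values: tuple[float, ...]
    coefficients: dict[str, tuple[Optional[float], ...]]

    def __post_init__(self) -> None:
        q = np.asarray(self.q_alb_values)
        if not np.all(np.diff(q) > 0):
            raise ValueError("q_alb_values must be strictly increasing")
        for analyte, vals in self.coefficients.items():
            if len(vals) != len(self.q_alb_values):
                raise ValueError(f"{analyte}: one coefficient per q_alb required")


def variation_coefficient(family: ReibergramFamily, q_alb: float) -> float:
    """Population variation coefficient ``(upper - lower) / mean`` at q_alb."""
    mean = hyperbolic_q(q_alb, family.mean)
    if mean <= 0:
        raise ValueError(
            f"{family.analyte}: mean curve non-positive at q_alb={q_alb}; "
            "variation coefficient undefined"
        )
    upper = hyperbolic_q(q_alb, family.upper)
    lower = hyperbolic_q(q_alb, family.lower)
    return (upper - lower) / mean


@dataclass(frozen=True)
class PatientRecord:
    """One individual's CSF/serum quotients (absolute fractions)."""

    id: str
    q_alb: float
    q_igg: Optional[float] = None
    q_iga: Optional[float] = None
    q_igm: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.q_alb < 1):
            raise ValueError(f"{self.id}: q_alb must be in (0, 1), got {self.q_alb}")
        for name in ("q_igg", "q_iga", "q_igm"):
            v = getattr(self, name)
            if v is not None and not (0 < v < 1):
                raise ValueError(f"{self.id}: {name} must be in (0, 1), got {v}")

    def quotient_for(self, analyte: str) -> Optional[float]:
        return getattr(self, f"q_{analyte.lower()}")


class Band(str, Enum):
    ABOVE_UPPER = "above_upper"
    WITHIN_REFERENCE = "within_reference"
    BELOW_LOWER = "below_lower"
    MISSING_DATA = "missing_data"


@dataclass(frozen=True)
class ClassificationResult:
    """Position of one observed quotient relative to the discrimination curves."""

    id: str
    analyte: str
    band: Band
    observed_q: Optional[float]
    limit_q_upper: float
    limit_q_lower: float
    mean_q: float
    ratio_to_mean: Optional[float]
    out_of_calibrated_range: bool = False


def classify(record: PatientRecord, family: ReibergramFamily) -> ClassificationResult:
    """Classify one patient's quotient against a Reibergram family.

    A missing analyte quotient yields an explicit ``MISSING_DATA`` result
    (never a silent skip).  A ``q_alb`` outside the calibrated range is
    still classified but flagged and warned about.
    """
    q_alb = record.q_alb
    lo, hi = family.q_alb_range
    out_of_range = not (lo <= q_alb <= hi)
    if out_of_range:
        warnings.warn(
            f"{record.id}: q_alb={q_alb:g} outside calibrated range "
            f"[{lo:g}, {hi:g}]; classification beyond calibrated range",
            stacklevel=2,
        )
    upper = hyperbolic_q(q_alb, family.upper)
    mean = hyperbolic_q(q_alb, family.mean)
    lower = hyperbolic_q(q_alb, family.lower)

    observed = record.quotient_for(family.analyte)
    if observed is None:
        return ClassificationResult(
            id=record.id, analyte=family.analyte, band=Band.MISSING_DATA,
            observed_q=None, limit_q_upper=upper, limit_q_lower=lower,
            mean_q=mean, ratio_to_mean=None, out_of_calibrated_range=out_of_range,
        )
    if observed > upper:
        band = Band.ABOVE_UPPER
    elif observed < lower:
        band = Band.BELOW_LOWER
    else:
        band = Band.WITHIN_REFERENCE
    ratio = observed / mean if mean > 0 else math.nan
    return ClassificationResult(
        id=record.id, analyte=family.analyte, band=band, observed_q=observed,
        limit_q_upper=upper, limit_q_lower=lower, mean_q=mean,
        ratio_to_mean=ratio, out_of_calibrated_range=out_of_range,
    )


def classify_record(
    record: PatientRecord, families: dict[str, ReibergramFamily]
) -> list[ClassificationResult]:
    """Classify one record against every supplied family (analyte order kept)."""
    return [classify(record, families[a]) for a in families]


# ---------------------------------------------------------------------------
# packaged defaults


def _load_packaged(name: str) -> dict:
    with resources.files("csfbarrier.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_default_families() -> dict[str, ReibergramFamily]:
    """Load the packaged hyperbolic curve families (scales applied)."""
    raw = _load_packaged("reibergram_params.json")
    s_b, s_c, s_q = (raw["scales"][k] for k in ("b_sq", "c", "q_alb"))
    lo, hi = (v * s_q for v in raw["q_alb_range"])
    families = {}
    for analyte, curves in raw["families"].items():
        params = {
            which: HyperbolicParams(
                a_over_b=p["a_over_b"], b_sq=p["b_sq"] * s_b, c=p["c"] * s_c
            )
            for which, p in curves.items()
        }
        families[analyte] = ReibergramFamily(
            analyte=analyte, q_alb_range=(lo, hi), **params
        )
    return families


def load_default_variation_grid() -> VariationGrid:
    """Load the published population variation-coefficient grid."""
    raw = _load_packaged("reibergram_params.json")
    grid = raw["variation_grid"]
    s_q = raw["scales"]["q_alb"]
    return VariationGrid(
        q_alb_values=tuple(v * s_q for v in grid["q_alb"]),
        coefficients={a: tuple(grid[a]) for a in ANALYTES},
    )


def plot_reibergram(
    family: ReibergramFamily,
    records: Optional[list[PatientRecord]] = None,
    ax=None,
):
    """Draw one quotient diagram on log-log axes.

    Lower-limit curve values below zero are clamped to the bottom of the
    plotted range (display only; computation never clamps).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    lo, hi = family.q_alb_range
    q = np.geomspace(lo, hi, 400)
    floor = 1e-5
    for params, style, label in (
        (family.upper, "--", "upper limit"),
        (family.mean, "-", "mean"),
        (family.lower, ":", "lower limit"),
    ):
        ax.plot(q, np.maximum(hyperbolic_q(q, params), floor), style, label=label)
    if records:
        pts = [
            (r.q_alb, r.quotient_for(family.analyte))
            for r in records
            if r.quotient_for(family.analyte) is not None
        ]
        if pts:
            xs, ys = zip(*pts)
            ax.plot(xs, ys, "k.", ms=4, label="patients")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$Q_{Alb}$")
    ax.set_ylabel(rf"$Q_{{{family.analyte}}}$")
    ax.legend(loc="upper left", fontsize=8)
    ax.set_title(f"Reibergram {family.analyte}")
    return ax
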