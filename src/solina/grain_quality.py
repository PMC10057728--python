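"""Commercial grain-quality computations.

Kernel morphometrics (ellipsoid volume and dimension ratios), CIELAB
colour derivatives (chroma, hue angle, CIE76 colour difference), and
chip digital-PCR copy-number quantification.

Units: kernel diameters in mm, volumes in mm^3; dPCR concentrations in
copies/uL with well volumes in uL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: CIE76 "just noticeable difference" for Delta-E; colour differences above
#: this are taken as perceptible to the unaided eye.
JND_DELTA_E = 2.3


# ---------------------------------------------------------------------------
# kernel morphometrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelMorphology:
    """Per-kernel size and shape descriptors.

    ``l1 >= l2 >= l3`` is the conventional ordering (major, intermediate,
    minor diameter); the ratios then all sit at or above 1.
    """

    l1: float
    l2: float
    l3: float
    volume: float
    ratio_l1_l2: float
    ratio_l1_l3: float
    ratio_l2_l3: float


def miller_volume(l1: float, l2: float, l3: float) -> float:
    """Ellipsoid (Miller) kernel volume V = pi * L1 * L2 * L3 / 6.

    Inputs in mm give mm^3. Vectorises over array-likes.
    """
    l1, l2, l3 = np.asarray(l1, float), np.asarray(l2, float), np.asarray(l3, float)
    if np.any(l1 <= 0) or np.any(l2 <= 0) or np.any(l3 <= 0):
        raise ValueError("kernel diameters must be positive")
    out = np.pi * l1 * l2 * l3 / 6.0
    return float(out) if out.ndim == 0 else out


def dimension_ratios(l1: float, l2: float, l3: float) -> tuple[float, float, float]:
    """Return the elongation/shape quotients (L1/L2, L1/L3, L2/L3)."""
    l1, l2, l3 = np.asarray(l1, float), np.asarray(l2, float), np.asarray(l3, float)
    if np.any(l2 == 0) or np.any(l3 == 0):
        raise ValueError("ratio denominators must be non-zero")
    r12, r13, r23 = l1 / l2, l1 / l3, l2 / l3
    if r12.ndim == 0:
        return float(r12), float(r13), float(r23)
    return r12, r13, r23


def kernel_morphology(l1: float, l2: float, l3: float) -> KernelMorphology:
    r12, r13, r23 = dimension_ratios(l1, l2, l3)
    return KernelMorphology(l1, l2, l3, miller_volume(l1, l2, l3), r12, r13, r23)


def kernel_cluster_summary(traits: pd.DataFrame, cluster_col: str = "cluster") -> pd.DataFrame:
    """Per-cluster kernel summaries under both averaging orders.

    ``volume_mean_of_kernels`` averages per-kernel volumes; ``volume_of_mean_dims``
    applies the ellipsoid formula to the mean diameters. The two differ
    (Jensen-type effect) and published tables commonly mix them, so both are
    reported side by side, together with ratios computed on mean diameters.
    """
    rows = []
    for cluster, sub in traits.groupby(cluster_col, sort=True):
        m1, m2, m3 = sub["L1"].mean(), sub["L2"].mean(), sub["L3"].mean()
        r12, r13, r23 = dimension_ratios(m1, m2, m3)
        rows.append({
            cluster_col: cluster,
            "L1": m1, "L2": m2, "L3": m3,
            "volume_mean_of_kernels": miller_volume(sub["L1"], sub["L2"], sub["L3"]).mean(),
            "volume_of_mean_dims": miller_volume(m1, m2, m3),
            "ratio_l1_l2": r12, "ratio_l1_l3": r13, "ratio_l2_l3": r23,
        })
    return pd.DataFrame(rows).set_index(cluster_col)


# ---------------------------------------------------------------------------
# colour
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColourMeasurement:
    """A CIELAB colour with its derived chroma/hue, and optionally the
    CIE76 difference against a reference colour."""

    lightness: float          # L*
    a: float                  # a*, red-green axis
    b: float                  # b*, yellow-blue axis
    chroma: float             # C* = sqrt(a*^2 + b*^2)
    hue_deg: float            # h in [0, 360)
    delta_e: float | None = None
    is_perceptible: bool | None = None


def delta_e76(lab1: tuple[float, float, float], lab2: tuple[float, float, float]) -> float:
    """CIE76 colour difference: Euclidean distance in (L*, a*, b*)."""
    return float(np.linalg.norm(np.asarray(lab1, float) - np.asarray(lab2, float)))


def colour_metrics(
    lightness: float,
    a: float,
    b: float,
    reference: tuple[float, float, float] | None = None,
) -> ColourMeasurement:
    """Derive C*, hue angle and (if a reference is given) Delta-E from CIELAB.

    The hue angle is atan2(b*, a*) in degrees mapped to [0, 360). Delta-E is
    only computed against a caller-supplied reference; perceptibility uses the
    2.3 JND convention of CIE76.
    """
    chroma = math.hypot(a, b)
    hue = math.degrees(math.atan2(b, a)) % 360.0
    de = per = None
    if reference is not None:
        de = delta_e76((lightness, a, b), reference)
        per = de > JND_DELTA_E
    return ColourMeasurement(lightness, a, b, chroma, hue, de, per)


# ---------------------------------------------------------------------------
# digital PCR
# ---------------------------------------------------------------------------

@dataclass
class DPCRChip:
    """Raw readout of one partitioned-PCR chip with two channels.

    ``positives`` maps channel name ("target"/"reference") to the number of
    wells positive for that channel; ``double_positive`` counts wells positive
    for both (loading is independent per molecule).
    """

    n_wells: int
    well_volume_ul: float
    positives: dict[str, int]
    double_positive: int = 0
    true_copies_per_ul: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValueError("chip needs at least one well")
        for channel, k in self.positives.items():
            if not 0 <= k <= self.n_wells:
                raise ValueError(f"positive count out of range for {channel!r}")


def dpcr_quantify(
    positives: int, n_wells: int, well_volume_ul: float
) -> tuple[float, tuple[float, float]]:
    """Poisson single-molecule concentration from a positive-well count.

    With occupancy lambda*v per well, P(positive) = 1 - exp(-lambda*v), so
    lambda = -ln(1 - k/n) / v. The 95% interval propagates the binomial
    variance of k/n by the delta method. A saturated chip (k = n) carries no
    upper information and raises.
    """
    if not 0 <= positives <= n_wells:
        raise ValueError("positive count out of range")
    if positives == n_wells:
        raise ValueError("all wells positive: concentration not quantifiable")
    phat = positives / n_wells
    lam = -math.log1p(-phat) / well_volume_ul
    # d lambda / d p = 1 / ((1-p) v)
    se = math.sqrt(phat * (1 - phat) / n_wells) / ((1 - phat) * well_volume_ul)
    z = stats.norm.ppf(0.975)
    return lam, (max(0.0, lam - z * se), lam + z * se)


def quantify_chip(chip: DPCRChip) -> dict[str, tuple[float, tuple[float, float]]]:
    """Concentration (with 95% CI) for every channel of a chip."""
    return {
        ch: dpcr_quantify(k, chip.n_wells, chip.well_volume_ul)
        for ch, k in chip.positives.items()
    }


def cnv_call(target_copies_per_ul: float, reference_copies_per_ul: float) -> tuple[float, int]:
    """Copy-number variation as the target/reference concentration ratio.

    The integer copy call is the nearest integer with half-up rounding, so a
    ratio of 1.9 calls two copies and 1.0 calls one.
    """
    if reference_copies_per_ul <= 0:
        raise ValueError("reference concentration must be positive")
    ratio = target_copies_per_ul / reference_copies_per_ul
    return ratio, int(math.floor(ratio + 0.5))
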