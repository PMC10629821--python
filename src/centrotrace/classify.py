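"""Age-classification of recombined centrosomes from two-channel intensities.

Two schemes mirror the manual and the unbiased analyses of RITE-birthdated
centrosomes:

* ``manual_classify`` reproduces the by-eye criteria referenced to the
  unrecombined centrosomes of the same image: ORANGE when the tdTomato
  signal is statistically indistinguishable from unrecombined centrosomes,
  GREEN when tdTomato is undetectable, YELLOW in between.
* ``tertile_classify`` splits the recombined centrosomes of one image into
  thirds by their NeonGreen-to-total ratio; the highest-ratio third is GREEN
  (youngest), the middle YELLOW, the lowest ORANGE (oldest).

Both operate per image (one cortical-unit scene) because the reference
statistics and the tertile boundaries are image-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from math import ceil

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "ColourCall",
    "ReferenceStats",
    "green_ratio",
    "green_ratio_table",
    "is_recombined",
    "manual_classify",
    "tertile_classify",
    "estimate_noise_floor",
    "reference_from_unrecombined",
]


class ColourCall(str, Enum):
    ORANGE = "ORANGE"
    YELLOW = "YELLOW"
    GREEN = "GREEN"
    UNRECOMBINED = "UNRECOMBINED"


@dataclass(frozen=True)
class ReferenceStats:
    """Per-image reference derived from unrecombined centrosomes.

    ``unrec_T_location`` / ``unrec_T_spread`` are the median and the median
    absolute deviation of the tdTomato signal over unrecombined centrosomes
    of the same image; ``noise_floor`` is the NeonGreen detection floor and
    ``noise_floor_T`` its tdTomato counterpart.  Manual classification
    refuses to run when fewer than three unrecombined centrosomes back the
    reference.
    """

    unrec_T_location: float
    unrec_T_spread: float
    noise_floor: float
    noise_floor_T: float = 0.0
    n_unrecombined: int = 0


def green_ratio(T_meas: float, N_meas: float) -> float:
    """NeonGreen over total signal, the age statistic in [0, 1]."""
    if T_meas < 0 or N_meas < 0:
        raise ParameterError("intensities must be non-negative (clamp first)")
    total = T_meas + N_meas
    if total == 0:
        raise ParameterError("undefined ratio: T_meas + N_meas == 0")
    return N_meas / total

def green_ratio_table(T_meas, N_meas) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised ratio with an exclusion mask for zero-total centrosomes."""
    T = np.asarray(T_meas, dtype=float)
    N = np.asarray(N_meas, dtype=float)
    if (T < 0).any() or (N < 0).any():
        raise ParameterError("intensities must be non-negative (clamp first)")
    total = T + N
    excluded = total == 0
    ratio = np.full(T.shape, np.nan)
    np.divide(N, total, out=ratio, where=~excluded)
    return ratio, excluded


def estimate_noise_floor(channel: np.ndarray, k: float = 3.0) -> float:
    """Detection floor as ``k`` times the MAD of a (mostly background) channel."""
    channel = np.asarray(channel, dtype=float)
    return k * float(np.median(np.abs(channel - np.median(channel))))


def is_recombined(N_meas, reference: ReferenceStats):
    """A centrosome is recombined when NeonGreen exceeds the detection floor."""
    return np.asarray(N_meas, dtype=float) > reference.noise_floor


def reference_from_unrecombined(
    unrec_T: np.ndarray, noise_floor: float, noise_floor_T: float | None = None
) -> ReferenceStats:
    """Build per-image reference statistics from unrecombined tdTomato signals."""
    unrec_T = np.asarray(unrec_T, dtype=float)
    loc = float(np.median(unrec_T)) if unrec_T.size else np.nan
    spread = float(np.median(np.abs(unrec_T - loc))) if unrec_T.size else np.nan
    return ReferenceStats(
        unrec_T_location=loc,
        unrec_T_spread=spread,
        noise_floor=noise_floor,
        noise_floor_T=noise_floor if noise_floor_T is None else noise_floor_T,
        n_unrecombined=int(unrec_T.size),
    )


def manual_classify(
    T_meas: float,
    N_meas: float,
    reference: ReferenceStats,
    c1: float = 2.0,
) -> ColourCall:
    """Manual colour criteria referenced to unrecombined centrosomes.

    UNRECOMBINED when NeonGreen is below the floor; otherwise ORANGE when
    tdTomato is within ``c1`` spreads of the unrecombined location, GREEN
    when tdTomato is below its own detection floor, YELLOW in between.
    """
    if not is_recombined(N_meas, reference):
        return ColourCall.UNRECOMBINED
    if reference.n_unrecombined < 3:
        raise ParameterError(
            "manual classification needs >= 3 unrecombined centrosomes in the image "
            f"(got {reference.n_unrecombined})"
        )
    if T_meas >= reference.unrec_T_location - c1 * reference.unrec_T_spread:
        return ColourCall.ORANGE
    if T_meas <= reference.noise_floor_T:
        return ColourCall.GREEN
    return ColourCall.YELLOW


def tertile_classify(ratios) -> list[ColourCall]:
    """Allocate recombined centrosomes of one image to ratio tertiles.

    Sorted by ratio descending with a stable tie-break on input order, the
    first ``ceil(n/3)`` are GREEN, the next ``ceil((n - n_green)/2)`` YELLOW
    and the remainder ORANGE, so group sizes never differ by more than one.
    """
    ratios = np.asarray(ratios, dtype=float)
    n = ratios.size
    if n < 3:
        raise ParameterError(f"tertile classification needs >= 3 centrosomes, got {n}")
    if np.isnan(ratios).any():
        raise ParameterError("ratios must be defined (exclude zero-total centrosomes first)")
    n_green = ceil(n / 3)
    n_yellow = ceil((n - n_green) / 2)
    order = np.argsort(-ratios, kind="stable")
    calls = np.empty(n, dtype=object)
    calls[order[:n_green]] = ColourCall.GREEN
    calls[order[n_green : n_green + n_yellow]] = ColourCall.YELLOW
    calls[order[n_green + n_yellow :]] = ColourCall.ORANGE
    return list(calls)
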