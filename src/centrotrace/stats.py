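"""Region-wise statistics and recovery of the inheritance-asymmetry parameter.

Aggregates colour calls by region (ventricular wall vs surround) and cortical
unit, compares per-unit proportions with the unpaired two-sample Student
t-test (equal variance, as in the original analysis; Welch available behind a
flag), computes fate percentages, and estimates the probability ``p_asym``
that the self-renewing daughter inherits the older centrosome.

The estimator is method-of-moments for single-division snapshots (fraction of
oldest-class centrosomes found on the ventricular wall) and, for deeper
lineages, a minimum-distance fit: a grid of candidate ``p`` values is pushed
through the same generative model (matched turnover and division depth, common
random numbers across the grid) and the value whose simulated region-by-colour
composition is closest in L2 to the observed one is returned, with a
percentile bootstrap over cortical units for the confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import ColourCall, tertile_classify
from .errors import ParameterError
from .lineage import SimConfig, simulate_cohort_arrays

__all__ = [
    "RegionColourCounts",
    "count_by_colour",
    "colour_proportions",
    "region_count_ratio",
    "compare_regions",
    "TTestResult",
    "stars",
    "fate_counts_from_cohort",
    "fate_percentages",
    "InferenceConfig",
    "AsymmetryEstimate",
    "estimate_asymmetry",
]

REGIONS = ["VENT", "NONVENT"]
COLOURS = ["ORANGE", "YELLOW", "GREEN"]


@dataclass(frozen=True)
class RegionColourCounts:
    """Counts of analysed recombined centrosomes for one cortical unit."""

    unit_id: int
    counts: pd.DataFrame  # index REGIONS, columns COLOURS
    n_unrecombined: int = 0
    n_excluded: int = 0


def count_by_colour(classified: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally (unit, region, colour) for analysed recombined centrosomes.

    Returns ``(counts, extras)``: ``counts`` is a complete long table over
    every unit x region x colour combination; ``extras`` reports the
    unrecombined and region-excluded puncta per unit separately.  Rows with
    missing labels raise, listing the offending indices.
    """
    required = {"unit_id", "region", "colour"}
    missing_cols = required - set(classified.columns)
    if missing_cols:
        raise ParameterError(f"classified table lacks columns {sorted(missing_cols)}")
    bad = classified.index[classified["region"].isna() | classified["colour"].isna()]
    if len(bad):
        raise ParameterError(f"missing region/colour labels at rows {list(bad)}")

    units = sorted(classified["unit_id"].unique())
    unrec = classified["colour"] == ColourCall.UNRECOMBINED.value
    excl = classified["region"] == "EXCLUDED"
    analysed = classified[~unrec & ~excl]

    idx = pd.MultiIndex.from_product([units, REGIONS, COLOURS], names=["unit_id", "region", "colour"])
    counts = (
        analysed.groupby(["unit_id", "region", "colour"])
        .size()
        .reindex(idx, fill_value=0)
        .rename("count")
        .reset_index()
    )
    extras = (
        pd.DataFrame(
            {
                "unit_id": classified["unit_id"],
                "unrecombined": unrec.astype(int),
                "excluded": (~unrec & excl).astype(int),
            }
        )
        .groupby("unit_id")
        .sum()
        .reset_index()
    )
    return counts, extras


def colour_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-(unit, region) colour proportions; zero-total regions are dropped.

    Each retained region's proportions sum to one.
    """
    totals = counts.groupby(["unit_id", "region"])["count"].transform("sum")
    empty = totals == 0
    if empty.any():
        dropped = counts.loc[empty, ["unit_id", "region"]].drop_duplicates()
        warnings.warn(
            f"dropping regions with no analysed centrosomes: {dropped.to_dict('records')}"
        )
    out = counts[~empty].copy()
    out["proportion"] = out["count"] / totals[~empty]
    return out


def region_count_ratio(counts: pd.DataFrame) -> pd.Series:
    """Pooled VENT / NONVENT count ratio per colour (NaN when undefined)."""
    pooled = counts.groupby(["region", "colour"])["count"].sum().unstack("region")
    vent = pooled.get("VENT", pd.Series(dtype=float))
    nonvent = pooled.get("NONVENT", pd.Series(dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = vent / nonvent.replace(0, np.nan)
    return ratio.reindex(COLOURS)


def stars(p: float) -> str:
    """Significance label: ns / * / ** / *** at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    stars: str
    n_a: int
    n_b: int


def compare_regions(a, b, equal_var: bool = True) -> TTestResult:
    """Unpaired two-sample Student t-test on per-unit values.

    Classic pooled-variance test by default; ``equal_var=False`` switches to
    Welch.  Zero pooled variance with equal means yields t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2 observations")
    if not equal_var:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        return TTestResult(float(t), float(p), stars(float(p)), a.size, b.size)
    n1, n2 = a.size, b.size
    m1, m2 = a.mean(), b.mean()
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        if m1 == m2:
            return TTestResult(0.0, 1.0, "ns", n1, n2)
        t = np.inf if m1 > m2 else -np.inf
        return TTestResult(float(t), 0.0, "***", n1, n2)
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), n1 + n2 - 2)
    return TTestResult(float(t), float(p), stars(float(p)), n1, n2)


def fate_counts_from_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-unit fate tallies over all cells (the targeted population)."""
    def _tally(grp: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n_targeted": len(grp),
                "n_sox2": int((grp["fate_marker"] == "SOX2").sum()),
                "n_ctip2": int((grp["fate_marker"] == "CTIP2").sum()),
                "n_undefined": int((grp["fate_marker"] == "UNDEFINED").sum()),
            }
        )
    return cohort.groupby("unit_id").apply(_tally, include_groups=False).reset_index()


def fate_percentages(fates: pd.DataFrame) -> pd.DataFrame:
    """Percent SOX2+ (NPC) and CTIP2+ (neuron) of targeted cells per unit."""
    fates = fates.copy()
    zero = fates["n_targeted"] == 0
    if zero.any():
        warnings.warn(f"excluding units with no targeted cells: {list(fates.loc[zero, 'unit_id'])}")
        fates = fates[~zero]
    fates["pct_sox2"] = 100.0 * fates["n_sox2"] / fates["n_targeted"]
    fates["pct_ctip2"] = 100.0 * fates["n_ctip2"] / fates["n_targeted"]
    return fates


# ---------------------------------------------------------------------------
# inheritance-asymmetry recovery


@dataclass(frozen=True)
class InferenceConfig:
    """Settings for :func:`estimate_asymmetry`.

    The assumed turnover ``tau`` and division depth ``n_div`` must match the
    conditions under which the data were generated/acquired; the reference
    simulation re-uses them.
    """

    n_div: int = 6
    tau: float = 0.05
    L0: float = 1.0
    f_rec: float = 0.4
    grid_step: float = 0.02
    ref_units: int = 600
    ref_lineages_per_unit: int = 12
    n_boot: int = 300
    ci_level: float = 0.95
    seed: int = 0


@dataclass(frozen=True)
class AsymmetryEstimate:
    p_hat: float
    ci_low: float
    ci_high: float
    method: str
    n_units: int
    config: InferenceConfig
    bootstrap: np.ndarray = field(repr=False, default=None)


def _unit_matrices(classified: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit 6-vectors of (region x colour) counts, order VENT then NONVENT."""
    analysed = classified[
        classified["region"].isin(REGIONS) & classified["colour"].isin(COLOURS)
    ]
    if analysed.empty:
        raise ParameterError("no analysed recombined centrosomes to infer from")
    units = np.asarray(sorted(analysed["unit_id"].unique()))
    mats = np.zeros((units.size, 6))
    r_idx = {r: i for i, r in enumerate(REGIONS)}
    c_idx = {c: i for i, c in enumerate(COLOURS)}
    u_idx = {u: i for i, u in enumerate(units)}
    for (u, r, c), cnt in analysed.groupby(["unit_id", "region", "colour"]).size().items():
        mats[u_idx[u], 3 * r_idx[r] + c_idx[c]] = cnt
    return units, mats


def _tertile_codes(ratios: np.ndarray, tie_order: np.ndarray) -> np.ndarray:
    """Colour index (0=ORANGE, 1=YELLOW, 2=GREEN) per punctum of one image."""
    calls = tertile_classify(ratios[tie_order])
    codes = np.empty(ratios.size, dtype=int)
    lut = {ColourCall.ORANGE: 0, ColourCall.YELLOW: 1, ColourCall.GREEN: 2}
    codes[tie_order] = [lut[c] for c in calls]
    return codes


def _reference_curves(grid: np.ndarray, cfg: InferenceConfig, rng: np.random.Generator) -> np.ndarray:
    """Simulated (region x colour) composition for each candidate p.

    Uses common random numbers across the grid (one shared uniform stream for
    recombination, inheritance and tie-breaking) so the curve is smooth in p
    and the Monte-Carlo error is shared rather than independent per point.
    """
    n_lin = cfg.ref_units * cfg.ref_lineages_per_unit
    u_rec = rng.random(n_lin)
    u_keep = rng.random((cfg.n_div, n_lin))
    curves = np.empty((grid.size, 6))
    base = SimConfig(
        p_asym=0.5,  # placeholder; draws are injected below
        tau=cfg.tau,
        L0=cfg.L0,
        f_rec=cfg.f_rec,
        n_div=cfg.n_div,
        n_lineages_per_unit=cfg.ref_lineages_per_unit,
        n_units=cfg.ref_units,
    )
    # recombination (hence puncta membership per unit) is fixed across the
    # grid, so the per-unit blocks and the tie-break ranks are shared; the
    # tertile split is applied to all units at once via one lexsort per p
    probe = _simulate_with_draws(base, 0.5, u_rec, u_keep)
    rec = probe["recombined"]
    unit = probe["unit_id"][rec]
    region = np.where(probe["is_vz"][rec], 0, 1)
    sizes = np.bincount(unit, minlength=base.n_units)
    ok_units = sizes >= 3
    keep = ok_units[unit]
    unit, region = unit[keep], region[keep]
    sizes = sizes[np.unique(unit)] if unit.size else sizes[:0]
    tie_rng = np.random.default_rng(int(rng.integers(2**31)))
    tie_rank = tie_rng.permutation(unit.size)
    # dense unit codes in sorted-unit order and per-position block offsets
    _, unit_dense = np.unique(unit, return_inverse=True)
    starts = np.zeros(sizes.size, dtype=int)
    if sizes.size:
        starts[1:] = np.cumsum(sizes)[:-1]
    n_green = np.ceil(sizes / 3).astype(int)
    n_yellow = np.ceil((sizes - n_green) / 2).astype(int)
    for gi, p in enumerate(grid):
        arrays = _simulate_with_draws(base, p, u_rec, u_keep)
        ratio = (arrays["N"][rec] / (arrays["T"][rec] + arrays["N"][rec]))[keep]
        order = np.lexsort((tie_rank, -ratio, unit_dense))
        pos = np.arange(unit.size) - starts[unit_dense[order]]
        code_sorted = np.where(
            pos < n_green[unit_dense[order]],
            2,
            np.where(pos < (n_green + n_yellow)[unit_dense[order]], 1, 0),
        )
        vec = np.bincount(3 * region[order] + code_sorted, minlength=6).astype(float)
        total = vec.sum()
        curves[gi] = vec / total if total else vec
    return curves


def _simulate_with_draws(
    base: SimConfig, p: float, u_rec: np.ndarray, u_keep: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorised snapshot with injected uniform draws (common random numbers)."""
    n = u_rec.size
    rec = u_rec < base.f_rec
    unit = np.repeat(np.arange(base.n_units), base.n_lineages_per_unit)
    res_T = np.full(n, float(base.L0))
    res_N = np.zeros(n)
    tau, L0 = base.tau, base.L0
    out_T, out_N, out_unit, out_rec, out_vz = [], [], [], [], []
    for d in range(1, base.n_div + 1):
        res_T *= 1.0 - tau
        res_N *= 1.0 - tau
        res_N[rec] += tau * L0
        res_T[~rec] += tau * L0
        new_T = np.where(rec, 0.0, L0)
        new_N = np.where(rec, L0, 0.0)
        keep_old = u_keep[d - 1] < p
        out_T.append(np.where(keep_old, new_T, res_T))
        out_N.append(np.where(keep_old, new_N, res_N))
        out_unit.append(unit)
        out_rec.append(rec)
        out_vz.append(np.zeros(n, dtype=bool))
        res_T = np.where(keep_old, res_T, new_T)
        res_N = np.where(keep_old, res_N, new_N)
    out_T.append(res_T)
    out_N.append(res_N)
    out_unit.append(unit)
    out_rec.append(rec)
    out_vz.append(np.ones(n, dtype=bool))
    return {
        "T": np.concatenate(out_T),
        "N": np.concatenate(out_N),
        "unit_id": np.concatenate(out_unit),
        "recombined": np.concatenate(out_rec),
        "is_vz": np.concatenate(out_vz),
    }


def estimate_asymmetry(
    classified: pd.DataFrame, config: InferenceConfig | None = None
) -> AsymmetryEstimate:
    """Recover ``p_asym`` from a classified, region-labelled cohort.

    For ``n_div == 1`` the method-of-moments estimate is the fraction of
    oldest-class (ORANGE) centrosomes found on the ventricular wall.  For
    deeper lineages a grid search over p in [0, 1] minimises the L2 distance
    between the observed and the model-simulated region-by-colour composition
    at matched tau and division depth.  The confidence interval is a
    percentile bootstrap over cortical units in both cases.
    """
    config = config or InferenceConfig()
    units, mats = _unit_matrices(classified)
    rng = np.random.default_rng(config.seed)
    alpha = 1.0 - config.ci_level

    if config.n_div == 1:
        def point(m: np.ndarray) -> float:
            orange_total = m[:, 0].sum() + m[:, 3].sum()
            if orange_total == 0:
                return np.nan
            return m[:, 0].sum() / orange_total

        p_hat = point(mats)
        if np.isnan(p_hat):
            raise ParameterError("no oldest-class centrosomes; moment estimator undefined")
        boot = np.array(
            [
                point(mats[rng.integers(units.size, size=units.size)])
                for _ in range(config.n_boot)
            ]
        )
        boot = boot[~np.isnan(boot)]
        lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2]) if boot.size else (np.nan, np.nan)
        return AsymmetryEstimate(float(p_hat), float(lo), float(hi), "moment", units.size, config, boot)

    grid = np.round(np.arange(0.0, 1.0 + 1e-9, config.grid_step), 10)
    curves = _reference_curves(grid, config, rng)

    def fit(m: np.ndarray) -> float:
        total = m.sum()
        v = m.sum(axis=0) / total
        return float(grid[np.argmin(((curves - v) ** 2).sum(axis=1))])

    p_hat = fit(mats)
    boot = np.array(
        [fit(mats[rng.integers(units.size, size=units.size)]) for _ in range(config.n_boot)]
    )
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    return AsymmetryEstimate(
        float(p_hat), float(lo), float(hi), "grid-l2", units.size, config, boot
    )
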