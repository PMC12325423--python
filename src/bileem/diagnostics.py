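"""Model-assessment diagnostics beyond scalar RSS and core consistency.

Zero-dimensional fit indicators cannot localize where on the wavelength
plane a trilinear model fails, so the assessment here is spatial and
per-sample: moving-window bias/RMSE/SD maps of modeled-minus-observed
residuals, reduced major axis (RMA) regression of modeled on observed
intensities (both surfaces carry error, so ordinary regression would bias
the slope), per-sample RMSE and RMSE-to-mean ratios, score-vs-DF curves
with monotonicity checks, and equal-score concentration-ratio estimation
between sources.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eem_core import EEMTensor, SampleRecord
from .errors import AlignmentError, OutOfRangeError
from .parafac import ParafacModel, core_consistency

__all__ = [
    "DiscrepancyMaps",
    "ScoreCurve",
    "discrepancy_maps",
    "rma_fit",
    "per_sample_fit",
    "score_df_curves",
    "concentration_ratio_at_score",
]


@dataclass
class DiscrepancyMaps:
    """Windowed residual statistics on the emission x excitation plane.

    Per cell: ``rmse**2 == bias**2 + sd**2`` exactly (population SD).
    """

    bias: np.ndarray
    rmse: np.ndarray
    sd: np.ndarray
    window_fraction: float
    rma: dict  # {slope, intercept, r2}
    emission_grid: np.ndarray | None = None
    excitation_grid: np.ndarray | None = None


@dataclass
class ScoreCurve:
    """Fitted factor score as a function of dilution factor for one source."""

    factor_id: int
    source_id: str
    points: list[tuple[float, float]]  # (DF, score), DF increasing

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValueError("score curve needs >= 2 points")
        dfs = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(dfs, dfs[1:])):
            raise ValueError("curve DFs must be strictly increasing")

    @property
    def dfs(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def scores(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


def discrepancy_maps(
    observed: EEMTensor | np.ndarray,
    modeled: EEMTensor | np.ndarray,
    window_fraction: float = 0.10,
    emission_grid: np.ndarray | None = None,
    excitation_grid: np.ndarray | None = None,
) -> DiscrepancyMaps:
    """Local bias, RMSE and SD of modeled-minus-observed residuals.

    For each grid cell the window collects every cell within
    ``window_fraction`` of the center wavelength on *both* axes
    (a +/-10% wavelength-proportional 2-D window by default), pooled over
    all samples; windows truncate at grid edges.  RMA regression of all
    modeled on all observed values is attached as a global summary.
    """
    if isinstance(observed, EEMTensor):
        emission_grid = observed.emission_grid
        excitation_grid = observed.excitation_grid
        obs = observed.values
    else:
        obs = np.asarray(observed, dtype=float)
    mod = modeled.values if isinstance(modeled, EEMTensor) else np.asarray(modeled, dtype=float)
    if obs.shape != mod.shape:
        raise AlignmentError(
            f"observed {obs.shape} and modeled {mod.shape} shapes differ")
    I, J, K = obs.shape
    em = np.asarray(emission_grid, dtype=float) if emission_grid is not None else np.arange(J, dtype=float) + 1.0
    ex = np.asarray(excitation_grid, dtype=float) if excitation_grid is not None else np.arange(K, dtype=float) + 1.0

    R = mod - obs
    S1 = R.sum(axis=0)          # sum of residuals over samples, per cell
    S2 = (R * R).sum(axis=0)
    # 2-D prefix sums for O(1) window aggregation
    P1 = np.zeros((J + 1, K + 1))
    P2 = np.zeros((J + 1, K + 1))
    P1[1:, 1:] = np.cumsum(np.cumsum(S1, axis=0), axis=1)
    P2[1:, 1:] = np.cumsum(np.cumsum(S2, axis=0), axis=1)

    # contiguous window index ranges per axis (grids strictly increasing)
    j_lo = np.searchsorted(em, em * (1 - window_fraction), side="left")
    j_hi = np.searchsorted(em, em * (1 + window_fraction), side="right")
    k_lo = np.searchsorted(ex, ex * (1 - window_fraction), side="left")
    k_hi = np.searchsorted(ex, ex * (1 + window_fraction), side="right")

    bias = np.empty((J, K))
    msq = np.empty((J, K))
    count = np.empty((J, K))
    for j in range(J):
        a, b = j_lo[j], j_hi[j]
        for k in range(K):
            c, d = k_lo[k], k_hi[k]
            n = (b - a) * (d - c) * I
            s1 = P1[b, d] - P1[a, d] - P1[b, c] + P1[a, c]
            s2 = P2[b, d] - P2[a, d] - P2[b, c] + P2[a, c]
            bias[j, k] = s1 / n
            msq[j, k] = s2 / n
            count[j, k] = n
    rmse = np.sqrt(np.maximum(msq, 0.0))
    sd = np.sqrt(np.maximum(msq - bias * bias, 0.0))

    try:
        rma = rma_fit(obs.ravel(), mod.ravel())
    except ValueError:
        rma = {"slope": np.nan, "intercept": np.nan, "r2": np.nan}
    return DiscrepancyMaps(bias, rmse, sd, window_fraction, rma, em, ex)


def rma_fit(x: np.ndarray, y: np.ndarray) -> dict:
    """Reduced major axis regression of y on x.

    slope = sign(corr) * sd(y)/sd(x); intercept = mean(y) - slope*mean(x);
    r2 is the squared Pearson correlation.  Symmetric: swapping x and y
    inverts the slope and leaves r2 unchanged.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("RMA needs >= 3 paired points")
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        raise ValueError("RMA undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    return {"slope": float(slope), "intercept": intercept, "r2": r * r}


def per_sample_fit(model: ParafacModel, tensor: EEMTensor) -> pd.DataFrame:
    """Per-sample RMSE, mean fluorescence and their ratio.

    High RMSE/mean flags weakly fluorescent samples whose residual structure
    the model cannot absorb.  The model-level core consistency is attached
    as context; a zero-mean sample gets a NaN ratio.
    """
    X = tensor.values
    resid = X - model.reconstruct()
    rmse = np.sqrt(np.mean(resid * resid, axis=(1, 2)))
    mean_fl = np.mean(np.abs(X), axis=(1, 2))
    ratio = np.where(mean_fl > 0, rmse / np.where(mean_fl > 0, mean_fl, 1.0), np.nan)
    try:
        cc = core_consistency(model, tensor)
    except Exception:
        cc = np.nan
    return pd.DataFrame({
        "sample_id": tensor.sample_ids(),
        "rmse": rmse,
        "mean_fluorescence": mean_fl,
        "rmse_over_mean": ratio,
        "core_consistency_context": cc,
    })


def score_df_curves(
    model: ParafacModel,
    records: list[SampleRecord],
    monotone_rtol: float = 1e-9,
) -> tuple[list[ScoreCurve], pd.DataFrame]:
    """Group fitted scores into per-(factor, source) curves over DF.

    Scores should rise monotonically with DF (fall with dilution) when
    dilution dominates second-order effects; each curve gets a monotonicity
    flag with the offending (DF, DF) pair reported when violated.
    """
    if len(records) != model.A.shape[0]:
        raise ValueError("records do not align with model scores")
    by_source: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        if rec.df is None:
            raise KeyError(f"sample {rec.sample_id!r} has no DF")
        key = rec.source_pool_id or rec.sample_id
        by_source.setdefault(key, []).append(i)
    curves, rows = [], []
    for src, idx in by_source.items():
        idx = sorted(idx, key=lambda i: records[i].df)
        dfs = [records[i].df for i in idx]
        if len(idx) < 2 or any(b <= a for a, b in zip(dfs, dfs[1:])):
            continue
        for f in range(model.F):
            pts = [(records[i].df, float(model.A[i, f])) for i in idx]
            curve = ScoreCurve(f + 1, src, pts)
            s = curve.scores
            tol = monotone_rtol * max(abs(s).max(), 1e-300)
            bad = np.nonzero(np.diff(s) < -tol)[0]
            monotone = bad.size == 0
            offending = None if monotone else (pts[bad[0]][0], pts[bad[0] + 1][0])
            rows.append((f + 1, src, monotone, offending))
            curves.append(curve)
    report = pd.DataFrame(rows, columns=["factor_id", "source_id",
                                         "monotone", "offending_pair"])
    return curves, report


def concentration_ratio_at_score(
    curves: list[ScoreCurve],
    score_level: float = 1000.0,
    reference_source: str | None = None,
    factor_id: int | None = None,
    monotone_rtol: float = 0.05,
) -> dict[str, float]:
    """Concentration ratios between sources at an equal fitted score.

    For each source, the DF reaching ``score_level`` is found by log-log
    linear interpolation along its score curve (dilution series are
    geometric, so interpolation is linear in log space); then
    ``ratio(source) = DF*(reference) / DF*(source)``: a source needing less
    material to reach the same fluorescence is proportionally more
    concentrated.  Every curve must bracket the level.

    Curves must be monotone up to noise: score inversions smaller than
    ``monotone_rtol`` times the curve maximum (the kind left at the noise
    floor of deep dilutions) are absorbed by interpolating on the isotonic
    envelope; larger inversions raise an error.
    """
    if factor_id is not None:
        curves = [c for c in curves if c.factor_id == factor_id]
    if not curves:
        raise ValueError("no curves to compare")
    df_star: dict[str, float] = {}
    for c in curves:
        s, d = c.scores, c.dfs
        env = np.maximum.accumulate(s)
        if np.any(env - s > monotone_rtol * max(env.max(), 1e-300)):
            raise ValueError(
                f"curve {c.source_id!r} factor {c.factor_id} is not monotone")
        s = env
        if not (s.min() <= score_level <= s.max()):
            raise OutOfRangeError(
                f"curve {c.source_id!r} factor {c.factor_id} does not bracket "
                f"score {score_level:g} (range {s.min():g}..{s.max():g})")
        if np.any(s <= 0) or np.any(d <= 0):
            # fall back to linear interpolation if logs are unavailable
            df_star[c.source_id] = float(np.interp(score_level, s, d))
        else:
            df_star[c.source_id] = float(np.exp(
                np.interp(np.log(score_level), np.log(s), np.log(d))))
    if reference_source is None:
        reference_source = curves[0].source_id
    if reference_source not in df_star:
        raise KeyError(f"reference source {reference_source!r} has no curve")
    ref = df_star[reference_source]
    return {src: ref / v for src, v in df_star.items()}
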