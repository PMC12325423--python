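"""Dilution curves, inner-filter-effect detection and thin-limit selection.

At high absorbance the excitation (and to a lesser extent emission) beam is
attenuated inside the cuvette, so fluorescence first saturates and then
*decreases* with concentration - the inner filter effect (IFE).  Trilinear
decomposition assumes fluorescence proportional to concentration ("thin
limit"), so instead of correcting for the IFE, samples whose dilution curves
show it are excluded: only measurements with DF <= 0.0025 enter the fit,
with explicit, logged exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eem_core import EEM, SampleRecord
from .errors import InsufficientDataError, NoSignalError

__all__ = [
    "DilutionCurve",
    "build_dilution_curve",
    "detect_inner_filter",
    "select_thin_limit",
    "THIN_LIMIT_DF",
]

#: Default thin-limit dilution threshold (DF at 1:400).
THIN_LIMIT_DF = 0.0025


@dataclass
class DilutionCurve:
    """Fluorescence at one (excitation, emission) cell across a dilution series."""

    source_id: str
    wavelength_pair: tuple[float, float]   # (excitation nm, emission nm)
    points: list[tuple[float, float]]      # (DF, intensity AU), DF increasing

    def __post_init__(self):
        if len(self.points) < 2:
            raise InsufficientDataError(
                f"dilution curve for {self.source_id!r} needs >= 2 points"
            )
        dfs = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(dfs, dfs[1:])):
            raise ValueError("curve DFs must be strictly increasing")

    @property
    def dfs(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


def build_dilution_curve(
    eems: list[EEM],
    records: list[SampleRecord],
    pair: tuple[float, float] | str = "peak",
) -> DilutionCurve:
    """Curve of intensity vs DF at one wavelength pair across a source's dilutions.

    ``pair="peak"`` uses the argmax cell of the most dilute EEM (least
    distorted by the IFE); otherwise intensities are read at the grid cell
    nearest the requested (excitation, emission) pair - no interpolation, to
    stay faithful to measured cells.
    """
    if len(eems) != len(records):
        raise ValueError("eems and records must align")
    if len(eems) < 2:
        raise InsufficientDataError("need at least 2 dilutions for a curve")
    order = np.argsort([r.df for r in records])
    eems = [eems[i] for i in order]
    records = [records[i] for i in order]
    if pair == "peak":
        most_dilute = eems[0]
        work = np.where(most_dilute.mask, -np.inf, most_dilute.intensity)
        j, k = np.unravel_index(np.argmax(work), work.shape)
        pair = (float(most_dilute.excitation_grid[k]),
                float(most_dilute.emission_grid[j]))
    ex_nm, em_nm = pair
    points = []
    for eem, rec in zip(eems, records):
        k = int(np.argmin(np.abs(eem.excitation_grid - ex_nm)))
        j = int(np.argmin(np.abs(eem.emission_grid - em_nm)))
        points.append((float(rec.df), float(eem.intensity[j, k])))
    source = records[0].source_pool_id or records[0].sample_id
    return DilutionCurve(source, (ex_nm, em_nm), points)


def detect_inner_filter(curve: DilutionCurve, drop_tol: float = 0.05) -> dict:
    """Flag inner-filter behavior on a dilution curve.

    The IFE is declared when the curve's maximum is *not* at the highest
    concentration and the intensity at the largest DF has dropped below
    ``(1 - drop_tol) * max`` - i.e. the curve has turned over rather than
    merely flattened within noise.  Also reports the largest DF up to which
    the intensity/DF ratio stays within ``drop_tol`` of its most-dilute
    value (the operational linear range).
    """
    F = curve.intensities
    dfs = curve.dfs
    if np.all(F == 0):
        raise NoSignalError(f"curve {curve.source_id!r} is all zero")
    imax = int(np.argmax(F))
    flag = bool(imax < len(F) - 1 and F[-1] < (1.0 - drop_tol) * F[imax])
    ratio = F / dfs
    r0 = ratio[0]
    linear_max = dfs[0]
    if r0 > 0:
        for df, r in zip(dfs, ratio):
            if abs(r - r0) <= drop_tol * r0:
                linear_max = df
            else:
                break
    return {
        "flag": flag,
        "peak_DF": float(dfs[imax]),
        "linear_range_max_DF": float(linear_max),
    }


def select_thin_limit(
    records: list[SampleRecord],
    threshold: float = THIN_LIMIT_DF,
    overrides: list[str] | None = None,
) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Keep records with DF <= threshold, plus explicitly overridden ids.

    Returns the included subset (input order preserved) and a per-record
    report with columns (sample_id, DF, decision, reason).  An empty result
    warns rather than fails.
    """
    overrides = set(overrides or [])
    included, rows = [], []
    for rec in records:
        if rec.df <= threshold:
            included.append(rec)
            rows.append((rec.sample_id, rec.df, "included",
                         f"DF <= {threshold:g}"))
        elif rec.sample_id in overrides:
            included.append(rec)
            rows.append((rec.sample_id, rec.df, "included", "override"))
        else:
            rows.append((rec.sample_id, rec.df, "excluded",
                         f"DF > {threshold:g} (inner-filter risk)"))
    report = pd.DataFrame(rows, columns=["sample_id", "DF", "decision", "reason"])
    if not included:
        import warnings

        warnings.warn("thin-limit selection produced an empty sample set",
                      stacklevel=2)
    return included, report
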