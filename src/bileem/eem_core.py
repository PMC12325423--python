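"""Data model for excitation-emission matrices (EEMs) and dilution arithmetic.

An EEM is one fluorescence surface measured over rectangular excitation and
emission wavelength grids; a study is a stack of such surfaces, one per
sample-dilution, aligned on shared grids into a three-way tensor
(samples x emission x excitation).  Dilution factors (DF = c/c0) act as
concentration proxies throughout: the bile fluorophores are not chemically
quantified, so serial dilution is the only concentration axis available.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AlignmentError, FormatError

__all__ = [
    "EEM",
    "SampleRecord",
    "EEMTensor",
    "dilution_factor",
    "parse_dilution_label",
    "serial_dilution_schedule",
    "read_eem",
    "write_eem",
    "stack_eems",
    "read_manifest",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EEM:
    """One excitation-emission fluorescence surface.

    Parameters
    ----------
    excitation_grid, emission_grid
        Strictly increasing wavelength grids in nm.
    intensity
        Fluorescence in arbitrary units (AU), indexed ``[emission, excitation]``.
    mask
        Boolean matrix, same shape as ``intensity``; ``True`` marks excised or
        missing cells.
    meta
        Free-form annotations (sample id, dilution, provenance ...).
    """

    excitation_grid: np.ndarray
    emission_grid: np.ndarray
    intensity: np.ndarray
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.excitation_grid = np.asarray(self.excitation_grid, dtype=float)
        self.emission_grid = np.asarray(self.emission_grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.intensity.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.excitation_grid.ndim != 1 or self.emission_grid.ndim != 1:
            raise ValueError("wavelength grids must be 1-D")
        if np.any(np.diff(self.excitation_grid) <= 0):
            raise ValueError("excitation grid must be strictly increasing")
        if np.any(np.diff(self.emission_grid) <= 0):
            raise ValueError("emission grid must be strictly increasing")
        expected = (self.emission_grid.size, self.excitation_grid.size)
        if self.intensity.shape != expected:
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match grids {expected}"
            )
        if self.mask.shape != self.intensity.shape:
            raise ValueError("mask shape does not match intensity")
        if not np.all(np.isfinite(self.intensity[~self.mask])):
            raise ValueError("non-finite intensity in unmasked cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def copy(self) -> "EEM":
        return EEM(
            self.excitation_grid.copy(),
            self.emission_grid.copy(),
            self.intensity.copy(),
            self.mask.copy(),
            dict(self.meta),
        )

    def same_grids(self, other: "EEM") -> bool:
        return (
            self.excitation_grid.size == other.excitation_grid.size
            and self.emission_grid.size == other.emission_grid.size
            and np.array_equal(self.excitation_grid, other.excitation_grid)
            and np.array_equal(self.emission_grid, other.emission_grid)
        )


_LABEL_RE = re.compile(r"^\s*1\s*:\s*(\d+)\s*$")


@dataclass
class SampleRecord:
    """Provenance and dilution metadata for one measured EEM.

    Exactly one DF source must be supplied: explicit ``df``, a ``"1:N"``
    ``dilution_label``, or the volume pair ``(v0_ul, v_solvent_ul)``.
    """

    sample_id: str
    species: str = "other"          # AME / PIO / other
    condition: str = "other"        # LAB / REF / POLLUT / other
    source_pool_id: str = ""
    v0_ul: float | None = None
    v_solvent_ul: float | None = None
    dilution_label: str | None = None
    df: float | None = None
    blank_id: str = ""

    def __post_init__(self):
        has_vol = self.v0_ul is not None or self.v_solvent_ul is not None
        sources = [self.df is not None, self.dilution_label is not None, has_vol]
        # volumes may accompany an explicit DF (cross-checked below); any
        # other combination is ambiguous
        if sum(sources) != 1 and not (self.df is not None and has_vol
                                      and self.dilution_label is None):
            raise ValueError(
                f"sample {self.sample_id!r}: exactly one of DF, dilution label "
                "or volume pair must be given"
            )
        if self.dilution_label is not None:
            self.df = parse_dilution_label(self.dilution_label)
        elif self.df is None:
            if self.v0_ul is None or self.v_solvent_ul is None:
                raise ValueError(
                    f"sample {self.sample_id!r}: both volumes required"
                )
            self.df = dilution_factor(self.v0_ul, self.v_solvent_ul)
        if not (0.0 < self.df <= 1.0):
            raise ValueError(f"sample {self.sample_id!r}: DF {self.df} outside (0, 1]")
        if self.v0_ul is not None and self.v_solvent_ul is not None and self.df is not None:
            implied = dilution_factor(self.v0_ul, self.v_solvent_ul)
            if abs(implied - self.df) > 1e-12:
                raise ValueError(
                    f"sample {self.sample_id!r}: DF {self.df} inconsistent with volumes"
                )


@dataclass
class EEMTensor:
    """Aligned stack of EEMs ready for trilinear decomposition.

    ``values[i, j, k]`` is the intensity of sample *i* at the *j*-th emission
    and *k*-th excitation wavelength.
    """

    samples: list[SampleRecord]
    emission_grid: np.ndarray
    excitation_grid: np.ndarray
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.emission_grid = np.asarray(self.emission_grid, dtype=float)
        self.excitation_grid = np.asarray(self.excitation_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        I, J, K = self.values.shape
        if I != len(self.samples):
            raise ValueError("sample list length does not match tensor")
        if (J, K) != (self.emission_grid.size, self.excitation_grid.size):
            raise ValueError("tensor shape does not match grids")
        if I < 1:
            raise ValueError("tensor needs at least one sample")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("non-finite values in unmasked cells")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.samples]

    def dfs(self) -> np.ndarray:
        return np.array([r.df for r in self.samples], dtype=float)

    def subset(self, sample_ids: list[str]) -> "EEMTensor":
        index = {r.sample_id: i for i, r in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        idx = [index[s] for s in sample_ids]
        return EEMTensor(
            [self.samples[i] for i in idx],
            self.emission_grid,
            self.excitation_grid,
            self.values[idx],
            self.mask[idx],
        )


# ---------------------------------------------------------------------------
# Dilution arithmetic
# ---------------------------------------------------------------------------

def dilution_factor(v0_ul: float, v_solvent_ul: float) -> float:
    """Concentration fraction after dilution: DF = c/c0 = V0/(V0+Vsolvent)."""
    if not (v0_ul > 0):
        raise ValueError(f"initial volume must be positive, got {v0_ul}")
    if v_solvent_ul < 0:
        raise ValueError(f"solvent volume must be non-negative, got {v_solvent_ul}")
    return v0_ul / (v0_ul + v_solvent_ul)


def parse_dilution_label(label: str) -> float:
    """DF for a ``"1:N"`` label under the initial-to-total-volume convention.

    ``"1:200"`` means 1 part bile in 200 parts total, i.e. DF = 1/200 = 0.005.
    (The alternative initial:solvent reading would give 1/201 and does not
    reproduce any printed DF value.)
    """
    m = _LABEL_RE.match(str(label))
    if not m:
        raise FormatError(f"malformed dilution label {label!r}; expected '1:N'")
    n = int(m.group(1))
    if n < 1:
        raise FormatError(f"dilution label {label!r}: N must be >= 1")
    return 1.0 / n


def serial_dilution_schedule(
    start_label: str, step_factor: int, n: int
) -> list[tuple[str, float]]:
    """Geometric serial-dilution schedule starting at ``start_label``.

    Returns ``n`` pairs ``(label, DF)`` with N multiplied by ``step_factor``
    at each step; DFs are strictly decreasing.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if step_factor < 2:
        raise ValueError("step_factor must be >= 2")
    base = round(1.0 / parse_dilution_label(start_label))
    out = []
    for i in range(n):
        denom = base * step_factor**i
        out.append((f"1:{denom}", 1.0 / denom))
    return out


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------
# On-disk dialect: delimited matrix, cell [0,0] empty, header row = excitation
# wavelengths (nm), first column = emission wavelengths (nm).  Masked cells
# are serialized as empty fields.  The "transposed" dialect swaps the roles.

def _parse_float(token: str, row: int, col: int, path) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"{path}: non-numeric cell {token!r} at row {row}, column {col}"
        ) from None


def read_eem(path, dialect: str = "default", delimiter: str = ",") -> EEM:
    """Read an EEM from a delimited matrix file.

    ``dialect="default"`` expects emission wavelengths down the first column
    and excitation wavelengths across the header; ``"transposed"`` swaps them.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delimiter) if r]
    if len(rows) < 2 or len(rows[0]) < 2:
        raise FormatError(f"{path}: not a wavelength-indexed matrix")
    header = [_parse_float(t, 0, c, path) for c, t in enumerate(rows[0][1:], start=1)]
    ncol = len(rows[0])
    axis0, matrix, mask = [], [], []
    for r, row in enumerate(rows[1:], start=1):
        if len(row) != ncol:
            raise FormatError(
                f"{path}: ragged row {r} ({len(row)} fields, expected {ncol})"
            )
        axis0.append(_parse_float(row[0], r, 0, path))
        vals, miss = [], []
        for c, token in enumerate(row[1:], start=1):
            if token.strip() == "":
                vals.append(np.nan)
                miss.append(True)
            else:
                vals.append(_parse_float(token, r, c, path))
                miss.append(False)
        matrix.append(vals)
        mask.append(miss)
    header_arr = np.array(header)
    axis0_arr = np.array(axis0)
    if np.any(np.diff(header_arr) <= 0):
        raise FormatError(f"{path}: header wavelength row not strictly increasing")
    if np.any(np.diff(axis0_arr) <= 0):
        raise FormatError(f"{path}: first-column wavelengths not strictly increasing")
    intensity = np.array(matrix, dtype=float)
    mask_arr = np.array(mask, dtype=bool)
    intensity[mask_arr] = 0.0
    if dialect == "default":
        em, ex = axis0_arr, header_arr
    elif dialect == "transposed":
        em, ex = header_arr, axis0_arr
        intensity = intensity.T
        mask_arr = mask_arr.T
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return EEM(ex, em, intensity, mask_arr, meta={"path": str(path)})


def write_eem(eem: EEM, path, dialect: str = "default", delimiter: str = ",") -> None:
    """Write an EEM; masked cells become empty fields (round-trip safe)."""
    path = Path(path)
    if dialect == "default":
        header = eem.excitation_grid
        axis0 = eem.emission_grid
        matrix, mask = eem.intensity, eem.mask
    elif dialect == "transposed":
        header = eem.emission_grid
        axis0 = eem.excitation_grid
        matrix, mask = eem.intensity.T, eem.mask.T
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow([""] + [repr(float(x)) for x in header])
        for j, lam in enumerate(axis0):
            row = [repr(float(lam))]
            for k in range(header.size):
                row.append("" if mask[j, k] else repr(float(matrix[j, k])))
            w.writerow(row)


# ---------------------------------------------------------------------------
# Stacking
# ---------------------------------------------------------------------------

def _interp_to_grid(eem: EEM, em_grid: np.ndarray, ex_grid: np.ndarray) -> np.ndarray:
    """Separable linear interpolation of an EEM surface onto new grids.

    Never extrapolates: callers must pass grids inside the EEM's range.
    """
    # emission axis first, then excitation
    tmp = np.empty((em_grid.size, eem.excitation_grid.size))
    for k in range(eem.excitation_grid.size):
        tmp[:, k] = np.interp(em_grid, eem.emission_grid, eem.intensity[:, k])
    out = np.empty((em_grid.size, ex_grid.size))
    for j in range(em_grid.size):
        out[j, :] = np.interp(ex_grid, eem.excitation_grid, tmp[j, :])
    return out


def stack_eems(
    eems: list[EEM], records: list[SampleRecord], regrid: bool = False
) -> EEMTensor:
    """Stack EEMs into a (samples x emission x excitation) tensor.

    Without ``regrid`` every EEM must share identical grids.  With ``regrid``
    each surface is linearly interpolated onto the intersection grid: the
    first EEM's grid points restricted to the wavelength range covered by all
    inputs (no extrapolation ever happens).
    """
    if len(eems) != len(records) or len(eems) < 1:
        raise ValueError("need equal, non-empty lists of EEMs and records")
    ref = eems[0]
    if all(ref.same_grids(e) for e in eems[1:]):
        values = np.stack([e.intensity for e in eems])
        mask = np.stack([e.mask for e in eems])
        return EEMTensor(list(records), ref.emission_grid.copy(),
                         ref.excitation_grid.copy(), values, mask)
    if not regrid:
        raise AlignmentError(
            "EEM wavelength grids differ; pass regrid=True to interpolate"
        )
    em_lo = max(e.emission_grid[0] for e in eems)
    em_hi = min(e.emission_grid[-1] for e in eems)
    ex_lo = max(e.excitation_grid[0] for e in eems)
    ex_hi = min(e.excitation_grid[-1] for e in eems)
    em_grid = ref.emission_grid[(ref.emission_grid >= em_lo) & (ref.emission_grid <= em_hi)]
    ex_grid = ref.excitation_grid[(ref.excitation_grid >= ex_lo) & (ref.excitation_grid <= ex_hi)]
    if em_grid.size == 0 or ex_grid.size == 0:
        raise AlignmentError("EEM wavelength ranges do not overlap")
    values = np.stack([_interp_to_grid(e, em_grid, ex_grid) for e in eems])
    mask = np.zeros(values.shape, dtype=bool)
    return EEMTensor(list(records), em_grid, ex_grid, values, mask)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def read_manifest(path) -> list[tuple[SampleRecord, str]]:
    """Read a sample manifest CSV into (record, eem_path) pairs.

    Columns: sample_id, species, condition, source_pool_id, blank_id,
    eem_path, and one DF source among dilution_label, (V0_uL, Vsolvent_uL)
    or DF.
    """
    import pandas as pd

    frame = pd.read_csv(path, dtype=str)
    if "sample_id" not in frame.columns or "eem_path" not in frame.columns:
        raise FormatError(f"{path}: manifest needs sample_id and eem_path columns")
    out = []
    for _, row in frame.iterrows():
        def get(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) or v == "" else v

        rec = SampleRecord(
            sample_id=str(row["sample_id"]),
            species=get("species") or "other",
            condition=get("condition") or "other",
            source_pool_id=get("source_pool_id") or "",
            v0_ul=float(get("V0_uL")) if get("V0_uL") else None,
            v_solvent_ul=float(get("Vsolvent_uL")) if get("Vsolvent_uL") else None,
            dilution_label=get("dilution_label"),
            df=float(get("DF")) if get("DF") else None,
            blank_id=get("blank_id") or "",
        )
        out.append((rec, str(row["eem_path"])))
    return out
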