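"""Synthetic EEM dilution-study generator with known ground truth.

Emulates the structure of a two-species fish-bile fluorescence study:
excitation 190-400 nm / emission 250-600 nm grids at 5 nm step, seven bile
sources (pooled lab-conditioned AME, lab-conditioned PIO individuals, and
AME from a reference and a polluted river), serial dilutions 1:100 ... 1:6400,
two to three Gaussian fluorophore families (a tryptophan-like peak at
Ex 225 / Em 360 nm and a PIO-dominant peak at Ex 345 / Em 410 nm), blank
background, Rayleigh/Raman scatter ridges, inner-filter attenuation and
measurement noise.  Every random draw is controlled by the scenario seed, and
each generated EEM carries a truth record (clean trilinear surface, loadings,
scores) so recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .eem_core import EEM, SampleRecord, serial_dilution_schedule, write_eem
from .preprocess import DEFAULT_RAMAN_SHIFT, scatter_centers

__all__ = [
    "FluorophoreSpec",
    "SourceSpec",
    "ScenarioConfig",
    "gaussian_profile",
    "make_eem",
    "make_study",
    "default_scenario",
]


@dataclass
class FluorophoreSpec:
    """One Gaussian fluorophore family.

    ``quantum_scale`` converts (concentration x DF) into peak fluorescence
    AU; ``absorptivity`` converts it into absorbance driving the inner
    filter effect.
    """

    name: str
    peak_ex: float      # nm
    peak_em: float      # nm
    fwhm_ex: float      # nm
    fwhm_em: float      # nm
    quantum_scale: float = 1.0
    absorptivity: float = 0.0

    def __post_init__(self):
        if self.peak_em <= self.peak_ex:
            raise ValueError(
                f"{self.name}: emission peak must lie above excitation (Stokes shift)")
        if self.fwhm_ex <= 0 or self.fwhm_em <= 0:
            raise ValueError(f"{self.name}: FWHMs must be positive")
        if self.quantum_scale < 0 or self.absorptivity < 0:
            raise ValueError(f"{self.name}: scales must be non-negative")


@dataclass
class SourceSpec:
    """One bile source: species, condition and fluorophore concentrations."""

    source_id: str
    species: str                        # AME | PIO
    condition: str                      # LAB | REF | POLLUT
    concentrations: dict[str, float]    # fluorophore name -> relative conc

    def __post_init__(self):
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError(f"{self.source_id}: concentrations must be >= 0")


@dataclass
class ScenarioConfig:
    """Full description of a synthetic study."""

    fluorophores: list[FluorophoreSpec]
    sources: list[SourceSpec]
    excitation_start: float = 190.0
    excitation_stop: float = 400.0
    emission_start: float = 250.0
    emission_stop: float = 600.0
    grid_step: float = 5.0
    extend_emission: bool = False   # True -> emission to 650 nm (81 points)
    dilution_start: str = "1:100"
    dilution_factor_step: int = 2
    n_dilutions: int = 7
    blank_amplitude: float = 5.0    # AU, smooth blank background
    ridge_amplitudes: dict = field(default_factory=lambda: {
        "rayleigh1": 300.0, "rayleigh2": 100.0, "raman1": 50.0, "raman2": 20.0})
    ridge_sd_nm: float = 2.0
    blank_ridge_fraction: float = 0.6   # solvent share of ridge height
    raman_shift: float = DEFAULT_RAMAN_SHIFT
    inner_filter: bool = True
    noise_sd: float | None = None   # AU; None -> noise_rel * max clean signal
    noise_rel: float = 0.01
    seed: int = 0

    def excitation_grid(self) -> np.ndarray:
        return np.arange(self.excitation_start, self.excitation_stop + 1e-9,
                         self.grid_step)

    def emission_grid(self) -> np.ndarray:
        stop = 650.0 if self.extend_emission else self.emission_stop
        return np.arange(self.emission_start, stop + 1e-9, self.grid_step)


def default_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """The default seven-source, three-fluorophore study.

    Factor-1 (tryptophan-like) concentrations are planted in the ratio
    POLLUT : REF : LAB : PIO = 16 : 3 : 1 : 0.09, factor 2 follows
    21 : 4 : 1 : 0.25, and factor 3 is ~6x more abundant in PIO than AME.
    Fluorophores 1 and 2 absorb more strongly than 3, so the AME-like
    sources show inner-filter curvature while PIO dilutes linearly.
    """
    fluors = [
        FluorophoreSpec("trp", 225.0, 360.0, 40.0, 55.0,
                        quantum_scale=5.0e4, absorptivity=15.0),
        FluorophoreSpec("f2", 270.0, 450.0, 45.0, 60.0,
                        quantum_scale=3.0e4, absorptivity=10.0),
        FluorophoreSpec("f3", 345.0, 410.0, 45.0, 50.0,
                        quantum_scale=2.5e4, absorptivity=2.0),
    ]
    sources = [
        SourceSpec("AME_LAB_1", "AME", "LAB", {"trp": 1.0, "f2": 1.0, "f3": 1.0}),
        SourceSpec("AME_LAB_2", "AME", "LAB", {"trp": 1.1, "f2": 0.9, "f3": 1.1}),
        SourceSpec("AME_LAB_3", "AME", "LAB", {"trp": 0.9, "f2": 1.1, "f3": 0.9}),
        SourceSpec("AME_REF", "AME", "REF", {"trp": 3.0, "f2": 4.0, "f3": 1.2}),
        SourceSpec("AME_POLLUT", "AME", "POLLUT", {"trp": 16.0, "f2": 21.0, "f3": 1.5}),
        SourceSpec("PIO_LAB_1", "PIO", "LAB", {"trp": 0.09, "f2": 0.25, "f3": 6.0}),
        SourceSpec("PIO_LAB_2", "PIO", "LAB", {"trp": 0.09, "f2": 0.25, "f3": 5.5}),
    ]
    cfg = ScenarioConfig(fluorophores=fluors, sources=sources, seed=seed)
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown scenario field {k!r}")
        setattr(cfg, k, v)
    return cfg


def gaussian_profile(peak: float, fwhm: float, grid: np.ndarray) -> np.ndarray:
    """Unit-maximum Gaussian on a wavelength grid: exp(-4 ln2 (l-peak)^2/fwhm^2)."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    grid = np.asarray(grid, dtype=float)
    return np.exp(-4.0 * np.log(2.0) * (grid - peak) ** 2 / fwhm ** 2)


def _source(scenario: ScenarioConfig, source_id: str) -> SourceSpec:
    for s in scenario.sources:
        if s.source_id == source_id:
            return s
    raise KeyError(f"unknown source {source_id!r}")


def _clean_surface(scenario: ScenarioConfig, src: SourceSpec, df: float):
    """Trilinear signal plus (optional) inner-filter attenuation.

    Linear part: L[j,k] = sum_f conc_f * DF * quantum_f * b_f[j] * c_f[k].
    Inner filter: multiply by 10^(-(A_ex[k] + A_em[j]) / 2) with absorbance
    A = sum_f conc_f * DF * absorptivity_f * (loading) - the standard
    primary+secondary absorption attenuation.
    """
    em = scenario.emission_grid()
    ex = scenario.excitation_grid()
    B = np.stack([gaussian_profile(f.peak_em, f.fwhm_em, em)
                  for f in scenario.fluorophores], axis=1)
    C = np.stack([gaussian_profile(f.peak_ex, f.fwhm_ex, ex)
                  for f in scenario.fluorophores], axis=1)
    conc = np.array([src.concentrations.get(f.name, 0.0)
                     for f in scenario.fluorophores])
    q = np.array([f.quantum_scale for f in scenario.fluorophores])
    scores = conc * df * q
    linear = np.einsum("f,jf,kf->jk", scores, B, C)
    if scenario.inner_filter:
        a = np.array([f.absorptivity for f in scenario.fluorophores])
        A_ex = np.einsum("f,kf->k", conc * df * a, C)
        A_em = np.einsum("f,jf->j", conc * df * a, B)
        atten = 10.0 ** (-(A_ex[None, :] + A_em[:, None]) / 2.0)
        surface = linear * atten
    else:
        surface = linear
    return surface, linear, scores, B, C


def _ridge_surface(scenario: ScenarioConfig, em: np.ndarray,
                   ex: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Gaussian-cross-section scatter ridges along the four scatter lines."""
    out = np.zeros((em.size, ex.size))
    sd = scenario.ridge_sd_nm
    for k, x in enumerate(ex):
        centers = scatter_centers(x, scenario.raman_shift)
        for name, amp in scenario.ridge_amplitudes.items():
            c = centers[name]
            out[:, k] += scale * amp * np.exp(-0.5 * ((em - c) / sd) ** 2)
    return out


def make_blank(scenario: ScenarioConfig, noise_sd: float = 0.0,
               rng: np.random.Generator | None = None) -> EEM:
    """Solvent blank: smooth background plus solvent-level scatter ridges."""
    em = scenario.emission_grid()
    ex = scenario.excitation_grid()
    surface = np.full((em.size, ex.size), scenario.blank_amplitude)
    surface = surface + _ridge_surface(scenario, em, ex,
                                       scale=scenario.blank_ridge_fraction)
    if noise_sd > 0 and rng is not None:
        surface = surface + rng.normal(0.0, noise_sd, surface.shape)
    return EEM(ex, em, surface, meta={"kind": "blank"})


def make_eem(
    scenario: ScenarioConfig,
    source_id: str,
    df: float,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[EEM, dict]:
    """One synthetic sample EEM plus its truth record.

    The truth record carries the clean trilinear surface (before the inner
    filter), the true scores (conc * DF * quantum_scale) and the loading
    matrices, so downstream recovery can be scored against ground truth.
    """
    src = _source(scenario, source_id)
    em = scenario.emission_grid()
    ex = scenario.excitation_grid()
    surface, linear, scores, B, C = _clean_surface(scenario, src, df)
    full = surface + scenario.blank_amplitude + _ridge_surface(scenario, em, ex)
    if noise_sd is None:
        noise_sd = scenario.noise_sd if scenario.noise_sd is not None else 0.0
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(scenario.seed)
        full = full + rng.normal(0.0, noise_sd, full.shape)
    meta = {"source_id": source_id, "DF": df, "synthetic": True}
    truth = {
        "source_id": source_id,
        "DF": df,
        "scores": scores.tolist(),
        "fluorophores": [f.name for f in scenario.fluorophores],
        "linear_surface": linear,
        "attenuated_surface": surface,
        "B": B,
        "C": C,
    }
    return EEM(ex, em, full, meta=meta), truth


def make_study(
    scenario: ScenarioConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Generate the full synthetic study.

    Returns a bundle with per-sample EEMs, sample records, the blank, truth
    records, and the noise level used.  When ``outdir`` is given, EEM CSVs,
    ``manifest.csv`` and ``truth.json`` are also written to disk in the
    pipeline's standard formats.
    """
    if scenario is None:
        scenario = default_scenario()
    rng = np.random.default_rng(scenario.seed)
    schedule = serial_dilution_schedule(
        scenario.dilution_start, scenario.dilution_factor_step,
        scenario.n_dilutions)

    # the noise floor is tied to the brightest clean signal in the study
    if scenario.noise_sd is not None:
        noise_sd = scenario.noise_sd
    else:
        peak = 0.0
        for src in scenario.sources:
            for _, df in schedule:
                surf, *_ = _clean_surface(scenario, src, df)
                peak = max(peak, float(surf.max()))
        noise_sd = scenario.noise_rel * peak

    blank = make_blank(scenario, noise_sd=0.0)
    eems, records, truths = [], [], []
    for src in scenario.sources:
        for label, df in schedule:
            eem, truth = make_eem(scenario, src.source_id, df,
                                  noise_sd=noise_sd, rng=rng)
            sid = f"{src.source_id}@{label.replace(':', '-')}"
            eem.meta["sample_id"] = sid
            truth["sample_id"] = sid
            rec = SampleRecord(
                sample_id=sid, species=src.species, condition=src.condition,
                source_pool_id=src.source_id, dilution_label=label,
                blank_id="blank")
            eems.append(eem)
            records.append(rec)
            truths.append(truth)

    bundle = {
        "scenario": scenario,
        "eems": eems,
        "records": records,
        "blank": blank,
        "truths": truths,
        "noise_sd": noise_sd,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = ["sample_id,species,condition,source_pool_id,dilution_label,"
                "blank_id,eem_path"]
        for eem, rec in zip(eems, records):
            fname = f"{rec.sample_id}.csv"
            write_eem(eem, outdir / fname)
            rows.append(",".join([rec.sample_id, rec.species, rec.condition,
                                  rec.source_pool_id, rec.dilution_label,
                                  rec.blank_id, fname]))
        write_eem(blank, outdir / "blank.csv")
        (outdir / "manifest.csv").write_text("\n".join(rows) + "\n")
        slim = []
        for t in truths:
            slim.append({k: v for k, v in t.items()
                         if k in ("sample_id", "source_id", "DF", "scores",
                                  "fluorophores")})
        payload = {
            "noise_sd": noise_sd,
            "seed": scenario.seed,
            "fluorophores": [asdict(f) for f in scenario.fluorophores],
            "sources": [asdict(s) for s in scenario.sources],
            "samples": slim,
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=1))
    return bundle
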