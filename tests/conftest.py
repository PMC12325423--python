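"""Shared fixtures: synthetic studies and fitted models reused across tests."""

import numpy as np
import pytest

import bileem as bm


def preprocess_study(study):
    """Blank-subtract, excise scatter and interpolate every EEM in a study."""
    return [bm.preprocess_eem(e, blank=study["blank"]) for e in study["eems"]]


def thin_limit_tensor(study, processed=None):
    """Thin-limit selected, stacked tensor plus the kept records."""
    processed = processed if processed is not None else preprocess_study(study)
    included, _ = bm.select_thin_limit(study["records"])
    keep = {r.sample_id for r in included}
    kept = [(e, r) for e, r in zip(processed, study["records"])
            if r.sample_id in keep]
    records = [r for _, r in kept]
    return bm.stack_eems([e for e, _ in kept], records), records


@pytest.fixture(scope="session")
def default_study():
    """The default 7-source noisy study at seed 42."""
    return bm.make_study(bm.default_scenario(seed=42))


@pytest.fixture(scope="session")
def default_fit(default_study):
    """F=3 non-negative fit of the thin-limit default study (seed 42)."""
    tensor, records = thin_limit_tensor(default_study)
    model = bm.fit_parafac(tensor, 3, bm.FitOptions(seed=42))
    return {"tensor": tensor, "records": records, "model": model,
            "study": default_study}


@pytest.fixture(scope="session")
def clean_linear_study():
    """Noise-free, artifact-free study with a deep dilution ladder.

    Four sources planted at factor-1 concentration ratios 16 : 3 : 1 : 0.09;
    with no noise, no inner filter, no blank and no scatter, every surface
    is exactly trilinear and every DF is in the thin limit, so fitted scores
    are exactly proportional to concentration.
    """
    scenario = bm.default_scenario(
        seed=7, noise_sd=0.0, inner_filter=False,
        blank_amplitude=0.0, ridge_amplitudes={},
        dilution_start="1:400", n_dilutions=9)
    scenario.sources = [s for s in scenario.sources if s.source_id in
                        ("AME_POLLUT", "AME_REF", "AME_LAB_1", "PIO_LAB_1")]
    return bm.make_study(scenario)


@pytest.fixture(scope="session")
def clean_linear_fit(clean_linear_study):
    # surfaces are already clean: stack directly, no preprocessing needed
    tensor, records = thin_limit_tensor(clean_linear_study,
                                        processed=clean_linear_study["eems"])
    model = bm.fit_parafac(tensor, 3, bm.FitOptions(seed=7))
    return {"tensor": tensor, "records": records, "model": model}


@pytest.fixture
def small_eem():
    """Tiny 4x3 EEM with simple grids for I/O and arithmetic tests."""
    ex = np.array([200.0, 250.0, 300.0])
    em = np.array([300.0, 350.0, 400.0, 450.0])
    vals = np.arange(12, dtype=float).reshape(4, 3) + 1.0
    return bm.EEM(ex, em, vals, meta={"sample_id": "tiny"})
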