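"""Shared fixtures: model-frame simulators and small synthetic archives."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def simulate_model_frame(
    rng,
    n_countries=8,
    substrate_betas=(0.3, -0.4, 0.6),
    n_species=40,
    sigma_country=0.3,
    sigma_species=0.5,
    k=1.5,
    base=-4.0,
    effort_range=(20, 120),
    slopes=None,
):
    """Simulate a count frame directly from the ZTNB mixed model.

    Exposures are exogenous (drawn per cell), counts are NB per cell and only
    positive cells are kept — exactly the zero-truncated sampling the model
    assumes.  Returns the frame; the true betas are the non-reference
    substrate effects in order S1, S2, ...
    """
    S = len(substrate_betas) + 1
    subs = [f"S{j}" for j in range(S)]
    beta = np.concatenate([[0.0], substrate_betas])
    uc = rng.normal(0, sigma_country, n_countries)
    vg = rng.normal(0, sigma_species, n_species)
    rows = []
    for c in range(n_countries):
        for s in range(S):
            off = np.log(rng.uniform(*effort_range))
            extra = np.zeros(n_species)
            if slopes is not None and s > 0:
                extra = slopes[:, s - 1]
            mu = np.exp(base + beta[s] + uc[c] + vg + extra + off)
            y = rng.negative_binomial(k, k / (k + mu))
            for g in np.nonzero(y)[0]:
                rows.append((f"C{c:02d}", subs[s], f"G{g:03d}", int(y[g]), off))
    return pd.DataFrame(
        rows, columns=["country", "substrateCategory", "species", "y", "log_offset"]
    )


@pytest.fixture(scope="session")
def small_archive():
    """A small synthetic archive with planted indicators and measurable pH."""
    from myxindic.simulate import GeneratorConfig, generate_archive

    cfg = GeneratorConfig(
        n_species=120,
        target_total_records=6000,
        seed=3,
        planted_indicators={"Planted_A": "LIG", "Planted_B": "COR"},
        frac_with_ph=0.05,
    )
    records, truth = generate_archive(cfg)
    return records, truth


@pytest.fixture(scope="session")
def small_model_frame():
    rng = np.random.default_rng(42)
    return simulate_model_frame(rng)
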