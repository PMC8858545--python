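import numpy as np
import pandas as pd
import pytest

from neurometab.synth import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default cohort (9 WT + 11 KO, planted prefrontal signal)."""
    return generate_cohort(CohortSpec(seed=42))


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no genotype effects and no latent coupling."""
    return generate_cohort(
        CohortSpec(seed=43, latent_coupling={}, genotype_effects={})
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def tiny_measurements():
    """A hand-sized long measurement table for filter/derivation tests."""
    rows = []
    for aid, vals in [
        ("A1", {"Cr": (4.0, 10.0), "PCr": (2.0, 12.0), "Glu": (8.0, 5.0),
                "GABA": (2.0, 20.0), "NAA": (7.5, 4.0), "Gln": (3.0, 15.0)}),
        ("A2", {"Cr": (4.2, 50.0), "PCr": (2.1, 8.0), "Glu": (7.9, 6.0),
                "GABA": (2.2, 50.1), "NAA": (7.7, 3.0), "Gln": (2.9, 9.0)}),
    ]:
        for met, (conc, crlb) in vals.items():
            rows.append(
                {"id": aid, "region": "PFC", "metabolite": met,
                 "concentration": conc, "crlb_pct": crlb}
            )
    return pd.DataFrame(rows)
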