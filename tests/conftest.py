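import numpy as np
import pandas as pd
import pytest

from flunipk.simulate import (
    TruePKParameters,
    single_dose_regimen,
)


@pytest.fixture
def lactating_params() -> TruePKParameters:
    """Lactating-doe magnitudes: CL 265 ml/kg/h, V 1400 ml/kg."""
    return TruePKParameters(CL=265.0, V=1400.0)


@pytest.fixture
def iv_single():
    return single_dose_regimen(1.1, "IV")


@pytest.fixture
def sc_single():
    return single_dose_regimen(1.1, "SC")


def make_depletion_frame(n_animals: int = 8,
                         times=(2.0, 4.0, 6.0, 8.0, 12.0, 18.0),
                         c0: float = 100.0,
                         lam: float = 0.1155,
                         resid_sd: float = 0.0,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Log-linear milk depletion records, optionally with ln-scale noise."""
    rows = []
    for a in range(n_animals):
        for t in times:
            ln_c = np.log(c0) - lam * t
            if resid_sd > 0:
                assert rng is not None
                ln_c += rng.normal(0.0, resid_sd)
            rows.append({"animal_id": f"goat-{a + 1:02d}", "time_h": t,
                         "conc_ng_ml": float(np.exp(ln_c))})
    return pd.DataFrame(rows)
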