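import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def two_plate_wells():
    """Two plates with different control means; ratios computed by hand."""
    rows = []
    for plate, ctrl in (("plateA", 10000.0), ("plateB", 20000.0)):
        for i, sig in enumerate((ctrl, ctrl)):
            rows.append(
                dict(plate_id=plate, well=f"A{i + 1:02d}", drug_a_conc_uM=0.0,
                     drug_b_conc_uM=0.0, dose_Gy=0.0, solvent="DMSO",
                     raw_signal=sig, experiment_id="exp01")
            )
        rows.append(
            dict(plate_id=plate, well="B01", drug_a_conc_uM=1.0,
                 drug_b_conc_uM=0.0, dose_Gy=0.0, solvent="DMSO",
                 raw_signal=ctrl / 4, experiment_id="exp01")
        )
    return pd.DataFrame(rows)


def viability_wells(conditions, control_signal=10000.0, experiment_id="exp01"):
    """Build a single-plate well table from {(a, b, dose): viability}."""
    rows = []
    k = 0
    for (a, b, dose), viab in conditions.items():
        k += 1
        rows.append(
            dict(plate_id="plate01", well=f"A{k:02d}", drug_a_conc_uM=a,
                 drug_b_conc_uM=b, dose_Gy=dose, solvent="DMSO",
                 raw_signal=viab * control_signal, experiment_id=experiment_id)
        )
    return pd.DataFrame(rows)
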