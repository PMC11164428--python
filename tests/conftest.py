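import numpy as np
import pandas as pd
import pytest

from isletflux.isotopomer_model import mid_from_isotopomers
from isletflux.nmr_multiplet import multiplet_forward
from isletflux.synthetic_data import (
    GCMS_METABOLITES,
    NMR_METABOLITES,
    default_profiles,
    steady_state,
)


def noiseless_cohort(flux) -> pd.DataFrame:
    """Measurement-space cohort rows (MID channels and multiplet components
    in fraction units) straight from the simulator, no noise."""
    dists = steady_state(flux)
    rows = []
    for met, n in GCMS_METABOLITES:
        mid = mid_from_isotopomers(dists[met])
        for k in range(n + 1):
            rows.append({"metabolite": met, "key": f"m+{k}", "value": mid[k]})
    for met in NMR_METABOLITES:
        fw = multiplet_forward(dists[met])
        for _, r in fw.iterrows():
            rows.append(
                {
                    "metabolite": met,
                    "key": f"C{int(r['position'])}:{r['component']}",
                    "value": r["intensity"],
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def human_profile():
    return default_profiles()[0]


@pytest.fixture(scope="session")
def mouse_profile():
    return default_profiles()[1]
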