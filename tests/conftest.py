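import numpy as np
import pandas as pd
import pytest

from sentnet.data import RegionTable
from sentnet.simulate import GeneratorParams, generate_cohort


def make_region_table(n_pairs: int = 3, volumes=None) -> RegionTable:
    rows = []
    for i in range(n_pairs):
        vol = volumes[i] if volumes is not None else 1000.0 + i
        for hemi, sign in (("L", -1), ("R", 1)):
            rows.append(
                (
                    f"r{i + 1}{hemi}",
                    f"r{i + 1}{hemi}",
                    f"p{i + 1}",
                    hemi,
                    vol,
                    sign * -40.0,
                    0.0,
                    10.0,
                    "",
                )
            )
    return RegionTable(
        pd.DataFrame(
            rows,
            columns=[
                "region_id",
                "abbreviation",
                "pair_id",
                "hemisphere",
                "volume_mm3",
                "mni_x",
                "mni_y",
                "mni_z",
                "network_label",
            ],
        )
    )


@pytest.fixture(scope="session")
def reduced_cohort():
    """A fast 40-pair / 40-subject cohort with full ground truth."""
    return generate_cohort(GeneratorParams.profile("reduced", seed=0))


@pytest.fixture(scope="session")
def reduced_params():
    return GeneratorParams.profile("reduced", seed=0)
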