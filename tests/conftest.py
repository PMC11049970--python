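import numpy as np
import pandas as pd
import pytest

from enteroshift.abundance import ReadCountTable
from enteroshift.synthetic import (
    EffectModel,
    SyntheticDesign,
    build_template,
    default_effects,
    simulate_cohort,
)


def make_table(counts: dict[str, dict[str, int]], meta: dict[str, dict] | None = None) -> ReadCountTable:
    """Small literal count table with minimal metadata."""
    df = pd.DataFrame(counts).T.fillna(0).astype(np.int64)
    if meta is None:
        meta = {
            s: {"rat_id": f"r{i}", "group": "single", "time_point": "0h",
                "environment": "fecal", "is_control": True}
            for i, s in enumerate(df.index)
        }
    mdf = pd.DataFrame(meta).T
    return ReadCountTable(df, mdf)


@pytest.fixture(scope="session")
def template():
    return build_template(n_genera=120, seed=11)


@pytest.fixture(scope="session")
def null_cohort(template):
    """21-rat cohort, five time points, no planted effects."""
    design = SyntheticDesign.default(seed=11)
    return simulate_cohort(design, template, EffectModel())


@pytest.fixture(scope="session")
def effect_cohort(template):
    design = SyntheticDesign.default(seed=12)
    effects = default_effects(template, seed=12)
    return simulate_cohort(design, template, effects)
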