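import numpy as np
import pandas as pd
import pytest

from mrmediate.summarystats import SUMMARY_COLUMNS, HarmonizedData


def make_harmonized(bx, sx, by, sy, ids=None) -> HarmonizedData:
    """Build a HarmonizedData directly from effect arrays."""
    bx = np.asarray(bx, float)
    table = pd.DataFrame(
        {
            "variant_id": ids if ids is not None else [f"v{i}" for i in range(len(bx))],
            "beta_exposure": bx,
            "se_exposure": np.asarray(sx, float),
            "beta_outcome": np.asarray(by, float),
            "se_outcome": np.asarray(sy, float),
        }
    )
    log = pd.DataFrame(columns=["variant_id", "action", "reason"])
    return HarmonizedData(table=table, log=log)


def make_assoc_frame(rows) -> pd.DataFrame:
    """Build a canonical summary-stats frame from dict rows (defaults filled)."""
    defaults = dict(
        chromosome="1",
        position_bp=1000,
        effect_allele="A",
        other_allele="G",
        eaf=0.3,
        beta=0.1,
        se=0.01,
        pvalue=1e-9,
        n=100000.0,
    )
    full = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["variant_id"] = f"rs{i}"
        rec.update(row)
        full.append(rec)
    return pd.DataFrame(full)[SUMMARY_COLUMNS]


@pytest.fixture
def harmonized_from_sim():
    """Merge simulated exposure/outcome frames into a HarmonizedData without
    exercising allele logic (the generator emits identical alleles)."""

    def _build(exposure: pd.DataFrame, outcome: pd.DataFrame) -> HarmonizedData:
        return make_harmonized(
            exposure["beta"], exposure["se"], outcome["beta"], outcome["se"],
            ids=list(exposure["variant_id"]),
        )

    return _build
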