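import numpy as np
import pandas as pd
import pytest

from methylpanel.io import (
    BetaMatrix,
    ReadMethylationRecord,
    RegionOfInterest,
    calls_from_string,
)
from methylpanel.select import MarkerPanel, PanelProbe


def make_read(region: RegionOfInterest, calls: str, read_id: str = "r",
              nm: int = 0, nt: int = 40, mq: float = 35.0) -> ReadMethylationRecord:
    return ReadMethylationRecord(read_id, region.region_id,
                                 calls_from_string(calls), nm, nt, mq)


@pytest.fixture
def region4() -> RegionOfInterest:
    return RegionOfInterest("regA", "chr1", 100, 220, (110, 150, 180, 200))


@pytest.fixture
def tiny_panel() -> MarkerPanel:
    return MarkerPanel(
        "detection",
        (
            PanelProbe("cgL", "low", 0.3),
            PanelProbe("cgH", "high", 0.7),
        ),
    )


@pytest.fixture
def grouped_beta():
    """Hand-built discovery matrix with known group medians.

    Probes:
      pGood   — low ref (0.02, tiny SD), class A tumors at 0.62, all else ~ref
      pNoisy  — low ref median but ref SD ~0.2
      pBadN   — like pGood but class B normals deviated to ~0.32
      pMid    — mid-scale reference (0.5)
      pInter  — classification-style: positive for A (0.8) but class B sits
                intermediate (0.25: not a qualifying tumor shift, yet not
                reference-like either)
      pAll    — positive for both A and B (0.7 both)
    """
    rng = np.random.default_rng(42)
    groups = (
        ["reference"] * 9 + ["A.T"] * 5 + ["A.N"] * 5 + ["B.T"] * 5 + ["B.N"] * 5
    )
    samples = [f"s{i}" for i in range(len(groups))]
    idx = {g: [i for i, x in enumerate(groups) if x == g]
           for g in set(groups)}

    def row(ref, at, an, bt, bn, sd=0.01):
        v = np.empty(len(groups))
        for g, mean in (("reference", ref), ("A.T", at), ("A.N", an),
                        ("B.T", bt), ("B.N", bn)):
            v[idx[g]] = np.clip(rng.normal(mean, sd, len(idx[g])), 0, 1)
        return v

    data = {
        "pGood": row(0.02, 0.62, 0.03, 0.03, 0.03),
        "pNoisy": row(0.05, 0.62, 0.05, 0.05, 0.05, sd=0.2),
        "pBadN": row(0.02, 0.62, 0.03, 0.03, 0.32),
        "pMid": row(0.5, 0.5, 0.5, 0.5, 0.5),
        "pInter": row(0.02, 0.8, 0.03, 0.25, 0.03),
        "pAll": row(0.02, 0.7, 0.03, 0.7, 0.03),
    }
    m = BetaMatrix(pd.DataFrame(data, index=samples).T)
    ann = pd.DataFrame({"group": groups},
                       index=pd.Index(samples, name="sample_id"))
    return m, ann
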