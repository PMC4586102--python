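import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from semscan import BetaMatrix, ProbeAnnotation, SampleSheet


@pytest.fixture
def tiny_beta() -> BetaMatrix:
    df = pd.DataFrame(
        [[0.1, 0.2, 0.3, 0.4], [0.5, 0.5, 0.5, 0.5], [0.9, 0.8, 0.7, 0.6]],
        index=["cg01", "cg02", "cg03"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return BetaMatrix(df)


@pytest.fixture
def tiny_annot() -> ProbeAnnotation:
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": ["cg01", "cg02", "cg03"],
                "chromosome": ["5", "X", "2"],
                "position": [100, 200, 300],
                "gene": ["GENEA", "GENEB", ""],
                "platforms": ["27K;450K", "450K", "27K;450K"],
            }
        )
    )


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "age": [10.0, 40.0, 70.0, 95.0],
                "sex": ["F", "M", "F", "F"],
                "bmi": [18.0, 25.0, np.nan, 27.0],
                "platform": ["450K", "450K", "27K", "27K"],
                "bs_control_intensity": [8000.0, 8000.0, 8000.0, 8000.0],
                "ds_xci": [np.nan, np.nan, 12.0, 30.0],
                "replicate_of": ["", "", "", ""],
            }
        )
    )


def naive_fences(values, k=3.0):
    """Independent brute-force fence oracle: sort and interpolate by hand."""
    v = sorted(float(x) for x in values)
    n = len(v)

    def q(p):
        pos = p * (n - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    q1, q3 = q(0.25), q(0.75)
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def naive_calls(df: pd.DataFrame, k=3.0):
    """Brute-force per-probe fence rule applied cell by cell."""
    out = set()
    for probe, row in df.iterrows():
        lo, hi = naive_fences(row.to_numpy(), k)
        for sample, val in row.items():
            if val > hi:
                out.add((probe, sample, "hyper"))
            elif val < lo:
                out.add((probe, sample, "hypo"))
    return out
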