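import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from concord import CommunityMatrix, SiteMetadata

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_community(values, label="x", sites=None, taxa=None) -> CommunityMatrix:
    values = np.asarray(values, dtype=float)
    sites = sites or [f"S{i:02d}" for i in range(values.shape[0])]
    taxa = taxa or [f"t{j}" for j in range(values.shape[1])]
    return CommunityMatrix(pd.DataFrame(values, index=sites, columns=taxa), label)


def make_metadata(class_counts: dict, rng=None) -> SiteMetadata:
    """Metadata with exactly the requested per-class site counts."""
    rng = rng or np.random.default_rng(0)
    rows = []
    i = 0
    for cls, n in class_counts.items():
        for _ in range(n):
            rows.append(
                {
                    "site_id": f"S{i:03d}",
                    "permanence_class": cls,
                    "days_ponded": float(rng.integers(30, 366)),
                    "max_depth": float(rng.uniform(5, 120)),
                    "amplitude_ratio": float(rng.uniform(0, 1)),
                    "evap_index": float(rng.uniform(0, 1)),
                }
            )
            i += 1
    return SiteMetadata(pd.DataFrame(rows).set_index("site_id"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
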