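import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import subtypesim as st

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def spec() -> st.SyntheticSpec:
    return st.SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def centroids(spec) -> st.CentroidSet:
    return st.make_centroids(spec)


@pytest.fixture(scope="session")
def archetype_suite(spec, centroids):
    """One archetype + repeated measures per subtype, for the four studied subtypes."""
    subtypes = [s for s in centroids.subtype_names if s != "Normal-like"]
    _, suite = st.make_archetype_suite(spec, subtypes=subtypes, centroids=centroids)
    return suite


@pytest.fixture(scope="session")
def sigma_model(archetype_suite) -> st.SigmaModel:
    gaussians = []
    subtype_by_archetype = {}
    for _, subtype, rm in archetype_suite:
        subtype_by_archetype[rm.archetype_id] = subtype
        gaussians.extend(st.fit_gene_gaussians(rm))
    points = st.gaussians_to_points(gaussians, subtype_by_archetype)
    cfg = st.SigmaFitConfig(n_boot=80, seed=5)
    return st.fit_sigma_model(points, cfg)


def symmetric_pair(n_genes: int = 50, seed: int = 0):
    """Two centroids that are gene-permutation images of each other.

    Swapping gene 2i with gene 2i+1 maps one centroid onto the other, so the
    exact midpoint sample is equidistant from both by construction — the
    cleanest possible 50/50 borderline case.
    """
    import pandas as pd

    assert n_genes % 2 == 0
    rng = np.random.default_rng(seed)
    v = rng.uniform(0.0, 10.0, size=n_genes)
    perm = np.arange(n_genes).reshape(-1, 2)[:, ::-1].ravel()
    genes = [f"G{i:03d}" for i in range(n_genes)]
    cents = st.CentroidSet(pd.DataFrame({"A": v, "B": v[perm]}, index=genes))
    midpoint = st.ExpressionProfile(
        "midpoint", pd.Series((v + v[perm]) / 2.0, index=genes)
    )
    return cents, midpoint
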