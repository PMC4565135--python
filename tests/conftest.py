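import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cmapsig import GeneUniverse, PairedExpressionDataset, ReferenceProfile

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_dataset(
    diffs: np.ndarray,
    genes: list[str] | None = None,
    name: str = "toy",
    baseline: float = 8.0,
) -> PairedExpressionDataset:
    """Paired dataset whose tumour-normal differences equal ``diffs`` exactly.

    ``diffs`` is genes x pairs; normal samples sit at a flat baseline so the
    paired t-test sees precisely the requested differences.
    """
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n_genes, n_pairs = diffs.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    tum_ids = [f"s{j}T" for j in range(n_pairs)]
    norm_ids = [f"s{j}N" for j in range(n_pairs)]
    normal = np.full((n_genes, n_pairs), baseline)
    values = pd.DataFrame(
        np.hstack([normal + diffs, normal]),
        index=pd.Index(genes, name="gene_id"),
        columns=tum_ids + norm_ids,
    )
    meta = pd.DataFrame(
        {
            "subject_id": [f"s{j}" for j in range(n_pairs)] * 2,
            "phenotype": ["tumour"] * n_pairs + ["normal"] * n_pairs,
            "stage": ["II"] * (2 * n_pairs),
        },
        index=pd.Index(tum_ids + norm_ids, name="sample_id"),
    )
    return PairedExpressionDataset(
        name=name, values=values, metadata=meta,
        pairs=list(zip(tum_ids, norm_ids)),
    )


def make_profile(
    signed_ranks: dict[str, int],
    compound: str = "cpd",
    replicate_id: str = "r1",
) -> ReferenceProfile:
    return ReferenceProfile(
        compound=compound,
        replicate_id=replicate_id,
        signed_ranks=pd.Series(signed_ranks, dtype=np.int64),
    )


def random_profile(
    N: int, rng: np.random.Generator, compound: str = "cpd", replicate_id: str = "r1"
) -> ReferenceProfile:
    genes = [f"g{i}" for i in range(N)]
    mags = rng.permutation(N) + 1
    signs = rng.choice([-1, 1], size=N)
    return make_profile(
        dict(zip(genes, mags * signs)), compound=compound, replicate_id=replicate_id
    )


@pytest.fixture
def toy_universe() -> GeneUniverse:
    return GeneUniverse(("g0", "g1", "g2", "g3"))
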