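"""Synthetic paired expression studies and reference databases with known truth.

The generator emulates the statistical structure the pipeline assumes:

* several independent paired tumour/normal studies over a shared gene
  universe, with unequal pair counts (default 15/19/4/18/15 — one
  deliberately under-powered 4-pair study);
* a subset of planted differentially expressed genes with log2 effects of a
  chosen size, each present in any given dataset with some probability and
  occasionally sign-flipped, so cross-dataset inconsistency and score
  cancellation are exercised;
* a compound reference database containing null compounds (random signed-rank
  permutations), planted inhibitors whose profiles reverse a chosen query
  signature at the top ranks, and planted mimics that match it.

Every draw is driven by a single integer seed, so studies are byte-identical
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .combine import QuerySignature
from .connectivity import ReferenceDatabase
from .io import GeneUniverse, PairedExpressionDataset

DEFAULT_PAIRS = (15, 19, 4, 18, 15)


@dataclass
class StudyTruth:
    """Ground truth of a generated study: which genes were planted, where."""

    deg_ids: list[str]
    effects: pd.Series                 # signed log2 effect per planted gene
    presence: pd.DataFrame             # planted gene x dataset bool
    flipped: pd.DataFrame              # planted gene x dataset bool

    def effect_in(self, dataset_name: str) -> pd.Series:
        """Realised log2 tumour-normal shift of each planted gene in a dataset."""
        sign = np.where(self.flipped[dataset_name], -1.0, 1.0)
        return self.effects * self.presence[dataset_name] * sign


@dataclass
class ReferenceTruth:
    """Ground truth of a generated reference database."""

    inhibitor_ids: list[str]
    mimic_ids: list[str]
    null_ids: list[str]
    strength: float
    signature: QuerySignature | None = None


@dataclass
class StudyConfig:
    """Generator conditions for a multi-dataset paired study.

    Defaults model a five-cohort design over 2000 genes with 100 planted
    DEGs at 2 log2 units, present in 80% of datasets each, 5% sign flips,
    a residual SD of 0.6 log2 units on the per-pair tumour-normal
    difference (typical paired-array repeatability), and subject-level
    baseline spread of 0.5 log2 units.
    """

    n_datasets: int = 5
    n_genes: int = 2000
    pairs_per_dataset: tuple[int, ...] = DEFAULT_PAIRS
    n_deg: int = 100
    effect_log2: float = 2.0
    presence_prob: float = 0.8
    flip_prob: float = 0.05
    noise_sd: float = 0.6
    subject_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0

    def __post_init__(self) -> None:
        if len(self.pairs_per_dataset) != self.n_datasets:
            raise ValueError("pairs_per_dataset length must equal n_datasets")
        if not 0 <= self.n_deg < self.n_genes:
            raise ValueError("need 0 <= n_deg < n_genes")
        if self.effect_log2 < 0:
            raise ValueError("effect_log2 must be >= 0")
        for p in (self.presence_prob, self.flip_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.pairs_per_dataset) < 2:
            raise ValueError("every dataset needs at least 2 pairs")


def generate_study(
    config: StudyConfig | None = None,
    seed: int | None = None,
    **overrides,
) -> tuple[list[PairedExpressionDataset], StudyTruth]:
    """Generate paired datasets with planted differential expression.

    For gene g and subject j of dataset d the normal-sample value is
    baseline_g + Normal(0, subject_sd) and the tumour value adds the planted
    shift (if g is a planted DEG present in d, possibly sign-flipped) plus
    Normal(0, noise_sd).  Returns the datasets and the :class:`StudyTruth`.
    Keyword overrides patch individual :class:`StudyConfig` fields.
    """
    if config is None:
        config = StudyConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(seed)
    c = config

    genes = [f"g{i:05d}" for i in range(c.n_genes)]
    dataset_names = [f"synth{d + 1}" for d in range(c.n_datasets)]
    deg_idx = np.sort(rng.choice(c.n_genes, size=c.n_deg, replace=False))
    deg_ids = [genes[i] for i in deg_idx]
    effect_signs = rng.choice([-1.0, 1.0], size=c.n_deg)
    effects = pd.Series(effect_signs * c.effect_log2, index=deg_ids, name="effect")
    presence = pd.DataFrame(
        rng.random((c.n_deg, c.n_datasets)) < c.presence_prob,
        index=deg_ids, columns=dataset_names,
    )
    flipped = pd.DataFrame(
        rng.random((c.n_deg, c.n_datasets)) < c.flip_prob,
        index=deg_ids, columns=dataset_names,
    )
    truth = StudyTruth(deg_ids, effects, presence, flipped)

    baseline = rng.normal(c.baseline_mean, c.baseline_sd, size=c.n_genes)
    datasets = []
    for d, (name, n_pairs) in enumerate(zip(dataset_names, c.pairs_per_dataset)):
        delta = np.zeros(c.n_genes)
        realised = truth.effect_in(name)
        delta[deg_idx] = realised.to_numpy()

        subj = rng.normal(0.0, c.subject_sd, size=(c.n_genes, n_pairs))
        normal = baseline[:, None] + subj
        tumour = normal + delta[:, None] + rng.normal(
            0.0, c.noise_sd, size=(c.n_genes, n_pairs)
        )
        tum_ids = [f"{name}_p{j + 1:02d}T" for j in range(n_pairs)]
        norm_ids = [f"{name}_p{j + 1:02d}N" for j in range(n_pairs)]
        values = pd.DataFrame(
            np.hstack([tumour, normal]),
            index=pd.Index(genes, name="gene_id"),
            columns=tum_ids + norm_ids,
        )
        meta = pd.DataFrame(
            {
                "subject_id": [f"{name}_p{j + 1:02d}" for j in range(n_pairs)] * 2,
                "phenotype": ["tumour"] * n_pairs + ["normal"] * n_pairs,
                "stage": ["II"] * (2 * n_pairs),
            },
            index=pd.Index(tum_ids + norm_ids, name="sample_id"),
        )
        datasets.append(
            PairedExpressionDataset(
                name=name, values=values, metadata=meta,
                pairs=list(zip(tum_ids, norm_ids)),
            )
        )
    return datasets, truth


@dataclass
class ReferenceSpec:
    """Composition of a synthetic reference database."""

    n_compounds: int = 200
    n_inhibitors: int = 12
    n_mimics: int = 0
    strength: float = 0.8
    replicates_range: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        if self.n_inhibitors + self.n_mimics > self.n_compounds:
            raise ValueError("planted compounds exceed n_compounds")
        if not 0 < self.strength <= 1:
            raise ValueError("strength must lie in (0, 1]")
        lo, hi = self.replicates_range
        if not 1 <= lo <= hi:
            raise ValueError("replicates_range must satisfy 1 <= lo <= hi")


def _random_profile_row(N: int, rng: np.random.Generator) -> np.ndarray:
    mags = rng.permutation(N) + 1
    signs = rng.choice([-1, 1], size=N)
    return mags * signs


def _planted_profile_row(
    N: int,
    sig_cols: np.ndarray,
    sig_signs: np.ndarray,
    strength: float,
    reverse: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Profile whose top rank magnitudes land on (a fraction of) the signature.

    The leading ``strength`` fraction of the signature genes (signature
    order, i.e. the most important genes first) is forced into the largest
    |rank| positions with signs opposite (inhibitor) or equal (mimic) to the
    signature; every other gene receives the remaining magnitudes in random
    order with random signs.  Replicates share the forced gene set but not
    the magnitude assignment within it.
    """
    m_sig = sig_cols.size
    n_forced = max(1, int(round(strength * m_sig)))
    forced_cols = sig_cols[:n_forced]
    forced_signs = sig_signs[:n_forced] * (-1 if reverse else 1)

    top_mags = np.arange(N, N - n_forced, -1)
    rng.shuffle(top_mags)

    row = np.zeros(N, dtype=np.int64)
    row[forced_cols] = top_mags * forced_signs
    rest_cols = np.setdiff1d(np.arange(N), forced_cols)
    rest_mags = rng.permutation(np.arange(1, N - n_forced + 1))
    rest_signs = rng.choice([-1, 1], size=rest_cols.size)
    row[rest_cols] = rest_mags * rest_signs
    return row


def generate_reference_db(
    universe: GeneUniverse,
    spec: ReferenceSpec | None = None,
    signature: QuerySignature | None = None,
    seed: int | None = None,
    **overrides,
) -> tuple[ReferenceDatabase, ReferenceTruth]:
    """Generate a reference database with planted inhibitors/mimics.

    ``signature`` is the query the planted compounds react to; it is
    required whenever inhibitors or mimics are requested.  Null compounds
    are uniformly random signed-rank permutations.  Replicate counts are
    drawn uniformly from ``spec.replicates_range``; planted structure is
    redrawn per replicate, so replicates agree on the signal but not on the
    noise.
    """
    if spec is None:
        spec = ReferenceSpec(**overrides)
    elif overrides:
        raise ValueError("pass either a spec or keyword overrides, not both")
    if (spec.n_inhibitors or spec.n_mimics) and signature is None:
        raise ValueError("planting inhibitors/mimics requires a signature")
    if signature is not None:
        sig_cols = universe.index_of(signature.genes)
        sig_signs = np.asarray(signature.signs, dtype=np.int64)

    rng = np.random.default_rng(seed)
    N = universe.N
    lo, hi = spec.replicates_range

    inhibitor_ids = [f"inhibitor{i + 1:03d}" for i in range(spec.n_inhibitors)]
    mimic_ids = [f"mimic{i + 1:03d}" for i in range(spec.n_mimics)]
    n_null = spec.n_compounds - spec.n_inhibitors - spec.n_mimics
    null_ids = [f"null{i + 1:04d}" for i in range(n_null)]

    rows, compounds, replicate_ids = [], [], []
    for cid in inhibitor_ids + mimic_ids + null_ids:
        k = int(rng.integers(lo, hi + 1))
        for r in range(k):
            if cid in inhibitor_ids:
                row = _planted_profile_row(
                    N, sig_cols, sig_signs, spec.strength, True, rng
                )
            elif cid in mimic_ids:
                row = _planted_profile_row(
                    N, sig_cols, sig_signs, spec.strength, False, rng
                )
            else:
                row = _random_profile_row(N, rng)
            rows.append(row)
            compounds.append(cid)
            replicate_ids.append(f"{cid}_r{r + 1}")
    database = ReferenceDatabase(
        np.vstack(rows), compounds, replicate_ids, universe, validate=False
    )
    truth = ReferenceTruth(
        inhibitor_ids=inhibitor_ids,
        mimic_ids=mimic_ids,
        null_ids=null_ids,
        strength=spec.strength,
        signature=signature,
    )
    return database, truth
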