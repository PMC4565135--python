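"""Expression-matrix and metadata input/output for paired tumour/normal studies.

A study is a log2-scale genes x samples matrix plus a sample sheet giving,
for every array, the subject it came from, its phenotype (normal or tumour)
and the tumour stage.  Samples are paired within subjects: each subject that
contributed exactly one tumour and one normal array yields one matched pair,
which is the unit of the downstream paired differential-expression analysis.

All files are plain TSV (UTF-8, '.' decimal): the matrix has a ``gene_id``
header column followed by one column per sample; the sample sheet has columns
``sample_id``, ``subject_id``, ``phenotype``, ``stage``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_PHENOTYPES = {"normal": "normal", "tumour": "tumour", "tumor": "tumour"}
_STAGES = {
    "i": "I", "1": "I",
    "ii": "II", "2": "II",
    "iii": "III", "3": "III",
    "iv": "IV", "4": "IV",
}
STAGE_ORDER = ("I", "II", "III", "IV")


def normalize_stage(value: str) -> str:
    """Map Roman or Arabic stage labels onto {'I','II','III','IV'}."""
    key = str(value).strip().lower()
    if key not in _STAGES:
        raise ValueError(f"unrecognised tumour stage {value!r}")
    return _STAGES[key]


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered set of probe/gene identifiers shared by every stage of a run.

    Identifiers are opaque strings (probe-set ids with spaces are fine); order
    is stable so that rank-based scores and reference profiles stay aligned.
    """

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("gene universe must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene universe contains duplicate identifiers")

    @property
    def N(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def index_of(self, genes: Sequence[str]) -> np.ndarray:
        """Positions of ``genes`` within the universe (error if absent)."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        try:
            return np.array([lookup[g] for g in genes], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in universe") from exc


@dataclass
class PairedExpressionDataset:
    """Log2 expression over a gene universe with tumour/normal sample pairing.

    Parameters
    ----------
    name : str
        Dataset label, used in score tables and output file names.
    values : pandas.DataFrame
        Genes x samples log2 intensities; index = gene ids, columns = sample ids.
    metadata : pandas.DataFrame
        Indexed by sample_id with columns subject_id, phenotype, stage.
    pairs : list of (tumour_sample_id, normal_sample_id)
    """

    name: str
    values: pd.DataFrame
    metadata: pd.DataFrame
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids in expression matrix: {dupes[:5]}")
        samples = set(self.values.columns)
        seen: set[str] = set()
        for tum, norm in self.pairs:
            for s in (tum, norm):
                if s not in samples:
                    raise ValueError(f"paired sample {s!r} missing from matrix")
                if s in seen:
                    raise ValueError(f"sample {s!r} appears in more than one pair")
                seen.add(s)
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def universe(self) -> GeneUniverse:
        return GeneUniverse(tuple(self.values.index))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def tumour_matrix(self) -> np.ndarray:
        """Genes x pairs matrix of tumour-sample log2 values."""
        return self.values[[t for t, _ in self.pairs]].to_numpy(dtype=float)

    @property
    def normal_matrix(self) -> np.ndarray:
        """Genes x pairs matrix of the matched normal-sample log2 values."""
        return self.values[[n for _, n in self.pairs]].to_numpy(dtype=float)

    def restrict(self, universe: GeneUniverse) -> "PairedExpressionDataset":
        """Restrict the matrix to ``universe`` (all genes must be present)."""
        missing = [g for g in universe.genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from dataset {self.name!r}: {missing[:5]}")
        return PairedExpressionDataset(
            name=self.name,
            values=self.values.loc[list(universe.genes)],
            metadata=self.metadata,
            pairs=list(self.pairs),
        )


def _build_pairs(metadata: pd.DataFrame) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    for subject, grp in metadata.groupby("subject_id", sort=True):
        tum = grp.index[grp["phenotype"] == "tumour"].tolist()
        norm = grp.index[grp["phenotype"] == "normal"].tolist()
        if len(tum) == 1 and len(norm) == 1:
            pairs.append((tum[0], norm[0]))
        elif len(tum) > 1 or len(norm) > 1:
            logger.warning(
                "subject %r has %d tumour / %d normal samples; dropped",
                subject, len(tum), len(norm),
            )
        else:
            dropped = tum + norm
            logger.warning(
                "subject %r has no matched pair; dropping sample(s) %s",
                subject, dropped,
            )
    return pairs


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV and normalise phenotype/stage labels."""
    try:
        meta = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed metadata TSV {path}: {exc}") from exc
    required = {"sample_id", "subject_id", "phenotype", "stage"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"metadata {path} has duplicate sample_id values")
    meta = meta.set_index("sample_id")
    pheno = meta["phenotype"].str.strip().str.lower()
    bad = pheno[~pheno.isin(_PHENOTYPES)].unique().tolist()
    if bad:
        raise ValueError(f"unrecognised phenotype labels: {bad}")
    meta["phenotype"] = pheno.map(_PHENOTYPES)
    meta["stage"] = meta["stage"].map(normalize_stage)
    return meta


def read_expression(
    matrix_path: str | Path,
    metadata_path: str | Path,
    name: str | None = None,
    linear_input: bool = False,
) -> PairedExpressionDataset:
    """Read an expression matrix and its sample sheet into a paired dataset.

    Pairs are built by matching ``subject_id`` across phenotypes; samples
    without a partner are dropped with a logged warning.  Set
    ``linear_input=True`` when the matrix holds linear-scale intensities,
    which are then log2-transformed on read (downstream fold-change rules
    assume a log2 scale).
    """
    matrix_path = Path(matrix_path)
    try:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed expression TSV {matrix_path}: {exc}") from exc
    if values.index.name != "gene_id":
        raise ValueError(
            f"{matrix_path}: first column must be named 'gene_id', "
            f"got {values.index.name!r}"
        )
    values.index = values.index.astype(str)
    if linear_input:
        if (values.to_numpy() <= 0).any():
            raise ValueError("linear-scale input must be strictly positive")
        values = np.log2(values)

    meta = read_metadata(metadata_path)
    known = [s for s in values.columns if s in meta.index]
    unknown = [s for s in values.columns if s not in meta.index]
    if unknown:
        logger.warning("samples absent from metadata dropped: %s", unknown)
    values = values[known]
    meta = meta.loc[known]
    pairs = _build_pairs(meta)
    if not pairs:
        raise ValueError(f"{matrix_path}: no tumour/normal pairs could be formed")
    keep = [s for pair in pairs for s in pair]
    dataset = PairedExpressionDataset(
        name=name or matrix_path.stem,
        values=values[keep],
        metadata=meta.loc[keep],
        pairs=pairs,
    )
    return dataset


def write_expression(
    dataset: PairedExpressionDataset,
    matrix_path: str | Path,
    metadata_path: str | Path,
    float_format: str = "%.6f",
) -> None:
    """Write a dataset back to the matrix + sample-sheet TSV pair."""
    out = dataset.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t", float_format=float_format)
    meta = dataset.metadata.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t")


def intersect_universes(datasets: Iterable[PairedExpressionDataset]) -> GeneUniverse:
    """Sorted intersection of the gene sets of one or more datasets.

    This is how a shared gene universe is built across array platforms with
    different probe content; every dataset can then be ``restrict``-ed to it.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    common: set[str] = set(datasets[0].values.index)
    for ds in datasets[1:]:
        common &= set(ds.values.index)
    if not common:
        raise ValueError("gene universes have an empty intersection")
    return GeneUniverse(tuple(sorted(common)))


def filter_by_stage(
    dataset: PairedExpressionDataset, stages: Iterable[str]
) -> PairedExpressionDataset:
    """Keep only pairs whose tumour sample is at one of ``stages``.

    Stage groups (e.g. II+III pooled versus IV alone) are how heterogeneous
    cohorts are split into more homogeneous sub-datasets before testing.
    The returned dataset is renamed ``<name>S<group>``.
    """
    wanted = {normalize_stage(s) for s in stages}
    keep_pairs = [
        (t, n) for t, n in dataset.pairs
        if dataset.metadata.loc[t, "stage"] in wanted
    ]
    if not keep_pairs:
        raise ValueError(
            f"no pairs remain in {dataset.name!r} for stages {sorted(wanted)}"
        )
    keep = [s for pair in keep_pairs for s in pair]
    label = "-".join(s for s in STAGE_ORDER if s in wanted)
    return PairedExpressionDataset(
        name=f"{dataset.name}S{label}",
        values=dataset.values[keep],
        metadata=dataset.metadata.loc[keep],
        pairs=keep_pairs,
    )
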