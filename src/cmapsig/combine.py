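"""Signed normalized-rank scoring and cross-dataset signature combination.

Within one dataset the M statistically significant genes are scored by their
significance rank i (1 = most significant):

    score_i = (M - i + 1) / M

so the top gene scores 1 and the last significant gene scores 1/M; dividing
by M makes scores comparable across datasets with very different power.
Non-significant genes score 0, significant genes failing the two-fold-change
biological filter are reset to 0 (after rank assignment — survivors keep
their original (M-i+1)/M values), and every score carries the sign of the
gene's regulation direction (+ up, - down in tumour versus normal).

Across D datasets the per-gene scores are summed into a total score in
[-D, D]; genes regulated in opposite directions in different datasets cancel.
Sorting by |total| descending yields the combined ranking from which query
signatures of any length m are drawn, and under-powered datasets (tiny M)
automatically contribute almost nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexp import DiffExpResults


@dataclass
class DatasetScoreVector:
    """Per-gene signed normalized rank scores for one dataset.

    ``scores`` is indexed by gene id over the full universe; zeros mark
    non-significant or filtered genes.  ``M`` is the size of the
    statistically significant group (None when the vector was built from an
    external table rather than a differential-expression fit).
    """

    dataset_name: str
    scores: pd.Series
    M: int | None = None

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            raise ValueError("score vector has duplicate gene ids")
        if (self.scores.abs() > 1).any():
            raise ValueError("scores must lie in [-1, 1]")

    @property
    def nonzero_count(self) -> int:
        return int((self.scores != 0).sum())


def score_dataset(
    result: DiffExpResults, min_abs_log2_fc: float = 1.0
) -> DatasetScoreVector:
    """Score one dataset's genes by signed normalized significance rank.

    The i-th most significant gene receives (M-i+1)/M signed by its
    regulation direction; significant genes with |mean log2 difference|
    below ``min_abs_log2_fc`` (default 1, i.e. under two-fold change) are
    zeroed after rank assignment, so they consume rank positions but
    contribute nothing.  Non-significant genes score 0.  M = 0 yields an
    all-zero vector.
    """
    frame = result.frame
    scores = pd.Series(0.0, index=frame.index, name=result.dataset_name)
    M = result.M
    if M > 0:
        ranks = np.arange(1, M + 1, dtype=float)
        values = (M - ranks + 1) / M
        sig = frame.loc[result.significant_ids]
        signs = np.sign(sig["mean_log2_diff"].to_numpy())
        passes_fc = np.abs(sig["mean_log2_diff"].to_numpy()) >= min_abs_log2_fc
        scores.loc[result.significant_ids] = values * signs * passes_fc
    return DatasetScoreVector(result.dataset_name, scores, M=M)


@dataclass
class QuerySignature:
    """Ordered gene list with regulation signs (+1 up, -1 down).

    This is the query handed to the connectivity engine: the m genes that
    best characterise the disease state, most important first.
    """

    genes: tuple[str, ...]
    signs: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.signs):
            raise ValueError("genes and signs differ in length")
        if len(self.genes) == 0:
            raise ValueError("signature must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +1 or -1")

    @property
    def m(self) -> int:
        return len(self.genes)

    def flipped(self) -> "QuerySignature":
        """The same genes with every regulation sign negated."""
        return QuerySignature(self.genes, tuple(-s for s in self.signs))

    def drop(self, remove: Sequence[str]) -> "QuerySignature":
        """Remove ``remove`` genes, preserving order and signs of the rest."""
        removed = set(remove)
        kept = [(g, s) for g, s in zip(self.genes, self.signs) if g not in removed]
        if not kept:
            raise ValueError("cannot drop every gene from a signature")
        genes, signs = zip(*kept)
        return QuerySignature(genes, signs)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"gene_id": self.genes, "sign": self.signs}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QuerySignature":
        frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sign": int})
        return cls(tuple(frame["gene_id"]), tuple(frame["sign"]))


class CombinedSignature:
    """Genes ranked by the absolute value of their summed cross-dataset score.

    ``frame`` is ordered by overall rank and holds one column per dataset,
    plus ``total_score``, ``n_nonzero_datasets`` and ``overall_rank``
    (1-based).  Ties in |total| break on the number of contributing datasets
    (descending), then gene id, so rankings are reproducible.
    """

    def __init__(self, frame: pd.DataFrame, dataset_names: list[str]) -> None:
        self.frame = frame
        self.dataset_names = dataset_names

    @property
    def D(self) -> int:
        """Number of datasets combined."""
        return len(self.dataset_names)

    @property
    def total_scores(self) -> pd.Series:
        return self.frame["total_score"]

    @property
    def nonzero_count(self) -> int:
        """Genes with a usable (non-zero) total score."""
        return int((self.frame["total_score"] != 0).sum())

    def take_top(self, m: int) -> QuerySignature:
        """Query signature of the top ``m`` genes; signs follow the totals."""
        if not 1 <= m <= self.nonzero_count:
            raise ValueError(
                f"m={m} outside 1..{self.nonzero_count} "
                "(ranked significant genes exhausted)"
            )
        head = self.frame.iloc[:m]
        signs = tuple(1 if t > 0 else -1 for t in head["total_score"])
        return QuerySignature(tuple(head.index.astype(str)), signs)

    def summary(self, top: int = 10) -> str:
        head = self.frame.head(top)
        lines = [
            f"Combined signature over {self.D} datasets: "
            f"{self.nonzero_count} genes with non-zero total score",
            head.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "ProbeID"
        out.to_csv(path, sep="\t", float_format="%.4f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CombinedSignature":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        names = [
            c for c in frame.columns
            if c not in ("total_score", "n_nonzero_datasets", "overall_rank",
                         "GeneSymbol")
        ]
        return cls(frame, names)


def combine_scores(vectors: Sequence[DatasetScoreVector]) -> CombinedSignature:
    """Sum per-dataset signed scores into an overall ranked signature.

    All vectors must cover the same gene universe.  The result is invariant
    to the order of the input vectors.
    """
    if not vectors:
        raise ValueError("need at least one score vector")
    base = set(vectors[0].scores.index)
    for v in vectors[1:]:
        if set(v.scores.index) != base:
            raise ValueError(
                f"score vector {v.dataset_name!r} covers a different gene universe"
            )
    names = [v.dataset_name for v in vectors]
    if len(set(names)) != len(names):
        raise ValueError("dataset names must be unique")
    frame = pd.concat(
        [v.scores.reindex(vectors[0].scores.index).rename(v.dataset_name)
         for v in vectors],
        axis=1,
    )
    frame["total_score"] = frame[names].sum(axis=1)
    frame["n_nonzero_datasets"] = (frame[names] != 0).sum(axis=1)
    order = pd.DataFrame(
        {
            "gene": frame.index.astype(str),
            "neg_abs_total": -frame["total_score"].abs().to_numpy(),
            "neg_nonzero": -frame["n_nonzero_datasets"].to_numpy(),
        }
    ).sort_values(["neg_abs_total", "neg_nonzero", "gene"], kind="mergesort")
    frame = frame.loc[order["gene"].to_numpy()]
    frame["overall_rank"] = np.arange(1, len(frame) + 1)
    return CombinedSignature(frame, names)
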