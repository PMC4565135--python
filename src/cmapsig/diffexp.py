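"""Per-dataset paired differential expression.

For every gene a classical paired t-test is run on the per-pair tumour minus
normal log2 differences.  Genes are then split into a statistically
significant group and a non-significant group using an adaptive threshold

    p < 1 / (pi0 * N)

where ``N`` is the number of genes analysed and ``pi0`` the estimated
proportion of non-differentially-expressed genes.  The threshold is chosen so
that the expected number of false positives among the significant genes is
one.  A biological filter (|mean log2 difference| >= 1, i.e. two-fold change)
is applied later by the signature combiner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .io import PairedExpressionDataset

Pi0Estimator = Callable[[np.ndarray], float]


def paired_t_test(dataset: PairedExpressionDataset) -> pd.DataFrame:
    """Classical paired t-test per gene on tumour minus normal differences.

    Returns a frame indexed by gene id with columns ``t_stat``, ``p_value``,
    ``mean_log2_diff`` and ``direction`` ('up', 'down' or 'flat').  The t
    statistic has ``n_pairs - 1`` degrees of freedom and p-values are
    two-sided.  Genes whose differences have zero variance are flagged with
    t = 0 and p = 1 (the test is undefined there).
    """
    if dataset.n_pairs < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diffs = dataset.tumour_matrix - dataset.normal_matrix  # genes x pairs
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[degenerate] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[degenerate] = 1.0
    direction = np.where(mean > 0, "up", np.where(mean < 0, "down", "flat"))
    return pd.DataFrame(
        {
            "t_stat": t,
            "p_value": np.clip(p, 0.0, 1.0),
            "mean_log2_diff": mean,
            "direction": direction,
            "zero_variance": degenerate,
        },
        index=dataset.values.index,
    )


def estimate_pi0(p_values: np.ndarray, lambda_: float = 0.5) -> float:
    """Estimate the proportion of true-null genes from a p-value vector.

    Uses the tail estimator pi0 = #{p > lambda} / ((1 - lambda) * n): under
    the null p-values are uniform, so the density above ``lambda`` is almost
    entirely null genes.  The estimate is clamped into (0, 1].  Reasonably
    accurate from a few hundred p-values upward.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("cannot estimate pi0 from an empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < lambda_ < 1:
        raise ValueError("lambda must lie in (0, 1)")
    pi0 = np.mean(p > lambda_) / (1.0 - lambda_)
    return float(np.clip(pi0, 1.0 / p.size, 1.0))


def fixed_pi0(value: float) -> Pi0Estimator:
    """A pi0 'estimator' that ignores the data and returns ``value``."""
    if not 0 < value <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    return lambda p_values: float(value)


def significance_threshold(pi0: float, n_genes: int) -> float:
    """Adaptive p-value threshold 1/(pi0*N) controlling E[false positives]=1."""
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return 1.0 / (pi0 * n_genes)


def fold_change(dataset: PairedExpressionDataset) -> pd.Series:
    """Per-gene linear fold change 2^(mean log2 tumour-normal difference).

    Computed from the mean of per-pair log2 differences (the paired
    geometric-mean ratio), consistent with the paired test.  The biological
    filter used downstream keeps genes with |mean_log2_diff| >= 1, i.e. at
    least two-fold change in either direction.
    """
    mean = (dataset.tumour_matrix - dataset.normal_matrix).mean(axis=1)
    return pd.Series(2.0 ** mean, index=dataset.values.index, name="fold_change")


@dataclass
class DiffExpResults:
    """Fitted per-gene paired differential-expression results for one dataset.

    Attributes
    ----------
    frame : pandas.DataFrame
        Per-gene t_stat, p_value, mean_log2_diff, fold_change, direction,
        significant (bool).
    pi0 : float
        Estimated proportion of non-differentially-expressed genes.
    threshold : float
        Significance threshold 1/(pi0*N).
    significant_ids : list of str
        Significant genes ordered by ascending p (ties: |t| descending,
        then gene id), i.e. the rank order the signature combiner consumes.
    """

    dataset_name: str
    frame: pd.DataFrame
    pi0: float
    threshold: float
    n_genes_analysed: int
    significant_ids: list[str] = field(default_factory=list)

    @property
    def M(self) -> int:
        """Number of statistically significant genes."""
        return len(self.significant_ids)

    def summary(self) -> str:
        lines = [
            f"Paired differential expression: {self.dataset_name}",
            f"  genes analysed      {self.n_genes_analysed}",
            f"  pi0 estimate        {self.pi0:.4f}",
            f"  p-value threshold   {self.threshold:.3e}  (= 1/(pi0*N))",
            f"  significant genes M {self.M}",
        ]
        if self.M:
            top = self.significant_ids[0]
            lines.append(f"  top gene            {top} "
                         f"(p={self.frame.loc[top, 'p_value']:.2e})")
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["significant"] = out["significant"].astype(int)
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


class PairedDiffExp:
    """Paired differential-expression model for one tumour/normal dataset.

    Parameters
    ----------
    dataset : PairedExpressionDataset
    pi0_estimator : callable, optional
        Maps the p-value vector to a pi0 estimate; defaults to the tail
        estimator :func:`estimate_pi0`.  Use :func:`fixed_pi0` to pin it.
    n_genes_analysed : int, optional
        The N of the 1/(pi0*N) threshold; defaults to the number of genes in
        the dataset's universe.

    Examples
    --------
    >>> results = PairedDiffExp(dataset).fit()
    >>> results.M, results.threshold  # doctest: +SKIP
    """

    def __init__(
        self,
        dataset: PairedExpressionDataset,
        pi0_estimator: Pi0Estimator | None = None,
        n_genes_analysed: int | None = None,
    ) -> None:
        self.dataset = dataset
        self.pi0_estimator = pi0_estimator or estimate_pi0
        self.n_genes_analysed = n_genes_analysed or len(dataset.universe)

    def fit(self) -> DiffExpResults:
        tests = paired_t_test(self.dataset)
        pi0 = float(self.pi0_estimator(tests["p_value"].to_numpy()))
        if not 0 < pi0 <= 1:
            raise ValueError(f"pi0 estimator returned {pi0}, outside (0, 1]")
        threshold = significance_threshold(pi0, self.n_genes_analysed)
        frame = tests.copy()
        frame["fold_change"] = fold_change(self.dataset)
        frame["significant"] = frame["p_value"] < threshold

        sig = frame[frame["significant"]]
        # deterministic rank order: p ascending, |t| descending, gene id
        order = pd.DataFrame(
            {
                "gene": sig.index.astype(str),
                "p": sig["p_value"].to_numpy(),
                "neg_abs_t": -sig["t_stat"].abs().to_numpy(),
            }
        ).sort_values(["p", "neg_abs_t", "gene"], kind="mergesort")
        return DiffExpResults(
            dataset_name=self.dataset.name,
            frame=frame,
            pi0=pi0,
            threshold=threshold,
            n_genes_analysed=self.n_genes_analysed,
            significant_ids=order["gene"].tolist(),
        )


def run_diffexp(
    dataset: PairedExpressionDataset,
    pi0: float | Pi0Estimator | None = None,
    n_genes_analysed: int | None = None,
) -> DiffExpResults:
    """Functional wrapper around :class:`PairedDiffExp`.

    ``pi0`` may be a fixed float, a custom estimator, or None for the
    default tail estimator.
    """
    estimator: Pi0Estimator | None
    if pi0 is None:
        estimator = None
    elif callable(pi0):
        estimator = pi0
    else:
        estimator = fixed_pi0(float(pi0))
    return PairedDiffExp(dataset, estimator, n_genes_analysed).fit()
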