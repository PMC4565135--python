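"""Signature-length selection by FDR-guided progression.

Rather than fixing the query-signature length a priori, the signature is
grown gene by gene from the top of the combined ranking.  At each length m
the connectivity engine counts the significant drug hits Ns in the desired
direction (negative scores, i.e. candidate inhibitors); the empirical false
discovery rate is Efp/Ns, the tolerated number of false-positive compounds
divided by the number of hits.  The progression stops at the first m whose
FDR reaches the target (with Efp=1 and a 0.10 target this means at least 10
hits), or when the ranked genes with non-zero total score are exhausted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .combine import CombinedSignature
from .connectivity import ConnectionResults, ConnectivityMap, ReferenceDatabase


def fdr_of(Ns: int, Efp: float = 1.0) -> float:
    """Empirical FDR Efp/Ns of a hit list; +inf when there are no hits."""
    if Efp <= 0:
        raise ValueError("Efp must be positive")
    if Ns < 0:
        raise ValueError("Ns must be >= 0")
    return math.inf if Ns == 0 else Efp / Ns


@dataclass
class ProgressionConfig:
    """Tuning knobs of the signature-length progression.

    Efp is the tolerated expected number of false-positive compound
    connections (sets the per-compound threshold Efp/Nc); fdr_target the
    stopping FDR; m grows from m_start in steps of m_step up to m_max
    (None: until the non-zero-total genes run out).
    """

    Efp: float = 1.0
    fdr_target: float = 0.10
    m_start: int = 1
    m_step: int = 1
    m_max: int | None = None

    def __post_init__(self) -> None:
        if self.Efp <= 0:
            raise ValueError("Efp must be positive")
        if not 0 < self.fdr_target < 1:
            raise ValueError("fdr_target must lie in (0, 1)")
        if self.m_start < 1 or self.m_step < 1:
            raise ValueError("m_start and m_step must be >= 1")


@dataclass
class ProgressionState:
    """Outcome of a progression run.

    ``trace`` records (m, Ns, FDR) for every visited length; ``final_m`` is
    the first length whose FDR met the target, or — when ``exhausted`` — the
    visited length with the most hits (smallest such m on ties).
    """

    trace: pd.DataFrame
    final_m: int
    exhausted: bool
    final_hits: pd.DataFrame
    final_results: ConnectionResults
    config: ProgressionConfig = field(default_factory=ProgressionConfig)

    @property
    def Ns(self) -> int:
        return len(self.final_hits)

    @property
    def fdr(self) -> float:
        return fdr_of(self.Ns, self.config.Efp)

    def summary(self) -> str:
        status = "exhausted ranked genes" if self.exhausted else "FDR target met"
        lines = [
            "Gene-signature progression",
            f"  status          {status}",
            f"  final length m  {self.final_m}",
            f"  drug hits Ns    {self.Ns}",
            f"  empirical FDR   {self.fdr:.4g}  (target {self.config.fdr_target})",
            f"  lengths visited {len(self.trace)}",
        ]
        if self.Ns:
            lines.append("  hits: " + ", ".join(self.final_hits.index.astype(str)))
        return "\n".join(lines)

    def trace_to_tsv(self, path: str | Path) -> None:
        out = self.trace.copy()
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _seed_for_m(seed: int | None, m: int) -> np.random.SeedSequence:
    entropy = 0 if seed is None else seed
    return np.random.SeedSequence(entropy=entropy, spawn_key=(m,))


def run_progression(
    combined: CombinedSignature,
    database: ReferenceDatabase,
    config: ProgressionConfig | None = None,
    n_null: int = 2000,
    seed: int | None = None,
) -> ProgressionState:
    """Grow the query signature until the drug-hit FDR reaches its target.

    At each visited m the top-m signature is scored against every compound
    with a fresh Monte-Carlo null (deterministically derived from ``seed``
    and m, so the trace is bit-reproducible and lengths are independent) and
    hits are counted among negative-score connections at p <= Efp/Nc.
    Returns the first-passage state, or the best (max Ns) visited state with
    ``exhausted=True`` if no length meets the target.
    """
    config = config or ProgressionConfig()
    if combined.nonzero_count == 0:
        raise ValueError("combined signature has no genes with non-zero score")
    engine = ConnectivityMap(database)
    m_cap = combined.nonzero_count
    if config.m_max is not None:
        m_cap = min(m_cap, config.m_max)
    if config.m_start > m_cap:
        raise ValueError(f"m_start={config.m_start} exceeds usable genes ({m_cap})")

    rows: list[dict] = []
    best: tuple[int, int, ConnectionResults] | None = None  # (Ns, -m) ordering
    for m in range(config.m_start, m_cap + 1, config.m_step):
        signature = combined.take_top(m)
        m_seed = _seed_for_m(seed, m)
        results = engine.query(
            signature,
            n_null=n_null,
            seed=m_seed,
            efp=config.Efp,
            direction_filter="negative",
        )
        hits = results.significant("negative")
        Ns = len(hits)
        fdr = fdr_of(Ns, config.Efp)
        rows.append({"m": m, "Ns": Ns, "FDR": fdr})
        if best is None or Ns > best[0]:
            best = (Ns, m, results)
        if fdr <= config.fdr_target:
            trace = pd.DataFrame(rows)
            return ProgressionState(
                trace=trace, final_m=m, exhausted=False,
                final_hits=hits, final_results=results, config=config,
            )
    assert best is not None
    _, best_m, best_results = best
    trace = pd.DataFrame(rows)
    return ProgressionState(
        trace=trace,
        final_m=best_m,
        exhausted=True,
        final_hits=best_results.significant("negative"),
        final_results=best_results,
        config=config,
    )
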