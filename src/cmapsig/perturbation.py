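"""Perturbation stability of significant drug connections.

A connection that survives only for one exact gene list is fragile.  To
gauge robustness, the final query signature is perturbed by removing a small
number of genes and every hit compound is re-tested for significance under
each perturbed signature (same Efp/Nc threshold, same negative-direction
filter).  The stability score of a compound is the fraction of perturbations
under which its connection remains significant: 1.0 means the hit does not
depend on any particular gene of the signature.

The default perturbation is the smallest one: single-gene removal,
enumerated exhaustively (all m leave-one-out signatures) when m is modest,
otherwise a fixed number of random removals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .combine import QuerySignature
from .connectivity import ConnectivityMap, ReferenceDatabase


@dataclass
class PerturbationConfig:
    """How to perturb: remove ``n_remove`` genes per perturbation.

    mode 'exhaustive' enumerates all leave-one-out signatures (n_remove must
    be 1); 'random' draws ``n_perturbations`` independent removals; 'auto'
    picks exhaustive leave-one-out when n_remove == 1 and m <= exhaustive_max_m.
    """

    n_remove: int = 1
    n_perturbations: int = 200
    mode: str = "auto"
    exhaustive_max_m: int = 200

    def __post_init__(self) -> None:
        if self.n_remove < 1:
            raise ValueError("n_remove must be >= 1 (no-op perturbation rejected)")
        if self.n_perturbations < 1:
            raise ValueError("n_perturbations must be >= 1")
        if self.mode not in ("auto", "exhaustive", "random"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")


@dataclass
class StabilityResult:
    compound: str
    n_perturbations: int
    n_retained: int

    @property
    def stability(self) -> float:
        return self.n_retained / self.n_perturbations


def perturb_signature(
    signature: QuerySignature,
    n_remove: int,
    n_perturbations: int,
    seed: int | None = None,
    mode: str = "random",
) -> list[QuerySignature]:
    """Perturbed copies of a signature, each missing ``n_remove`` genes.

    Order and signs of the surviving genes are preserved.  'exhaustive'
    mode (n_remove=1) returns the m leave-one-out signatures and ignores the
    seed; 'random' mode draws ``n_perturbations`` independent uniform
    subsets without replacement within each perturbation.
    """
    m = signature.m
    if not 1 <= n_remove < m:
        raise ValueError(f"n_remove={n_remove} must satisfy 1 <= n_remove < m={m}")
    if mode == "exhaustive":
        if n_remove != 1:
            raise ValueError("exhaustive mode enumerates single-gene removals only")
        return [signature.drop([g]) for g in signature.genes]
    if mode != "random":
        raise ValueError(f"unknown perturbation mode {mode!r}")
    rng = np.random.default_rng(seed)
    out = []
    genes = np.asarray(signature.genes, dtype=object)
    for _ in range(n_perturbations):
        removed = rng.choice(genes, size=n_remove, replace=False)
        out.append(signature.drop(list(removed)))
    return out


def _resolve_mode(config: PerturbationConfig, m: int) -> str:
    if config.mode != "auto":
        return config.mode
    if config.n_remove == 1 and m <= config.exhaustive_max_m:
        return "exhaustive"
    return "random"


def stability_scores(
    signature: QuerySignature,
    database: ReferenceDatabase,
    hits: Sequence[str] | pd.DataFrame,
    config: PerturbationConfig | None = None,
    efp: float = 1.0,
    n_null: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Perturbation-stability score of each hit compound.

    ``hits`` is the list of compounds significant under the unperturbed
    signature (or the hits frame from the connectivity engine).  For every
    perturbed signature, each hit is re-queried against its own replicate
    profiles with the full-database Nc in the threshold and the
    negative-direction filter; the returned frame has one row per compound
    with ``n_perturbations``, ``n_retained``, ``stability`` and the
    perturbation mode used.
    """
    config = config or PerturbationConfig()
    if isinstance(hits, pd.DataFrame):
        compounds = list(hits.index.astype(str))
    else:
        compounds = list(hits)
    if not compounds:
        raise ValueError("hits list is empty; nothing to score")

    mode = _resolve_mode(config, signature.m)
    perturbed = perturb_signature(
        signature,
        n_remove=config.n_remove,
        n_perturbations=config.n_perturbations,
        seed=seed,
        mode=mode,
    )
    engine = ConnectivityMap(database)
    retained = {c: 0 for c in compounds}
    for k, sig_k in enumerate(perturbed):
        sub_seed = np.random.SeedSequence(
            entropy=0 if seed is None else seed, spawn_key=(k,)
        )
        res = engine.query(
            sig_k,
            n_null=n_null,
            seed=sub_seed,
            efp=efp,
            direction_filter="negative",
            compounds=compounds,
        )
        still = set(res.significant("negative").index.astype(str))
        for c in compounds:
            if c in still:
                retained[c] += 1
    n_pert = len(perturbed)
    frame = pd.DataFrame(
        {
            "n_perturbations": n_pert,
            "n_retained": [retained[c] for c in compounds],
        },
        index=pd.Index(compounds, name="compound"),
    )
    frame["stability"] = frame["n_retained"] / n_pert
    frame["mode"] = mode
    return frame
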