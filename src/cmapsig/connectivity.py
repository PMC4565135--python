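"""Signed-rank connectivity mapping of query signatures against compound profiles.

A reference profile encodes one compound treatment as signed ranks over the
gene universe: the gene most perturbed by the compound carries magnitude N
(the universe size), the least perturbed magnitude 1, and the sign gives the
regulation direction.  A query signature of m signed genes is scored against
a profile by

    cscore = sum_i s_i * r(g_i) / (N + (N-1) + ... + (N-m+1))

where s_i is the signature sign and r(g) the profile's signed rank.  The
denominator is the largest attainable |sum|, so cscore lies in [-1, 1]:
+1 means the compound's strongest genes coincide with the signature in the
same directions (the compound mimics the state), -1 perfect reversal (a
candidate inhibitor).

Statistical significance comes from a null of random signatures: uniformly
drawn gene subsets of the same size with independent random signs.  P-values
are one-sided in the direction of the observed score, exact by enumeration
on small universes and Monte-Carlo with a (r+1)/(n+1) pseudocount otherwise.
Compounds with several replicate profiles are scored by the mean replicate
cscore, with the null built on the same mean.  A connection is declared
significant at p <= Efp/Nc, which caps the expected number of false-positive
compounds at Efp across the whole database of Nc compounds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .combine import QuerySignature
from .io import GeneUniverse

_EXHAUSTIVE_LIMIT = 1_000_000
_EXHAUSTIVE_QUERY_LIMIT = 20_000
_NULL_CHUNK = 512


@dataclass
class ReferenceProfile:
    """One replicate treatment profile: signed ranks over the gene universe."""

    compound: str
    replicate_id: str
    signed_ranks: pd.Series  # indexed by gene id; values in {-N..-1, 1..N}

    def __post_init__(self) -> None:
        mags = np.sort(np.abs(self.signed_ranks.to_numpy(dtype=np.int64)))
        n = len(mags)
        if n == 0 or not np.array_equal(mags, np.arange(1, n + 1)):
            raise ValueError(
                f"profile {self.compound}/{self.replicate_id}: rank magnitudes "
                "must be a permutation of 1..N with no zeros"
            )


class ReferenceDatabase:
    """A compound reference database held as a profiles x genes rank matrix.

    Parameters
    ----------
    ranks : ndarray of shape (P, N), integer
        Signed ranks; each row's magnitudes are a permutation of 1..N.
    compounds, replicate_ids : sequences of length P
    universe : GeneUniverse
        Column order of ``ranks``.
    """

    def __init__(
        self,
        ranks: np.ndarray,
        compounds: Sequence[str],
        replicate_ids: Sequence[str],
        universe: GeneUniverse,
        validate: bool = True,
    ) -> None:
        ranks = np.asarray(ranks, dtype=np.int64)
        if ranks.ndim != 2 or ranks.shape[1] != universe.N:
            raise ValueError("ranks must be P x N over the universe")
        if not len(compounds) == len(replicate_ids) == ranks.shape[0]:
            raise ValueError("compounds/replicate_ids must match ranks rows")
        if validate:
            expect = np.arange(1, universe.N + 1)
            mags = np.sort(np.abs(ranks), axis=1)
            if not (mags == expect).all():
                raise ValueError("each profile's magnitudes must permute 1..N")
        self.ranks = ranks
        self.compounds = np.asarray(compounds, dtype=object)
        self.replicate_ids = np.asarray(replicate_ids, dtype=object)
        self.universe = universe

    @property
    def n_profiles(self) -> int:
        return self.ranks.shape[0]

    @property
    def compound_names(self) -> list[str]:
        return sorted(set(self.compounds.tolist()))

    @property
    def Nc(self) -> int:
        """Number of distinct compounds (the Nc of the Efp/Nc threshold)."""
        return len(set(self.compounds.tolist()))

    def profile(self, i: int) -> ReferenceProfile:
        return ReferenceProfile(
            compound=str(self.compounds[i]),
            replicate_id=str(self.replicate_ids[i]),
            signed_ranks=pd.Series(self.ranks[i], index=list(self.universe.genes)),
        )

    def profiles_of(self, compound: str) -> np.ndarray:
        """Row indices of the replicates of ``compound``."""
        idx = np.flatnonzero(self.compounds == compound)
        if idx.size == 0:
            raise KeyError(f"compound {compound!r} not in reference database")
        return idx

    @classmethod
    def from_profiles(cls, profiles: Sequence[ReferenceProfile]) -> "ReferenceDatabase":
        if not profiles:
            raise ValueError("need at least one profile")
        genes = tuple(profiles[0].signed_ranks.index)
        universe = GeneUniverse(genes)
        ranks = np.vstack(
            [p.signed_ranks.reindex(list(genes)).to_numpy(dtype=np.int64)
             for p in profiles]
        )
        return cls(
            ranks,
            [p.compound for p in profiles],
            [p.replicate_id for p in profiles],
            universe,
        )

    def to_tsv(self, path: str | Path) -> None:
        """Long-format TSV: compound, replicate_id, gene_id, signed_rank."""
        P, N = self.ranks.shape
        frame = pd.DataFrame(
            {
                "compound": np.repeat(self.compounds, N),
                "replicate_id": np.repeat(self.replicate_ids, N),
                "gene_id": np.tile(np.asarray(self.universe.genes, dtype=object), P),
                "signed_rank": self.ranks.ravel(),
            }
        )
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceDatabase":
        frame = pd.read_csv(
            path, sep="\t",
            dtype={"compound": str, "replicate_id": str, "gene_id": str,
                   "signed_rank": np.int64},
        )
        required = {"compound", "replicate_id", "gene_id", "signed_rank"}
        if missing := required - set(frame.columns):
            raise ValueError(f"reference TSV missing columns {sorted(missing)}")
        genes = tuple(sorted(frame["gene_id"].unique()))
        universe = GeneUniverse(genes)
        wide = frame.pivot_table(
            index=["compound", "replicate_id"], columns="gene_id",
            values="signed_rank", aggfunc="first",
        )
        if wide.isna().any().any():
            raise ValueError("every profile must cover the full gene universe")
        wide = wide[list(genes)]
        compounds = [c for c, _ in wide.index]
        reps = [r for _, r in wide.index]
        return cls(wide.to_numpy(dtype=np.int64), compounds, reps, universe)


def _signature_columns(
    signature: QuerySignature, universe: GeneUniverse
) -> tuple[np.ndarray, np.ndarray]:
    idx = universe.index_of(signature.genes)
    signs = np.asarray(signature.signs, dtype=np.int64)
    return idx, signs


def max_possible_sum(N: int, m: int) -> int:
    """Largest attainable |signed-rank sum| for an m-gene signature: sum N..N-m+1."""
    if not 1 <= m <= N:
        raise ValueError(f"signature length m={m} outside 1..N={N}")
    return m * N - m * (m - 1) // 2


def connection_score(signature: QuerySignature, profile: ReferenceProfile) -> float:
    """Normalized signed-rank agreement between signature and profile, in [-1,1]."""
    universe = GeneUniverse(tuple(profile.signed_ranks.index))
    idx, signs = _signature_columns(signature, universe)
    ranks = profile.signed_ranks.to_numpy(dtype=np.int64)
    raw = int(np.dot(signs, ranks[idx]))
    return raw / max_possible_sum(universe.N, signature.m)


def _sample_null_signatures(
    N: int, m: int, n_null: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random gene-index subsets (without replacement) and independent signs."""
    keys = rng.random((n_null, N))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m] if m < N else \
        np.tile(np.arange(N), (n_null, 1))
    signs = rng.integers(0, 2, size=(n_null, m)) * 2 - 1
    return idx, signs


def _enumerate_signatures(N: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Index/sign arrays of every signed m-gene signature over N genes."""
    combos = np.array(list(itertools.combinations(range(N), m)), dtype=np.intp)
    patterns = np.array(
        list(itertools.product((1, -1), repeat=m)), dtype=np.int64
    )
    idx = np.repeat(combos, len(patterns), axis=0)
    signs = np.tile(patterns, (len(combos), 1))
    return idx, signs


def _null_raw_scores(
    ranks: np.ndarray, idx: np.ndarray, signs: np.ndarray
) -> np.ndarray:
    """Raw signed-rank sums of each null signature against each profile.

    Returns an (n_null, P) matrix; chunked to bound memory.
    """
    n_null = idx.shape[0]
    P = ranks.shape[0]
    out = np.empty((n_null, P), dtype=np.int64)
    for start in range(0, n_null, _NULL_CHUNK):
        stop = min(start + _NULL_CHUNK, n_null)
        gathered = ranks[:, idx[start:stop]]          # (P, chunk, m)
        out[start:stop] = np.einsum(
            "pkm,km->kp", gathered, signs[start:stop]
        )
    return out


def _one_sided_p(observed: float, null: np.ndarray, pseudocount: bool) -> float:
    """One-sided tail probability in the direction of the observed score."""
    if observed >= 0:
        hits = int((null >= observed).sum())
    else:
        hits = int((null <= observed).sum())
    if pseudocount:
        return (hits + 1) / (null.size + 1)
    return hits / null.size


def exhaustive_null_scores(ranks_row: np.ndarray, m: int) -> np.ndarray:
    """All raw scores over every size-m signed signature (the exact null).

    Enumerates C(N, m) * 2^m signatures; feasible for small N and m only.
    """
    N = ranks_row.size
    sign_patterns = np.array(
        list(itertools.product((1, -1), repeat=m)), dtype=np.int64
    )
    scores = []
    for subset in itertools.combinations(range(N), m):
        vals = ranks_row[list(subset)]
        scores.append(sign_patterns @ vals)
    return np.concatenate(scores)


def profile_p_value(
    signature: QuerySignature,
    profile: ReferenceProfile,
    n_null: int = 2000,
    seed: int | None = None,
    method: str = "auto",
) -> float:
    """One-sided p-value of a signature/profile connection score.

    The null draws random signatures: uniform gene subsets of size m with
    independent uniform signs.  ``method`` is 'exhaustive' (exact
    enumeration), 'mc' (Monte-Carlo with an (r+1)/(n+1) pseudocount, so p is
    never 0) or 'auto', which enumerates exactly whenever
    C(N, m) * 2^m <= 1e6.
    """
    universe = GeneUniverse(tuple(profile.signed_ranks.index))
    idx, signs = _signature_columns(signature, universe)
    ranks = profile.signed_ranks.to_numpy(dtype=np.int64)
    m, N = signature.m, universe.N
    raw = int(np.dot(signs, ranks[idx]))

    n_states = comb(N, m) * 2 ** m
    if method not in ("auto", "exhaustive", "mc"):
        raise ValueError(f"unknown method {method!r}")
    use_exhaustive = method == "exhaustive" or (
        method == "auto" and n_states <= _EXHAUSTIVE_LIMIT
    )
    if use_exhaustive:
        if n_states > _EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"exhaustive enumeration infeasible: {n_states} states"
            )
        null = exhaustive_null_scores(ranks, m)
        return _one_sided_p(raw, null, pseudocount=False)
    if n_null < 1000:
        raise ValueError("Monte-Carlo mode needs n_null >= 1000")
    rng = np.random.default_rng(seed)
    null_idx, null_signs = _sample_null_signatures(N, m, n_null, rng)
    null = _null_raw_scores(ranks[None, :], null_idx, null_signs)[:, 0]
    return _one_sided_p(raw, null, pseudocount=True)


@dataclass
class ConnectionResult:
    """One compound's connection to a query signature."""

    compound: str
    replicate_count: int
    cscore: float
    p_value: float
    z_score: float
    significant: bool
    direction: str  # 'positive' | 'negative'


class ConnectionResults:
    """Per-compound connection scores, p-values and z-scores for one query.

    ``frame`` is indexed by compound with columns ``replicate_count``,
    ``cscore``, ``p_value``, ``z_score``, ``significant``, ``direction``,
    ordered by ascending p then descending |z|.
    """

    def __init__(self, frame: pd.DataFrame, m: int, efp: float, nc: int,
                 n_null: int, seed: int | None) -> None:
        self.frame = frame
        self.m = m
        self.efp = efp
        self.nc = nc
        self.n_null = n_null
        self.seed = seed

    @property
    def threshold(self) -> float:
        return self.efp / self.nc

    def significant(self, direction_filter: str | None = "negative") -> pd.DataFrame:
        """Rows passing p <= Efp/Nc, optionally restricted to one direction."""
        return significant_connections(
            self.frame, efp=self.efp, nc=self.nc,
            direction_filter=direction_filter,
        )

    @property
    def results(self) -> list[ConnectionResult]:
        return [
            ConnectionResult(
                compound=str(ix),
                replicate_count=int(row["replicate_count"]),
                cscore=float(row["cscore"]),
                p_value=float(row["p_value"]),
                z_score=float(row["z_score"]),
                significant=bool(row["significant"]),
                direction=str(row["direction"]),
            )
            for ix, row in self.frame.iterrows()
        ]

    def summary(self, top: int = 10) -> str:
        head = self.frame.head(top)
        lines = [
            f"Connectivity mapping: m={self.m} signature vs {self.nc} compounds",
            f"  significance threshold Efp/Nc = {self.efp:g}/{self.nc} "
            f"= {self.threshold:.3e}   (n_null={self.n_null}, seed={self.seed})",
            f"  significant connections: "
            f"{int(self.frame['significant'].sum())} "
            f"({int(((self.frame['significant']) & (self.frame['cscore'] < 0)).sum())} negative)",
            head.to_string(
                float_format=lambda v: f"{v:.4g}",
                columns=["replicate_count", "cscore", "p_value", "z_score",
                         "significant"],
            ),
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "Compound"
        out = out.rename(
            columns={"replicate_count": "Replicate", "cscore": "cscore",
                     "p_value": "pvalue", "z_score": "zscore"}
        )
        out.to_csv(path, sep="\t", float_format="%.4g")


def significant_connections(
    results: pd.DataFrame | Sequence[ConnectionResult],
    efp: float,
    nc: int,
    direction_filter: str | None = "negative",
) -> pd.DataFrame:
    """Connections with p <= Efp/Nc in the desired direction of action.

    ``direction_filter='negative'`` keeps only compounds that reverse the
    signature (candidate inhibitors of the disease state); 'positive' keeps
    mimics; None keeps both.
    """
    if efp <= 0:
        raise ValueError("Efp must be positive")
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(
            [
                {
                    "compound": r.compound,
                    "replicate_count": r.replicate_count,
                    "cscore": r.cscore,
                    "p_value": r.p_value,
                    "z_score": r.z_score,
                    "direction": r.direction,
                }
                for r in results
            ]
        ).set_index("compound")
    threshold = efp / nc
    keep = results["p_value"] <= threshold
    if direction_filter == "negative":
        keep &= results["cscore"] < 0
    elif direction_filter == "positive":
        keep &= results["cscore"] > 0
    elif direction_filter is not None:
        raise ValueError(f"unknown direction filter {direction_filter!r}")
    return results[keep]


class ConnectivityMap:
    """Connectivity-mapping engine over a reference database.

    The model object holds the database; :meth:`query` scores a signature
    against every compound (or a subset), attaches Monte-Carlo p-values and
    z-scores at the compound level, and flags significant connections at the
    Efp/Nc threshold.

    Examples
    --------
    >>> cmap = ConnectivityMap(database)
    >>> res = cmap.query(signature, n_null=2000, seed=7)
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(self, database: ReferenceDatabase) -> None:
        if database.n_profiles == 0:
            raise ValueError("reference database is empty")
        self.database = database

    def query(
        self,
        signature: QuerySignature,
        n_null: int = 2000,
        seed: int | None = None,
        efp: float = 1.0,
        direction_filter: str | None = "negative",
        compounds: Sequence[str] | None = None,
    ) -> ConnectionResults:
        """Score ``signature`` against every compound of the database.

        The compound-level statistic is the mean replicate cscore; its null
        is the same mean computed over random signatures of the same length
        (shared across compounds) scored against each compound's replicates.
        When the signed-signature state space C(N, m) * 2^m is small (a
        single-gene query, or tiny test universes) the null is enumerated
        exactly and deterministically; otherwise ``n_null`` Monte-Carlo
        draws with an (r+1)/(n+1) pseudocount are used.  ``compounds``
        restricts the computation to a subset while keeping the
        full-database Nc in the significance threshold.
        """
        db = self.database
        if n_null < 1:
            raise ValueError("n_null must be >= 1")
        idx, signs = _signature_columns(signature, db.universe)
        maxsum = max_possible_sum(db.universe.N, signature.m)

        if compounds is None:
            rows = np.arange(db.n_profiles)
        else:
            rows = np.concatenate([db.profiles_of(c) for c in compounds])
        ranks = db.ranks[rows]
        row_compounds = db.compounds[rows]

        obs = (ranks[:, idx] @ signs) / maxsum            # per-profile cscore
        n_states = comb(db.universe.N, signature.m) * 2 ** signature.m
        exact = n_states <= _EXHAUSTIVE_QUERY_LIMIT
        if exact:
            null_idx, null_signs = _enumerate_signatures(
                db.universe.N, signature.m
            )
        else:
            rng = np.random.default_rng(seed)
            null_idx, null_signs = _sample_null_signatures(
                db.universe.N, signature.m, n_null, rng
            )
        null = _null_raw_scores(ranks, null_idx, null_signs) / maxsum

        records = []
        for compound in dict.fromkeys(row_compounds.tolist()):  # stable order
            mask = row_compounds == compound
            k = int(mask.sum())
            obs_mean = float(obs[mask].mean())
            null_mean = null[:, mask].mean(axis=1)
            p = _one_sided_p(obs_mean, null_mean, pseudocount=not exact)
            sd = float(null_mean.std(ddof=1)) if null.shape[0] > 1 else np.nan
            z = (obs_mean - float(null_mean.mean())) / sd if sd else np.nan
            records.append(
                {
                    "compound": compound,
                    "replicate_count": k,
                    "cscore": obs_mean,
                    "p_value": p,
                    "z_score": z,
                    "direction": "positive" if obs_mean >= 0 else "negative",
                }
            )
        frame = pd.DataFrame(records).set_index("compound")
        frame["significant"] = frame["p_value"] <= efp / db.Nc
        frame = frame.sort_values(
            by=["p_value", "z_score"], kind="mergesort"
        )
        if direction_filter is not None:
            # significance flag respects the requested direction of action
            if direction_filter == "negative":
                frame["significant"] &= frame["cscore"] < 0
            elif direction_filter == "positive":
                frame["significant"] &= frame["cscore"] > 0
            else:
                raise ValueError(f"unknown direction filter {direction_filter!r}")
        return ConnectionResults(
            frame, m=signature.m, efp=efp, nc=db.Nc,
            n_null=int(null.shape[0]), seed=None if exact else seed,
        )


def compound_connection(
    signature: QuerySignature,
    database: ReferenceDatabase,
    compound: str,
    n_null: int = 2000,
    seed: int | None = None,
    efp: float = 1.0,
) -> ConnectionResult:
    """Connection of one compound to a signature (mean over its replicates)."""
    res = ConnectivityMap(database).query(
        signature, n_null=n_null, seed=seed, efp=efp,
        direction_filter=None, compounds=[compound],
    )
    return res.results[0]
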