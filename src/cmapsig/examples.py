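"""A published-style worked example for the score-combination step.

The tables below reproduce the per-dataset signed normalized-rank scores of
fifteen probe sets from a five-cohort colorectal-cancer study (stage II-III
and stage IV sub-datasets of three GEO series): the top-ranked gene of each
individual sub-dataset (FXR1, CDH3, COL11A1, HSPH1, SMPD1) and the ten
genes that top the combined ranking (SLC4A4 down to CBFB).  They provide a
hand-checkable fixture for :func:`cmapsig.combine.combine_scores`: summing
each row's five dataset scores must reproduce the published total scores
(ten rows exactly at four decimals; five rows — flagged ``rounded`` — differ
by at most 2e-4 because the published totals were rounded from higher
precision inputs).

Note how GSE21510S4, a 4-pair sub-dataset with only 7 significant genes,
contributes zero to every top-ranked gene: under-powered cohorts fade out of
the combination automatically.
"""

from __future__ import annotations

import pandas as pd

from .combine import CombinedSignature, DatasetScoreVector, combine_scores

DATASET_COLUMNS = [
    "GSE21510S2-3", "GSE41258S2-3", "GSE21510S4", "GSE41258S4", "GSE49355S4",
]

# probe, symbol, five per-dataset scores, published total, published overall
# rank, and whether the published total shows a <=2e-4 rounding offset
_ROWS = [
    ("201637 s at", "FXR1",     1.0000,  0.0000, 0.0,  0.0000,  0.0000,  1.0000, 1000, False),
    ("203256 at",   "CDH3",     0.6174,  1.0000, 0.0,  0.9400,  0.9983,  3.5557,   25, False),
    ("37892 at",    "COL11A1",  0.9990,  0.8303, 0.0,  1.0000,  0.4707,  3.3000,   64, False),
    ("206976 s at", "HSPH1",    0.3651,  0.9524, 0.0,  0.0000,  1.0000,  2.3175,  262, False),
    ("216230 x at", "SMPD1",   -0.6184, -0.8424, -1.0, 0.0000,  0.0000, -2.4608,  222, False),
    ("203908 at",   "SLC4A4",  -0.9933, -0.9847, 0.0, -0.9895, -0.9883, -3.9557,    1, True),
    ("207502 at",   "GUCA2B",  -0.9904, -0.9973, 0.0, -0.9797, -0.9826, -3.9500,    2, False),
    ("207003 at",   "GUCA2A",  -0.9627, -0.9989, 0.0, -0.9822, -0.9513, -3.8951,    3, False),
    ("205480 s at", "UGP2",    -0.9912, -0.9732, 0.0, -0.9197, -0.9996, -3.8836,    4, True),
    ("205950 s at", "CA1",     -0.9974, -0.8872, 0.0, -0.9959, -0.9352, -3.8159,    5, True),
    ("212942 s at", "KIAA1199", 0.9472,  0.9962, 0.0,  0.8775,  0.9926,  3.8135,    6, False),
    ("203961 at",   "NEBL",     0.9788,  0.9639, 0.0,  0.8508,  0.9887,  3.7821,    7, True),
    ("219909 at",   "MMP28",   -0.9332, -0.9995, 0.0, -0.8856, -0.9613, -3.7796,    8, False),
    ("213766 x at", "GNA11",   -0.9973, -0.9037, 0.0, -0.9059, -0.9609, -3.7677,    9, True),
    ("202370 s at", "CBFB",     0.9886,  0.8933, 0.0,  0.9335,  0.9522,  3.7676,   10, False),
]


def worked_example_scores() -> pd.DataFrame:
    """Per-dataset score columns plus published totals/ranks, by probe id."""
    frame = pd.DataFrame(
        _ROWS,
        columns=["ProbeID", "GeneSymbol", *DATASET_COLUMNS,
                 "published_total", "published_rank", "rounded"],
    ).set_index("ProbeID")
    return frame


def worked_example_vectors() -> list[DatasetScoreVector]:
    """The five dataset score columns as :class:`DatasetScoreVector` objects."""
    frame = worked_example_scores()
    return [
        DatasetScoreVector(name, frame[name].rename(name)) for name in DATASET_COLUMNS
    ]


def worked_example_combined() -> CombinedSignature:
    """Combined signature recomputed from the per-dataset columns."""
    return combine_scores(worked_example_vectors())


def symbol_of(probe: str) -> str:
    return str(worked_example_scores().loc[probe, "GeneSymbol"])


def probe_of(symbol: str) -> str:
    frame = worked_example_scores()
    hits = frame.index[frame["GeneSymbol"] == symbol]
    if len(hits) != 1:
        raise KeyError(f"gene symbol {symbol!r} not in the worked example")
    return str(hits[0])
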