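"""Example data: a 14-gene Metasequoia glyptostroboides reference-gene screen.

A qRT-PCR survey of 14 candidate reference genes in *Metasequoia* scored
the panel under four condition sets — a six-tissue panel, leaves and buds
sampled over a flowering-induction (MglFlora) hormone time course, and an
abscisic-acid (ABA) time course — with each of the four per-gene stability
algorithms.  The resulting rank orderings (most stable first) are bundled
here as the worked example for consensus rank aggregation, together with
the panel's dilution-series amplification efficiencies.

These are orderings of real assay results, not synthetic fixtures; the raw
Ct values behind them are not included.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "METASEQUOIA_GENES",
    "METASEQUOIA_EFFICIENCIES",
    "METASEQUOIA_RANKINGS",
    "metasequoia_ranking_lists",
    "metasequoia_rankings_frame",
]

METASEQUOIA_GENES: list[str] = [
    "ACT2", "AP-2", "Cpn60β", "EF1α", "elF-5A", "GAPDH", "GIIα",
    "HIS", "RA", "RP", "RPL17", "TATA", "TUB", "UBQ",
]

#: Dilution-series amplification efficiencies (fold per cycle) of the
#: 14 candidate reference genes and the two target genes.
METASEQUOIA_EFFICIENCIES: dict[str, float] = {
    "ACT2": 1.9807,
    "AP-2": 2.1419,
    "Cpn60β": 1.9454,
    "EF1α": 1.9384,
    "elF-5A": 2.0517,
    "GAPDH": 2.0367,
    "GIIα": 1.9042,
    "HIS": 2.0234,
    "RA": 1.9410,
    "RP": 1.8518,
    "RPL17": 1.9946,
    "TATA": 1.9278,
    "TUB": 2.0385,
    "UBQ": 1.9534,
    "FT": 1.8475,
    "PYL8": 1.9692,
}

#: Per-condition rank orderings (most stable first) from the four per-gene
#: algorithms.  Keys: condition -> algorithm -> ordered gene list.
METASEQUOIA_RANKINGS: dict[str, dict[str, list[str]]] = {
    "tissue": {
        "delta_ct": [
            "Cpn60β", "EF1α", "elF-5A", "AP-2", "ACT2", "GIIα", "RPL17",
            "RP", "HIS", "TATA", "GAPDH", "UBQ", "RA", "TUB",
        ],
        "bestkeeper": [
            "AP-2", "HIS", "TATA", "EF1α", "ACT2", "Cpn60β", "GAPDH",
            "GIIα", "RP", "RPL17", "elF-5A", "TUB", "UBQ", "RA",
        ],
        "genorm": [
            "AP-2", "Cpn60β", "elF-5A", "EF1α", "ACT2", "RP", "GIIα",
            "RPL17", "HIS", "TATA", "GAPDH", "UBQ", "RA", "TUB",
        ],
        "normfinder": [
            "AP-2", "Cpn60β", "elF-5A", "GIIα", "EF1α", "ACT2", "RP",
            "RPL17", "HIS", "TATA", "GAPDH", "UBQ", "RA", "TUB",
        ],
    },
    "leaf_mglflora": {
        "delta_ct": [
            "TATA", "elF-5A", "RPL17", "EF1α", "GAPDH", "UBQ", "RA",
            "GIIα", "TUB", "HIS", "Cpn60β", "RP", "AP-2", "ACT2",
        ],
        "bestkeeper": [
            "HIS", "ACT2", "TUB", "TATA", "EF1α", "Cpn60β", "UBQ",
            "GIIα", "elF-5A", "GAPDH", "RA", "RPL17", "RP", "AP-2",
        ],
        "genorm": [
            "RPL17", "elF-5A", "GAPDH", "TATA", "TUB", "UBQ", "EF1α",
            "RA", "GIIα", "Cpn60β", "HIS", "RP", "AP-2", "ACT2",
        ],
        "normfinder": [
            "TATA", "elF-5A", "EF1α", "RPL17", "UBQ", "GAPDH", "TUB",
            "RA", "GIIα", "HIS", "Cpn60β", "RP", "AP-2", "ACT2",
        ],
    },
    "bud_mglflora": {
        "delta_ct": [
            "TATA", "ACT2", "EF1α", "HIS", "RPL17", "RA", "GIIα",
            "TUB", "UBQ", "Cpn60β", "GAPDH", "elF-5A", "RP", "AP-2",
        ],
        "bestkeeper": [
            "Cpn60β", "GIIα", "HIS", "EF1α", "TATA", "ACT2", "GAPDH",
            "RA", "elF-5A", "RPL17", "TUB", "UBQ", "RP", "AP-2",
        ],
        "genorm": [
            "EF1α", "HIS", "ACT2", "TATA", "GIIα", "Cpn60β", "RA",
            "GAPDH", "RPL17", "UBQ", "TUB", "elF-5A", "RP", "AP-2",
        ],
        "normfinder": [
            "TATA", "RPL17", "ACT2", "RA", "EF1α", "HIS", "GIIα",
            "TUB", "UBQ", "elF-5A", "Cpn60β", "GAPDH", "RP", "AP-2",
        ],
    },
    "aba": {
        "delta_ct": [
            "elF-5A", "EF1α", "TATA", "ACT2", "Cpn60β", "RPL17", "RP",
            "AP-2", "HIS", "GAPDH", "RA", "GIIα", "UBQ", "TUB",
        ],
        "bestkeeper": [
            "TATA", "Cpn60β", "elF-5A", "EF1α", "HIS", "ACT2", "RPL17",
            "AP-2", "RP", "GAPDH", "RA", "GIIα", "UBQ", "TUB",
        ],
        "genorm": [
            "EF1α", "TATA", "elF-5A", "ACT2", "Cpn60β", "RPL17", "RP",
            "AP-2", "HIS", "GAPDH", "RA", "GIIα", "UBQ", "TUB",
        ],
        "normfinder": [
            "TATA", "EF1α", "elF-5A", "ACT2", "Cpn60β", "RPL17", "RP",
            "AP-2", "HIS", "GAPDH", "RA", "GIIα", "UBQ", "TUB",
        ],
    },
}


def metasequoia_ranking_lists(condition: str = "tissue") -> list[list[str]]:
    """The four algorithm orderings for one condition, ready for aggregation."""
    if condition not in METASEQUOIA_RANKINGS:
        raise KeyError(
            f"unknown condition {condition!r}; choose from "
            f"{sorted(METASEQUOIA_RANKINGS)}"
        )
    per_alg = METASEQUOIA_RANKINGS[condition]
    return [list(per_alg[a]) for a in ("delta_ct", "bestkeeper", "genorm", "normfinder")]


def metasequoia_rankings_frame(condition: str = "tissue") -> pd.DataFrame:
    """Same data as a rank x algorithm DataFrame (cells are gene ids)."""
    per_alg = METASEQUOIA_RANKINGS[condition]
    return pd.DataFrame(per_alg, index=pd.RangeIndex(1, 15, name="rank"))
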