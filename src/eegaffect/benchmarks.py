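"""Published electrode rankings from three public affect datasets.

These are the per-electrode valence (V) and arousal (A) ranks reported for
the DREAMER, DEAP, and OASIS portable-EEG emotion datasets under univariate
F-score selection on the 14-channel Emotiv montage.  They serve as reference
inputs for scalp-region summaries (e.g. what share of the top electrodes is
frontal) without needing the underlying licensed recordings.
"""
from __future__ import annotations

from .selection import ScoreTable

__all__ = ["PUBLISHED_ELECTRODE_RANKS", "published_ranking_tables"]

# electrode -> {dataset: {"A": rank, "V": rank}}
PUBLISHED_ELECTRODE_RANKS: dict[str, dict[str, dict[str, int]]] = {
    "AF3": {"DREAMER": {"A": 10, "V": 13}, "DEAP": {"A": 10, "V": 8},
            "OASIS": {"A": 7, "V": 6}},
    "AF4": {"DREAMER": {"A": 9, "V": 11}, "DEAP": {"A": 12, "V": 10},
            "OASIS": {"A": 8, "V": 8}},
    "F3": {"DREAMER": {"A": 11, "V": 10}, "DEAP": {"A": 7, "V": 11},
           "OASIS": {"A": 5, "V": 5}},
    "F4": {"DREAMER": {"A": 13, "V": 14}, "DEAP": {"A": 8, "V": 6},
           "OASIS": {"A": 6, "V": 9}},
    "F7": {"DREAMER": {"A": 14, "V": 12}, "DEAP": {"A": 1, "V": 1},
           "OASIS": {"A": 1, "V": 1}},
    "F8": {"DREAMER": {"A": 3, "V": 5}, "DEAP": {"A": 2, "V": 2},
           "OASIS": {"A": 4, "V": 4}},
    "FC5": {"DREAMER": {"A": 5, "V": 9}, "DEAP": {"A": 14, "V": 14},
            "OASIS": {"A": 10, "V": 7}},
    "FC6": {"DREAMER": {"A": 6, "V": 4}, "DEAP": {"A": 3, "V": 4},
            "OASIS": {"A": 9, "V": 10}},
    "O1": {"DREAMER": {"A": 12, "V": 8}, "DEAP": {"A": 13, "V": 7},
           "OASIS": {"A": 11, "V": 11}},
    "O2": {"DREAMER": {"A": 8, "V": 3}, "DEAP": {"A": 6, "V": 9},
           "OASIS": {"A": 14, "V": 13}},
    "P7": {"DREAMER": {"A": 4, "V": 2}, "DEAP": {"A": 5, "V": 3},
           "OASIS": {"A": 12, "V": 12}},
    "P8": {"DREAMER": {"A": 7, "V": 6}, "DEAP": {"A": 4, "V": 5},
           "OASIS": {"A": 13, "V": 14}},
    "T7": {"DREAMER": {"A": 1, "V": 7}, "DEAP": {"A": 9, "V": 13},
           "OASIS": {"A": 3, "V": 2}},
    "T8": {"DREAMER": {"A": 2, "V": 1}, "DEAP": {"A": 11, "V": 12},
           "OASIS": {"A": 2, "V": 3}},
}

DATASETS = ("DREAMER", "DEAP", "OASIS")


def published_ranking_tables(label: str) -> list[ScoreTable]:
    """One :class:`ScoreTable` per benchmark dataset for ``label``
    ('valence' or 'arousal')."""
    key = {"valence": "V", "arousal": "A"}[label]
    tables = []
    for ds in DATASETS:
        ranks = {ch: info[ds][key]
                 for ch, info in PUBLISHED_ELECTRODE_RANKS.items()}
        tables.append(ScoreTable.from_ranks(ranks, target=label,
                                            granularity="electrode"))
    return tables
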