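"""Univariate feature/electrode ranking by correlation F-score.

For each feature column the Pearson correlation rho with the target label is
converted to F = rho^2 / (1 - rho^2) * (n - 2); per-feature and per-electrode
scores aggregate column F-scores (mean by default) and are ranked descending.
Pair (asymmetry) columns are excluded from electrode attribution because they
belong to two electrodes at once.
"""
from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import stats

from .core import LabelVector, Montage, default_montage
from .features import SPECS, FeatureMatrix

__all__ = [
    "ScoreTable", "variance_filter", "common_codes", "pearson_r", "f_value",
    "column_scores", "rank_features", "rank_electrodes", "region_summary",
]


@dataclass
class ScoreTable:
    """Ranked names with F-scores; rank 1 carries the maximum score."""

    entries: list[tuple[str, float, int]]  # (name, F, rank)
    target: str = "valence"
    granularity: str = "feature"

    def __post_init__(self):
        ranks = sorted(r for _, _, r in self.entries)
        if ranks != list(range(1, len(self.entries) + 1)):
            raise ValueError("ranks must be a permutation of 1..n")

    @property
    def names_by_rank(self) -> list[str]:
        return [name for name, _, _ in
                sorted(self.entries, key=lambda e: e[2])]

    def top(self, k: int) -> list[str]:
        return self.names_by_rank[:k]

    def rank_of(self, name: str) -> int:
        for n, _, r in self.entries:
            if n == name:
                return r
        raise KeyError(name)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            sorted(self.entries, key=lambda e: e[2]),
            columns=["name", "f_score", "rank"],
        )

    @classmethod
    def from_ranks(cls, ranks: dict[str, int], target: str = "valence",
                   granularity: str = "electrode") -> "ScoreTable":
        """Build a table from published rank numbers alone (scores unknown);
        a rank-r entry is given the placeholder score n - r so ordering is
        consistent."""
        n = len(ranks)
        entries = [(name, float(n - r), r) for name, r in ranks.items()]
        return cls(entries, target=target, granularity=granularity)


def variance_filter(fm: FeatureMatrix, threshold: float = 0.0):
    """Drop columns whose variance is <= ``threshold``.

    Returns the filtered matrix and the metadata of dropped columns.
    """
    var = fm.values.var(axis=0)
    constant = fm.values.max(axis=0) == fm.values.min(axis=0)
    low = (var <= threshold) | constant  # ptp==0 catches fp residue of var
    keep = np.flatnonzero(~low)
    dropped = [fm.column_meta[i] for i in np.flatnonzero(low)]
    if keep.size == 0:
        raise ValueError("variance filter would drop every column")
    return fm.select_columns(keep), dropped


def common_codes(matrices) -> tuple[str, ...]:
    """Feature codes that survive the variance filter in *every* matrix —
    the cross-dataset common subset used to align batteries."""
    surviving = []
    for fm in matrices:
        filtered, _ = variance_filter(fm)
        surviving.append(set(filtered.codes))
    common = set.intersection(*surviving) if surviving else set()
    return tuple(sorted(common))


def pearson_r(x: np.ndarray, y) -> float:
    """Pearson correlation; a zero-variance column scores 0 with a warning so
    rankings stay total."""
    x = np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, LabelVector) else np.asarray(y, dtype=float)
    if x.size != yv.size:
        raise ValueError("column and label lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if x.std() == 0 or yv.std() == 0:
        warnings.warn("zero-variance input; correlation defined as 0")
        return 0.0
    return float(np.corrcoef(x, yv)[0, 1])


def f_value(r: float, n: int) -> float:
    """Univariate regression F-statistic from a correlation coefficient."""
    if n <= 2:
        raise ValueError("need n > 2")
    if abs(r) >= 1.0:
        return float("inf")
    return r * r / (1.0 - r * r) * (n - 2)


def column_scores(fm: FeatureMatrix, y) -> np.ndarray:
    """Per-column F-scores against the label vector."""
    yv = y.values if isinstance(y, LabelVector) else np.asarray(y, dtype=float)
    if len(yv) != fm.n_segments:
        raise ValueError("label length does not match segment count")
    n = len(yv)
    out = np.empty(fm.values.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(out.size):
            out[j] = f_value(pearson_r(fm.values[:, j], yv), n)
    return out


def column_pvalues(fm: FeatureMatrix, y) -> np.ndarray:
    """Per-column p-values of the F(1, n-2) test behind the scores."""
    scores = column_scores(fm, y)
    n = fm.n_segments
    return stats.f.sf(scores, 1, n - 2)


def _rank_names(scored: list[tuple[str, float]],
                order: list[str]) -> list[tuple[str, float, int]]:
    """Rank descending by score; ties broken by position in ``order``."""
    pos = {name: i for i, name in enumerate(order)}
    ranked = sorted(scored, key=lambda e: (-e[1], pos[e[0]]))
    return [(name, score, i + 1) for i, (name, score) in enumerate(ranked)]


def rank_features(fm: FeatureMatrix, y, target: str = "valence",
                  aggregate: str = "mean") -> ScoreTable:
    """Rank feature codes by aggregated column F-score (one rank per code).

    Per-trial labels must already be broadcast to segment rows.  Ties break
    by alphabetical code.
    """
    scores = column_scores(fm, y)
    agg = {"mean": np.mean, "max": np.max}[aggregate]
    scored = []
    for code in fm.codes:
        cols = fm.columns_for_code(code)
        scored.append((code, float(agg(scores[cols]))))
    entries = _rank_names(scored, sorted(c for c, _ in scored))
    return ScoreTable(entries, target=target, granularity="feature")


def rank_electrodes(fm: FeatureMatrix, y, montage: Montage | None = None,
                    target: str = "valence",
                    aggregate: str = "mean") -> ScoreTable:
    """Rank electrodes by the aggregated F-score of their per-channel feature
    columns (asymmetry-pair columns excluded).  Ties break by montage order.
    """
    montage = montage or default_montage()
    scores = column_scores(fm, y)
    agg = {"mean": np.mean, "max": np.max}[aggregate]
    scored = []
    for ch in montage.channels:
        cols = fm.columns_for_channel(ch)
        if cols.size == 0:
            continue
        scored.append((ch, float(agg(scores[cols]))))
    if not scored:
        raise ValueError("no per-channel columns to attribute to electrodes")
    entries = _rank_names(scored, list(montage.channels))
    return ScoreTable(entries, target=target, granularity="electrode")


def region_summary(rankings, montage: Montage | None = None,
                   top_k: int = 3) -> dict[str, int]:
    """Pool the ``top_k`` electrodes of each ranking and report the share of
    each scalp region as an integer-truncated percentage."""
    montage = montage or default_montage()
    if top_k > len(montage.channels):
        raise ValueError("top_k exceeds montage size")
    pool: list[str] = []
    for table in rankings:
        pool.extend(table.top(top_k))
    if not pool:
        raise ValueError("empty electrode pool")
    out = {}
    for region in montage.regions:
        members = set(montage.region_channels(region))
        count = sum(1 for ch in pool if ch in members)
        out[region] = int(100 * count // len(pool))
    return out
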