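"""Divergence structure by taxonomic rank: pooled summaries, histograms,
barcode-gap ratios, and the subcluster-corrected intraspecific mean.

Every specimen pair contributes to exactly one rank: the lowest rank at
which the two lineages share a name (conspecific -> within_species,
congeneric -> within_genus, and so on up to within_class).  Statistics are
pooled over pairwise comparisons by default; a per-taxon averaging mode is
available because published distance summaries do not always state their
pooling.  All reported distances are percentages (matrix entries, which
are proportions, times 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from barcode_audit.distances import DistanceMatrix

RANKS = ("within_species", "within_genus", "within_family", "within_order", "within_class")
_LEVELS = ("species", "genus", "family", "order", "class")


@dataclass
class RankSummary:
    rank: str
    n_taxa: int
    n_comparisons: int
    min: Optional[float]   # %
    mean: Optional[float]  # %
    max: Optional[float]   # %
    se: Optional[float]    # %


def rank_of_pair(lineage_a: Mapping[str, str], lineage_b: Mapping[str, str]) -> Optional[str]:
    """Lowest shared rank of two lineages, or None if none at/below class."""
    for level, rank in zip(_LEVELS, RANKS):
        if lineage_a[level] == lineage_b[level]:
            return rank
    return None


def _pair_ranks(dm: DistanceMatrix, taxonomy: pd.DataFrame):
    """Vectorised rank assignment for every upper-triangle pair.

    Returns (i, j, values, rank_code) with rank_code -1 for pairs whose
    lineages share nothing at or below class.
    """
    tax = taxonomy.loc[dm.labels]
    codes = {
        level: pd.factorize(tax[level])[0] for level in _LEVELS
    }
    i, j, vals = dm.condensed()
    rank_code = np.full(len(i), -1, dtype=int)
    # assign from class downward so the lowest shared rank wins
    for k in range(len(_LEVELS) - 1, -1, -1):
        c = codes[_LEVELS[k]]
        rank_code[c[i] == c[j]] = k
    return i, j, vals, rank_code, codes


def rank_summary_table(
    dm: DistanceMatrix,
    taxonomy: pd.DataFrame,
    partition: Optional[Mapping[str, object]] = None,
    pooling: str = "comparisons",
) -> list[RankSummary]:
    """Min/mean/max/SE of K2P divergence per taxonomic rank.

    ``partition`` optionally maps specimen IDs of deep-divergent species to
    subcluster unit labels; conspecific pairs assigned to different units
    are then dropped from the within-species pool, which is how the
    subcluster-corrected intraspecific mean is obtained.

    ``pooling='comparisons'`` pools all pairwise comparisons of a rank;
    ``pooling='taxa'`` first averages within each taxon of that rank and
    then averages the taxon means (min/max remain pooled).  SE is the
    standard deviation of the pooled comparisons over sqrt(count).
    """
    if pooling not in ("comparisons", "taxa"):
        raise ValueError("pooling must be 'comparisons' or 'taxa'")
    i, j, vals, rank_code, codes = _pair_ranks(dm, taxonomy)
    defined = ~np.isnan(vals)

    if partition is not None:
        units = np.array(
            [str(partition.get(label, "")) for label in dm.labels], dtype=object
        )
        cross = (rank_code == 0) & (units[i] != units[j])
        rank_code = rank_code.copy()
        rank_code[cross] = -2  # dropped from within-species pool
    out = []
    for k, rank in enumerate(RANKS):
        mask = (rank_code == k) & defined
        v = vals[mask] * 100.0
        taxon = codes[_LEVELS[k]]
        n_taxa = len(np.unique(taxon[i[mask]])) if mask.any() else 0
        if len(v) == 0:
            out.append(RankSummary(rank, 0, 0, None, None, None, None))
            continue
        if pooling == "taxa":
            groups = pd.Series(v).groupby(taxon[i[mask]]).mean()
            mean = float(groups.mean())
        else:
            mean = float(v.mean())
        se = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        out.append(
            RankSummary(rank, n_taxa, len(v), float(v.min()), mean, float(v.max()), se)
        )
    return out


def summary_frame(summaries: list[RankSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": s.rank,
                "n_taxa": s.n_taxa,
                "n_comparisons": s.n_comparisons,
                "min_pct": None if s.min is None else round(s.min, 4),
                "mean_pct": None if s.mean is None else round(s.mean, 4),
                "max_pct": None if s.max is None else round(s.max, 4),
                "se_pct": None if s.se is None else round(s.se, 4),
            }
            for s in summaries
        ]
    )


def divergence_histogram(
    dm: DistanceMatrix,
    taxonomy: pd.DataFrame,
    bin_width_pct: float = 1.0,
    threshold_pct: float = 2.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Binned divergence counts per rank plus the percent below a threshold.

    Returns ``(hist, below)`` where ``hist`` has columns rank, bin_left_pct,
    count (bin counts sum to the number of defined comparisons of the rank)
    and ``below[rank]`` is the percentage of that rank's comparisons with
    divergence strictly below ``threshold_pct``.
    """
    i, j, vals, rank_code, _ = _pair_ranks(dm, taxonomy)
    defined = ~np.isnan(vals)
    rows = []
    below: dict[str, float] = {}
    for k, rank in enumerate(RANKS):
        v = vals[(rank_code == k) & defined] * 100.0
        if len(v) == 0:
            below[rank] = float("nan")
            continue
        nbins = int(np.floor(v.max() / bin_width_pct)) + 1
        edges = np.arange(nbins + 1) * bin_width_pct
        counts, _ = np.histogram(v, bins=edges)
        # np.histogram closes the last bin on the right; that is fine here
        # because the top edge exceeds the maximum by construction.
        for left, c in zip(edges[:-1], counts):
            rows.append({"rank": rank, "bin_left_pct": float(left), "count": int(c)})
        below[rank] = float((v < threshold_pct).mean() * 100.0)
    return pd.DataFrame(rows), below


def barcode_gap_ratio(summaries: list[RankSummary]) -> Optional[float]:
    """Ratio of the within-genus mean to the within-species mean.

    The classical barcode-gap magnitude: how many times larger congeneric
    divergence is than intraspecific divergence.  None if either mean is
    missing or the intraspecific mean is zero (ratio undefined).
    """
    by_rank = {s.rank: s for s in summaries}
    ws = by_rank["within_species"].mean
    wg = by_rank["within_genus"].mean
    if ws is None or wg is None or ws == 0.0:
        return None
    return wg / ws
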