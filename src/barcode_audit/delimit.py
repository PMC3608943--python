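"""Threshold-based species delimitation and cryptic-lineage detection.

Four related screens built on the K2P distance matrix:

* nearest-neighbour analysis — for every species, the heterospecific
  species attaining the minimum inter-specimen distance;
* low-divergence screening — species pairs whose minimum inter-specimen
  distance falls strictly below a cutoff (2% by default);
* discrimination verdicts — a species fails if it shares a haplotype
  (distance exactly zero) with another species, or if its specimens do not
  form an exclusive cluster on the NJ tree;
* deep-divergence flagging and subcluster partitioning — species whose
  maximum intraspecific distance exceeds the cutoff are split into
  single-linkage subclusters, the machinery behind candidate cryptic
  species and the corrected intraspecific mean.

Species-to-species distance is the *minimum* over inter-specimen pairs
throughout (the nearest-neighbour convention); a mean-based alternative is
available where noted.  Cutoffs are proportions internally and compared
strictly (< for low divergence, > for deep divergence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from barcode_audit.distances import DistanceMatrix
from barcode_audit.njtree import Tree


class NearestNeighborRow(NamedTuple):
    species: str
    nearest: str
    nnd_pct: float


@dataclass
class Partition:
    """Subcluster assignment of one species' specimens."""

    species: str
    assignment: dict  # specimen_id -> subcluster id (1-based int)
    intra_means_pct: dict  # subcluster -> mean intra distance % (None if singleton)
    between_pct: dict  # (c1, c2) -> (min, mean, max) in %

    @property
    def n_subclusters(self) -> int:
        return len(set(self.assignment.values()))

    def units(self) -> dict:
        """Specimen -> globally unique subcluster unit label."""
        return {
            sid: f"{self.species}|{c}" for sid, c in self.assignment.items()
        }


@dataclass
class DiscriminationVerdict:
    species: str
    discriminated: bool
    failure_mode: str  # "none" | "shared_haplotype" | "non_exclusive_cluster"
    offending: list = field(default_factory=list)


def _species_structure(dm: DistanceMatrix, taxonomy: pd.DataFrame):
    """Per-species-pair minimum distances and per-species intraspecific maxima.

    Returns (species list, min_inter SxS with inf where no defined pair,
    max_intra per species with -inf where no defined pair, specimen counts).
    """
    tax = taxonomy.loc[dm.labels]
    codes, species = pd.factorize(tax["species"])
    S = len(species)
    i, j, vals = dm.condensed()
    ok = ~np.isnan(vals)
    si, sj = codes[i[ok]], codes[j[ok]]
    v = vals[ok]
    min_inter = np.full((S, S), np.inf)
    inter = si != sj
    np.minimum.at(min_inter, (si[inter], sj[inter]), v[inter])
    np.minimum.at(min_inter, (sj[inter], si[inter]), v[inter])
    max_intra = np.full(S, -np.inf)
    intra = ~inter
    np.maximum.at(max_intra, si[intra], v[intra])
    n_specimens = np.bincount(codes, minlength=S)
    return list(species), min_inter, max_intra, n_specimens


def nearest_neighbor_table(dm: DistanceMatrix, taxonomy: pd.DataFrame) -> list[NearestNeighborRow]:
    """For each species, its nearest heterospecific species and the NND (%).

    Ties go to the alphabetically first neighbour.  A species all of whose
    inter-specimen distances are undefined yields a row with NaN distance
    and an empty neighbour name.
    """
    species, min_inter, _, _ = _species_structure(dm, taxonomy)
    if len(species) < 2:
        raise ValueError("nearest-neighbour analysis needs >= 2 species")
    order = np.argsort(species)  # alphabetical tie-break
    rows = []
    for a, sp in enumerate(species):
        col = min_inter[a]
        finite = np.isfinite(col)
        finite[a] = False
        if not finite.any():
            rows.append(NearestNeighborRow(sp, "", float("nan")))
            continue
        best = min(
            (col[b], species[b]) for b in order if finite[b]
        )
        rows.append(NearestNeighborRow(sp, best[1], best[0] * 100.0))
    return sorted(rows)


def low_divergence_pairs(
    dm: DistanceMatrix, taxonomy: pd.DataFrame, cutoff: float = 0.02
) -> list[tuple[str, str, float]]:
    """Unordered species pairs with minimum inter-specimen distance < cutoff.

    Returns (species_a, species_b, min_distance_pct) sorted by pair name;
    the inequality is strict, so ``cutoff=0`` returns nothing.
    """
    species, min_inter, _, _ = _species_structure(dm, taxonomy)
    out = []
    for a in range(len(species)):
        for b in range(a + 1, len(species)):
            d = min_inter[a, b]
            if np.isfinite(d) and d < cutoff:
                pair = tuple(sorted((species[a], species[b])))
                out.append((pair[0], pair[1], d * 100.0))
    return sorted(out)


def discrimination_status(
    dm: DistanceMatrix, tree: Tree, taxonomy: pd.DataFrame
) -> tuple[list[DiscriminationVerdict], float]:
    """Per-species discrimination verdicts and the overall success fraction.

    A species fails with ``shared_haplotype`` if any of its specimens sits
    at distance exactly zero from a heterospecific specimen; otherwise with
    ``non_exclusive_cluster`` if its specimens are not monophyletic on the
    tree; otherwise it is discriminated.
    """
    species, min_inter, _, _ = _species_structure(dm, taxonomy)
    # one bipartition scan serves every species' exclusivity check
    leaf_labels = set(tree.labels)
    ref = min(leaf_labels)
    splits = set(tree.bipartitions())
    members_of: dict[str, set] = {}
    for sid in leaf_labels:
        members_of.setdefault(taxonomy.loc[sid, "species"], set()).add(sid)

    def _exclusive(sp: str) -> bool:
        members = members_of.get(sp, set())
        if not members:
            raise ValueError(f"species {sp!r} absent from tree")
        if len(members) == 1 or members == leaf_labels:
            return True
        target = frozenset(members if ref not in members else leaf_labels - members)
        if len(target) < 2 or len(target) > len(leaf_labels) - 2:
            return True  # complement is a single leaf: pendant edge
        return target in splits

    verdicts = []
    n_ok = 0
    for a, sp in enumerate(species):
        shared = [
            species[b]
            for b in range(len(species))
            if b != a and np.isfinite(min_inter[a, b]) and min_inter[a, b] == 0.0
        ]
        if shared:
            verdicts.append(DiscriminationVerdict(sp, False, "shared_haplotype", sorted(shared)))
            continue
        if not _exclusive(sp):
            verdicts.append(DiscriminationVerdict(sp, False, "non_exclusive_cluster"))
            continue
        verdicts.append(DiscriminationVerdict(sp, True, "none"))
        n_ok += 1
    return sorted(verdicts, key=lambda v: v.species), n_ok / len(species)


def deep_divergence_flags(
    dm: DistanceMatrix, taxonomy: pd.DataFrame, cutoff: float = 0.02
) -> pd.DataFrame:
    """Species whose maximum intraspecific distance strictly exceeds the cutoff.

    Only species with >= 2 specimens (hence >= 1 intraspecific comparison)
    can be flagged.  Returns a DataFrame with species and
    max_intraspecific_pct, sorted by species.
    """
    species, _, max_intra, n_spec = _species_structure(dm, taxonomy)
    rows = [
        {"species": sp, "max_intraspecific_pct": max_intra[a] * 100.0}
        for a, sp in enumerate(species)
        if n_spec[a] >= 2 and np.isfinite(max_intra[a]) and max_intra[a] > cutoff
    ]
    return pd.DataFrame(rows, columns=["species", "max_intraspecific_pct"]).sort_values(
        "species", ignore_index=True
    )


def subcluster_partition(
    dm: DistanceMatrix,
    species: str,
    taxonomy: pd.DataFrame,
    linkage_cutoff: float = 0.02,
    mode: str = "cutoff",
) -> Partition:
    """Single-linkage subclusters of one species' specimens.

    ``mode='cutoff'`` cuts the single-linkage dendrogram so that specimens
    end up together iff they are connected by a chain of distances strictly
    below ``linkage_cutoff``.  ``mode='largest-gap'`` instead cuts at the
    midpoint of the largest gap between consecutive merge heights, which
    mimics delimiting subclusters by eye on a dendrogram and can recover
    splits shallower than the fixed cutoff.
    """
    if mode not in ("cutoff", "largest-gap"):
        raise ValueError("mode must be 'cutoff' or 'largest-gap'")
    members = [
        sid for sid in dm.labels if taxonomy.loc[sid, "species"] == species
    ]
    if not members:
        raise ValueError(f"species {species!r} has no specimens in the matrix")
    if len(members) == 1:
        return Partition(species, {members[0]: 1}, {1: None}, {})
    sub = dm.submatrix(members).values.copy()
    # undefined pairs cannot attest proximity: treat as unlinkable (a large
    # finite value, since scipy linkage rejects inf)
    sub[np.isnan(sub)] = np.inf
    condensed = squareform(np.where(np.isinf(sub), 1e6, sub), checks=False)
    Z = linkage(condensed, method="single")
    if mode == "cutoff":
        t = np.nextafter(linkage_cutoff, -np.inf)  # strict '<' at the cutoff
    else:
        heights = Z[:, 2]
        gaps = np.diff(np.concatenate([[0.0], heights]))
        t = np.nextafter(heights[np.argmax(gaps)], -np.inf)
    labels = fcluster(Z, t=t, criterion="distance")
    # renumber subclusters 1..k in order of first appearance
    remap: dict[int, int] = {}
    assignment = {}
    for sid, c in zip(members, labels):
        if c not in remap:
            remap[c] = len(remap) + 1
        assignment[sid] = remap[c]
    k = len(remap)
    idx = {sid: i for i, sid in enumerate(members)}
    groups = {c: [idx[s] for s, cc in assignment.items() if cc == c] for c in range(1, k + 1)}
    intra_means = {}
    for c, g in groups.items():
        if len(g) < 2:
            intra_means[c] = None
            continue
        block = sub[np.ix_(g, g)]
        vals = block[np.triu_indices(len(g), 1)]
        vals = vals[np.isfinite(vals)]
        intra_means[c] = float(vals.mean() * 100.0) if len(vals) else None
    between = {}
    for c1 in range(1, k + 1):
        for c2 in range(c1 + 1, k + 1):
            block = sub[np.ix_(groups[c1], groups[c2])].ravel()
            block = block[np.isfinite(block)]
            if len(block):
                between[(c1, c2)] = (
                    float(block.min() * 100.0),
                    float(block.mean() * 100.0),
                    float(block.max() * 100.0),
                )
    return Partition(species, assignment, intra_means, between)


def partition_units(partitions: list[Partition]) -> dict:
    """Merge per-species partitions into one specimen -> unit mapping."""
    units: dict = {}
    for p in partitions:
        units.update(p.units())
    return units


def genus_calibration_table(
    dm: DistanceMatrix, taxonomy: pd.DataFrame, min_species: int = 3
) -> pd.DataFrame:
    """Per-genus divergence calibration for genera with >= ``min_species``.

    For each such genus: pooled interspecific specimen-pair min/mean/max
    (%), the range of per-species maximum intraspecific distances, and an
    overlap flag set when some species' intraspecific maximum exceeds the
    genus' interspecific minimum — the situation in which a global 2%
    cutoff can hide real diversity and a genus-specific cutoff is needed.
    """
    tax = taxonomy.loc[dm.labels]
    i, j, vals = dm.condensed()
    ok = ~np.isnan(vals)
    sp = tax["species"].to_numpy()
    gen = tax["genus"].to_numpy()
    rows = []
    for genus in sorted(set(gen)):
        members = gen == genus
        species_here = sorted(set(sp[members]))
        if len(species_here) < min_species:
            continue
        both = members[i] & members[j] & ok
        inter = both & (sp[i] != sp[j])
        intra = both & (sp[i] == sp[j])
        iv = vals[inter] * 100.0
        max_intra = {}
        for a, b, v in zip(i[intra], j[intra], vals[intra]):
            s = sp[a]
            max_intra[s] = max(max_intra.get(s, 0.0), v * 100.0)
        intra_vals = sorted(max_intra.values())
        overlap = bool(iv.size and intra_vals and max(intra_vals) > iv.min())
        rows.append(
            {
                "genus": genus,
                "n_species": len(species_here),
                "inter_min_pct": float(iv.min()) if iv.size else None,
                "inter_mean_pct": float(iv.mean()) if iv.size else None,
                "inter_max_pct": float(iv.max()) if iv.size else None,
                "intra_max_low_pct": intra_vals[0] if intra_vals else None,
                "intra_max_high_pct": intra_vals[-1] if intra_vals else None,
                "overlap": overlap,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genus", "n_species", "inter_min_pct", "inter_mean_pct",
            "inter_max_pct", "intra_max_low_pct", "intra_max_high_pct", "overlap",
        ],
    )
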