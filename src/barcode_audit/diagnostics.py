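"""Character-based nucleotide diagnostics (NDs).

Within a comparison group of species (typically a genus, or a single
low-divergence species pair), an alignment position is an *exclusive* ND
for a species when that species is fixed for one nucleotide there and the
nucleotide occurs in no other species of the group; it is a *partial
shared* ND when the species is fixed and its state is absent from some but
not all other species.  Species lacking exclusive NDs can still be told
apart by their unique combination of states over the informative
positions, so the module also computes combination-based discrimination
with a minimal discriminating position subset.

Positions are reported 1-based relative to the group alignment.  N and gap
states are ignored when assessing fixation: a species is "fixed" at a
position when its unambiguous states there reduce to a single nucleotide.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

_NUCS = frozenset("ACGT")


@dataclass
class DiagnosticProfile:
    """Per-species, per-position character states for a comparison group.

    ``states[(species, pos)]`` is the frozenset of unambiguous nucleotides
    the species shows at 1-based position ``pos``; an empty set means the
    species had no unambiguous state there (treated as unknown).
    ``classification[(species, pos)]`` is 'exclusive', 'partial' or
    'uninformative'.  Globally constant positions are dropped from
    ``positions``.
    """

    group: tuple
    positions: tuple
    states: dict
    classification: dict


def build_site_profiles(records: Sequence) -> DiagnosticProfile:
    """Build the ND profile for a group of aligned specimen records."""
    by_species: dict[str, list[str]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r.sequence)
    group = tuple(sorted(by_species))
    if len(group) < 2:
        raise ValueError("a diagnostic group needs >= 2 species")
    lengths = {len(s) for seqs in by_species.values() for s in seqs}
    if len(lengths) != 1:
        raise ValueError("group sequences are not aligned")
    L = lengths.pop()

    states: dict = {}
    positions = []
    for pos in range(1, L + 1):
        col = {
            sp: frozenset(s[pos - 1] for s in seqs) & _NUCS
            for sp, seqs in by_species.items()
        }
        for sp, st in col.items():
            if not st:
                warnings.warn(
                    f"{sp}: no unambiguous state at position {pos}; "
                    "position treated as unknown for this species",
                    stacklevel=2,
                )
        known = [st for st in col.values() if st]
        all_fixed_same = (
            len(known) == len(col)
            and all(len(st) == 1 for st in known)
            and len(frozenset.union(*known)) == 1
        )
        if all_fixed_same:
            continue
        positions.append(pos)
        for sp in group:
            states[(sp, pos)] = col[sp]

    classification = {}
    for pos in positions:
        for sp in group:
            classification[(sp, pos)] = _classify(states, group, sp, pos)
    return DiagnosticProfile(group, tuple(positions), states, classification)


def _classify(states: dict, group: tuple, focal: str, pos: int) -> str:
    own = states[(focal, pos)]
    if len(own) != 1:
        return "uninformative"
    (state,) = own
    others = [states[(sp, pos)] for sp in group if sp != focal]
    # an unknown (empty) state set could contain anything: it can never
    # certify absence, so it blocks exclusivity
    absent = [st for st in others if st and state not in st]
    if len(absent) == len(others):
        return "exclusive"
    if absent:
        return "partial"
    return "uninformative"


def classify_nds(profile: DiagnosticProfile, focal_species: str) -> dict:
    """Exclusive and partial ND lists for one species of the group.

    Returns ``{'exclusive': [(pos, state)], 'partial': [(pos, state,
    excluded_species)]}`` where ``excluded_species`` are the group members
    the partial ND separates the focal species from.
    """
    if focal_species not in profile.group:
        raise ValueError(f"{focal_species!r} not in group {profile.group}")
    exclusive, partial = [], []
    for pos in profile.positions:
        cls = profile.classification[(focal_species, pos)]
        if cls == "uninformative":
            continue
        (state,) = profile.states[(focal_species, pos)]
        if cls == "exclusive":
            exclusive.append((pos, state))
        else:
            excluded = sorted(
                sp
                for sp in profile.group
                if sp != focal_species
                and profile.states[(sp, pos)]
                and state not in profile.states[(sp, pos)]
            )
            partial.append((pos, state, excluded))
    return {"exclusive": exclusive, "partial": partial}


@dataclass
class CombinationResult:
    positions: tuple
    strings: dict           # species -> state string ('*' = polymorphic/unknown)
    unique: dict            # species -> bool
    minimal_subset: tuple   # positions sufficient for every separable pair
    failures: list          # unordered species pairs that cannot be separated


def _separates(profile: DiagnosticProfile, a: str, b: str, pos: int) -> bool:
    sa, sb = profile.states[(a, pos)], profile.states[(b, pos)]
    return len(sa) == 1 and len(sb) == 1 and sa != sb


def combination_discriminator(
    profile: DiagnosticProfile, exhaustive_limit: int = 12
) -> CombinationResult:
    """Combination-based discrimination over the informative positions.

    A species is discriminated by combination iff its state string over the
    informative sites differs from every other species' string, where a
    within-species polymorphic (or unknown) position is a wildcard that
    matches anything — two species are separated at a position only when
    both are fixed there for different states.  The minimal discriminating
    subset covers every separable pair: greedy set cover, replaced by an
    exhaustive search when there are at most ``exhaustive_limit``
    informative positions.
    """
    group, positions = profile.group, profile.positions
    strings = {
        sp: "".join(
            next(iter(profile.states[(sp, p)])) if len(profile.states[(sp, p)]) == 1 else "*"
            for p in positions
        )
        for sp in group
    }
    pair_sites: dict[tuple, set] = {}
    for a, b in itertools.combinations(group, 2):
        pair_sites[(a, b)] = {
            p for p in positions if _separates(profile, a, b, p)
        }
    separable = {pair for pair, sites in pair_sites.items() if sites}
    failures = sorted(pair for pair in pair_sites if pair not in separable)
    unique = {
        sp: all(
            (tuple(sorted((sp, other))) in {tuple(sorted(p)) for p in separable})
            for other in group
            if other != sp
        )
        for sp in group
    }

    minimal: tuple = ()
    if separable:
        if len(positions) <= exhaustive_limit:
            minimal = _exhaustive_cover(positions, pair_sites, separable)
        else:
            minimal = _greedy_cover(positions, pair_sites, separable)
    return CombinationResult(positions, strings, unique, minimal, failures)


def _greedy_cover(positions, pair_sites, separable) -> tuple:
    uncovered = set(separable)
    chosen: list = []
    while uncovered:
        best = max(
            positions,
            key=lambda p: sum(1 for pair in uncovered if p in pair_sites[pair]),
        )
        gain = [pair for pair in uncovered if best in pair_sites[pair]]
        if not gain:  # cannot happen while uncovered <= separable
            break
        chosen.append(best)
        uncovered.difference_update(gain)
    return tuple(sorted(chosen))


def _exhaustive_cover(positions, pair_sites, separable) -> tuple:
    for size in range(1, len(positions) + 1):
        for subset in itertools.combinations(positions, size):
            sset = set(subset)
            if all(pair_sites[pair] & sset for pair in separable):
                return tuple(subset)
    return tuple(positions)


def nd_report(profile: DiagnosticProfile) -> pd.DataFrame:
    """Long-format ND table: species, position, state(s), classification."""
    rows = []
    for sp in profile.group:
        for pos in profile.positions:
            cls = profile.classification[(sp, pos)]
            st = profile.states[(sp, pos)]
            rows.append(
                {
                    "species": sp,
                    "position": pos,
                    "states": "".join(sorted(st)) if st else "?",
                    "classification": cls,
                }
            )
    return pd.DataFrame(rows, columns=["species", "position", "states", "classification"])


def combination_grid(result: CombinationResult) -> pd.DataFrame:
    """Species-by-position character grid over the informative sites."""
    return pd.DataFrame(
        {sp: list(s) for sp, s in result.strings.items()},
        index=list(result.positions),
    ).T
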