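"""Seeded simulator of COI barcode datasets for a recently radiated fauna.

The generator emulates the statistical structure of a large regional
freshwater-fish barcode survey: ~650 bp protein-coding sequences that are
stop-free in the vertebrate mitochondrial code, substitutions concentrated
at third codon positions, shallow congeneric divergence (a recent
radiation), very low within-species divergence per cohesive unit, a small
fraction of species carrying deep intraspecific splits (candidate cryptic
species), and at least one heterospecific shared-haplotype pair.

Sequences evolve down the simulated taxonomy by Poisson substitution from
a stop-free root: each mutation event picks a site with codon-position-
biased probability, applies a transition with odds ``kappa``:2 over the
two transversions, and is resampled if it would create an internal stop
codon.  Intraspecific variation is star-like — independent Poisson
mutation of each specimen from its species (or lineage) centroid — which
reproduces the pairwise-distance moments the downstream analyses consume
without simulating a coalescent genealogy.

Every dataset carries a truth table (specimen lineages, deep-split
species, shared-haplotype pairs, realised codon-position event counts) so
each pipeline stage can be checked against construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from barcode_audit.seqio import SpecimenRecord, write_specimens

_CODES = "ACGT"
# vertebrate mitochondrial stops in 0..3 coding (A=0, C=1, G=2, T=3)
_STOP_CODONS = {(3, 0, 0), (3, 0, 2), (0, 2, 0), (0, 2, 2)}

Range = Union[int, tuple]


@dataclass
class SimConfig:
    """Generator configuration; defaults emulate a megadiverse, recently
    radiated fish fauna sampled at survey scale (~250 species, ~1,200
    specimens in 10 orders).

    Divergence targets are mean pairwise K2P percentages at each rank;
    branch depths are derived from them by halving rank-to-rank
    differences.  Species stem branches are drawn exponentially around
    the calibrated mean (a Yule-like recent radiation), so a realistic
    fraction of congeneric pairs falls below the 2% screening cutoff;
    deeper branches are fixed at their rank means.  ``codon_rate_weights`` are relative substitution rates of
    codon positions (1, 2, 3); the default puts ~60% of events at third
    positions.  ``deep_split_depth`` is the percent divergence range
    between intraspecific lineages of deep-split species, and
    ``deep_split_fraction`` the fraction of species given such lineages.
    """

    n_orders: int = 10
    n_families_per_order: Range = (2, 5)
    n_genera_per_family: Range = (2, 5)
    n_species_per_genus: Range = (1, 3)
    specimens_per_species: tuple = (1, 56)
    specimens_mean: float = 4.9
    seq_length: int = 648
    kappa: float = 6.0
    codon_rate_weights: tuple = (2.0, 1.0, 4.5)
    target_congeneric_divergence: float = 6.8   # % mean, within genus
    target_family_divergence: float = 20.1      # % mean, within family
    target_order_divergence: float = 23.3       # % mean, within order
    target_class_divergence: float = 24.5       # % mean, within class
    intraspecific_theta: float = 0.3            # % expected within-unit divergence
    modal_haplotype_fraction: float = 0.5       # share of specimens carrying the modal haplotype
    min_species_branch: float = 0.25            # % floor under the exponential stem
    deep_split_fraction: float = 0.055
    deep_split_depth: tuple = (1.4, 8.0)        # % between-lineage divergence
    deep_split_lineages: tuple = (2, 3)
    shared_haplotype_pairs: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_orders < 1 or self.seq_length < 3:
            raise ValueError("counts and sequence length must be positive")
        if any(w < 0 for w in self.codon_rate_weights) or sum(self.codon_rate_weights) <= 0:
            raise ValueError("codon rate weights must be non-negative, not all zero")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not 0.0 <= self.deep_split_fraction <= 1.0:
            raise ValueError("deep_split_fraction must be in [0, 1]")
        if self.deep_split_depth[0] <= self.intraspecific_theta:
            raise ValueError(
                "deep_split_depth minimum must exceed intraspecific_theta, "
                "otherwise splits are indistinguishable from noise"
            )
        if self.shared_haplotype_pairs < 0:
            raise ValueError("shared_haplotype_pairs must be >= 0")
        if not 0.0 <= self.modal_haplotype_fraction < 1.0:
            raise ValueError("modal_haplotype_fraction must be in [0, 1)")

    def branch_depths(self) -> dict[str, float]:
        """Per-level branch lengths (substitution events/site), from targets.

        A pair of specimens whose lowest shared rank is the genus diverges
        along two species branches plus two specimen tips, so the species
        branch is half the congeneric target net of the intraspecific tip
        contribution (theta), and so on up the hierarchy.
        """
        tip = self.intraspecific_theta

        def _half(target: float) -> float:
            return max(target - tip, 0.0) / 200.0

        half = {
            "species": _half(self.target_congeneric_divergence),
            "genus": _half(self.target_family_divergence),
            "family": _half(self.target_order_divergence),
            "order": _half(self.target_class_divergence),
        }
        b_s = half["species"]
        b_g = max(half["genus"] - b_s, 0.0)
        b_f = max(half["family"] - b_s - b_g, 0.0)
        b_o = max(half["order"] - b_s - b_g - b_f, 0.0)
        return {"order": b_o, "family": b_f, "genus": b_g, "species": b_s}


@dataclass
class TruthTable:
    """Ground truth emitted alongside a simulated dataset."""

    specimens: pd.DataFrame       # index specimen_id; species, lineage
    species: pd.DataFrame         # index species; is_deep_split, n_lineages, split_depth_pct
    shared_pairs: list            # (species_a, species_b, overwritten_specimen)
    n_events: int
    n_third_position_events: int

    @property
    def third_position_event_share(self) -> float:
        if self.n_events == 0:
            return float("nan")
        return self.n_third_position_events / self.n_events

    def deep_split_species(self) -> list[str]:
        return sorted(self.species.index[self.species["is_deep_split"]])

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        self.specimens.to_csv(outdir / "truth_specimens.tsv", sep="\t")
        self.species.to_csv(outdir / "truth_species.tsv", sep="\t")
        pd.DataFrame(
            self.shared_pairs,
            columns=["species_a", "species_b", "overwritten_specimen"],
        ).to_csv(outdir / "truth_shared_pairs.tsv", sep="\t", index=False)


@dataclass
class SimulatedDataset:
    records: list
    truth: TruthTable
    config: SimConfig
    _centroids: dict = field(default_factory=dict, repr=False)
    _rng: Optional[np.random.Generator] = field(default=None, repr=False)
    _stats: dict = field(default_factory=dict, repr=False)

    def taxonomy(self) -> pd.DataFrame:
        from barcode_audit.seqio import taxonomy_frame

        return taxonomy_frame(self.records)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_specimens(self.records, outdir / "sequences.fasta", outdir / "metadata.tsv")
        self.truth.write(outdir)
        with open(outdir / "sim_config.json", "w") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=2, default=list)


class _Mutator:
    """Applies codon-position-weighted, kappa-biased, stop-avoiding mutations."""

    def __init__(self, config: SimConfig):
        L = config.seq_length
        pos = np.arange(L) % 3
        w = np.asarray(config.codon_rate_weights, dtype=float)[pos]
        self.site_cum = np.cumsum(w / w.sum())
        self.p_ts = config.kappa / (config.kappa + 2.0)
        self.L = L
        self.events = 0
        self.third_position_events = 0

    def mutate(self, seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
        """Evolve a copy of ``seq`` for expected ``t`` substitutions/site."""
        out = seq.copy()
        n = rng.poisson(t * self.L)
        for _ in range(n):
            for _attempt in range(1000):
                site = int(np.searchsorted(self.site_cum, rng.random()))
                base = out[site]
                if rng.random() < self.p_ts:
                    new = base ^ 2
                else:
                    new = base ^ (1 if rng.random() < 0.5 else 3)
                if self._creates_stop(out, site, new):
                    continue
                out[site] = new
                self.events += 1
                if site % 3 == 2:
                    self.third_position_events += 1
                break
        return out

    def _creates_stop(self, seq: np.ndarray, site: int, new: int) -> bool:
        start = site - site % 3
        if start + 3 > self.L:
            return False  # trailing partial codon cannot be a stop
        codon = [int(seq[start]), int(seq[start + 1]), int(seq[start + 2])]
        codon[site - start] = int(new)
        return tuple(codon) in _STOP_CODONS

    def random_root(self, rng: np.random.Generator) -> np.ndarray:
        """A stop-free random sequence of the configured length."""
        seq = np.empty(self.L, dtype=np.uint8)
        n_codons = self.L // 3
        for c in range(n_codons):
            while True:
                codon = tuple(int(x) for x in rng.integers(0, 4, size=3))
                if codon not in _STOP_CODONS:
                    break
            seq[3 * c : 3 * c + 3] = codon
        tail = self.L - 3 * n_codons
        if tail:
            seq[3 * n_codons :] = rng.integers(0, 4, size=tail)
        return seq


def _decode(seq: np.ndarray) -> str:
    return "".join(_CODES[b] for b in seq)


def _draw(rng: np.random.Generator, value: Range) -> int:
    if isinstance(value, int):
        return value
    lo, hi = value
    return int(rng.integers(lo, hi + 1))


def _specimen_seq(
    centroid: np.ndarray, mut: "_Mutator", rng: np.random.Generator, config: SimConfig
) -> np.ndarray:
    """One tip haplotype: the unit's modal haplotype with the configured
    probability, otherwise the centroid mutated at a rate rescaled so the
    expected pairwise within-unit divergence stays at theta."""
    p = config.modal_haplotype_fraction
    if p and rng.random() < p:
        return centroid.copy()
    t = config.intraspecific_theta / (1.0 - p) / 200.0
    return mut.mutate(centroid, t, rng)


def _n_specimens(rng: np.random.Generator, config: SimConfig) -> int:
    lo, hi = config.specimens_per_species
    m = int(rng.geometric(1.0 / config.specimens_mean))
    return int(min(max(m, lo), hi))


def _nearest_congener_gap(centroids: dict, genus_of: dict) -> dict:
    """Per species, the K2P distance (%) to its nearest congener centroid."""
    from barcode_audit.distances import k2p_matrix_from_encoded

    by_genus: dict[str, list[str]] = {}
    for sp in centroids:
        by_genus.setdefault(genus_of[sp], []).append(sp)
    gaps: dict[str, float] = {}
    for genus, members in by_genus.items():
        if len(members) < 2:
            continue
        mat = k2p_matrix_from_encoded(np.vstack([centroids[sp] for sp in members]))
        np.fill_diagonal(mat, np.nan)
        for i, sp in enumerate(members):
            row = mat[i]
            finite = row[np.isfinite(row)]
            gaps[sp] = float(finite.min() * 100.0) if len(finite) else float("inf")
    return gaps


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a full synthetic survey: sequences, metadata and truth.

    Deterministic for a fixed config (byte-identical FASTA for the same
    seed).  Anomalies (deep intraspecific splits and shared-haplotype
    pairs) are applied by :func:`inject_anomalies` as the final step.
    """
    base = _simulate_base(config)
    return inject_anomalies(base, config)


def _simulate_base(config: SimConfig) -> SimulatedDataset:
    config.validate()
    rng = np.random.default_rng(config.seed)
    mut = _Mutator(config)
    depths = config.branch_depths()

    # taxonomy skeleton first, so infeasible anomaly configs fail before
    # any sequence is evolved
    taxa = []  # (order, family, genus, species, n_specimens)
    gi = fi = si = 0
    for oi in range(config.n_orders):
        order = f"Order{oi + 1:02d}"
        for _ in range(_draw(rng, config.n_families_per_order)):
            fi += 1
            family = f"Family{fi:03d}"
            for _ in range(_draw(rng, config.n_genera_per_family)):
                gi += 1
                genus = f"Genus{gi:03d}"
                for k in range(_draw(rng, config.n_species_per_genus)):
                    si += 1
                    species = f"{genus} sp. {k + 1}"
                    taxa.append((order, family, genus, species, _n_specimens(rng, config)))

    genus_sizes = pd.Series([t[2] for t in taxa]).value_counts()
    n_congeneric_pairs = int((genus_sizes * (genus_sizes - 1) // 2).sum())
    if config.shared_haplotype_pairs > n_congeneric_pairs:
        raise ValueError(
            f"config requests {config.shared_haplotype_pairs} shared-haplotype "
            f"pairs but the taxonomy offers only {n_congeneric_pairs} congeneric pairs"
        )

    root = mut.random_root(rng)
    order_c: dict[str, np.ndarray] = {}
    family_c: dict[str, np.ndarray] = {}
    genus_c: dict[str, np.ndarray] = {}
    species_c: dict[str, np.ndarray] = {}
    records: list[SpecimenRecord] = []
    rows = []
    counter = 0
    for order, family, genus, species, m in taxa:
        if order not in order_c:
            order_c[order] = mut.mutate(root, depths["order"], rng)
        if family not in family_c:
            family_c[family] = mut.mutate(order_c[order], depths["family"], rng)
        if genus not in genus_c:
            genus_c[genus] = mut.mutate(family_c[family], depths["genus"], rng)
        # species ages are Yule-like in a recent radiation: exponential
        # stem lengths around the calibrated mean give the long left tail
        # of congeneric divergences; the small floor keeps even the
        # youngest species pairs separable from intraspecific spread, as
        # observed (closely allied pairs remain cohesive clusters)
        floor = config.min_species_branch / 100.0
        stem = floor + rng.exponential(max(depths["species"] - floor, 0.0))
        centroid = mut.mutate(genus_c[genus], stem, rng)
        species_c[species] = centroid
        for _ in range(m):
            counter += 1
            sid = f"SIM{counter:05d}"
            seq = _specimen_seq(centroid, mut, rng, config)
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    species=species,
                    genus=genus,
                    family=family,
                    order=order,
                    class_="Actinopterygii",
                    sequence=_decode(seq),
                )
            )
            rows.append({"specimen_id": sid, "species": species, "lineage": 1})

    specimens = pd.DataFrame(rows).set_index("specimen_id")
    species_frame = pd.DataFrame(
        {
            "is_deep_split": False,
            "n_lineages": 1,
            "split_depth_pct": 0.0,
        },
        index=pd.Index([t[3] for t in taxa], name="species"),
    )
    truth = TruthTable(specimens, species_frame, [], mut.events, mut.third_position_events)
    return SimulatedDataset(
        records,
        truth,
        config,
        _centroids=species_c,
        _rng=rng,
        _stats={"mutator": mut, "genus_centroids": genus_c},
    )


def inject_anomalies(dataset: SimulatedDataset, config: SimConfig) -> SimulatedDataset:
    """Apply deep intraspecific splits and shared-haplotype pairs in place.

    Deep-split species are drawn (without replacement) with probability
    proportional to their number of intraspecific comparisons, among
    species with at least two specimens — deep splits are only observable
    where comparisons exist, and survey-scale splits surface in
    well-sampled species.  A chosen species receives lineage centroids at
    half the split depth around its original centroid, so lineages end up
    the configured depth apart while remaining closer to one another than
    to any congener (the species stays cohesive on the tree for all
    configured depths); its specimens are re-drawn around their assigned
    lineage.

    For each shared-haplotype pair, the second species is re-centred on the
    first's centroid — its specimens are re-drawn around that centroid and
    one of them is overwritten with an exact haplotype of the first
    species.  This reproduces the observed situation (two nominal species
    forming one cohesive haplotype cluster) without manufacturing a deep
    intraspecific split inside the second species.  Deep-split species are
    excluded from these pairs so the two anomaly sets stay disjoint.

    :func:`simulate_dataset` calls this once; calling it again on the same
    dataset would stack further anomalies.
    """
    rng = dataset._rng if dataset._rng is not None else np.random.default_rng(config.seed + 1)
    mut: _Mutator = dataset._stats.get("mutator") or _Mutator(config)
    by_species: dict[str, list[SpecimenRecord]] = {}
    for r in dataset.records:
        by_species.setdefault(r.species, []).append(r)

    # --- deep intraspecific splits ------------------------------------
    all_species = list(dataset.truth.species.index)
    n_deep = int(round(config.deep_split_fraction * len(all_species)))
    sampled = [sp for sp in all_species if len(by_species.get(sp, [])) >= 2]

    lo_d, hi_d = config.deep_split_depth
    # a split deeper than the species' gap to its nearest congener would
    # not present as one deeply divergent species but as a misassigned
    # congener; cap each candidate's admissible depth by that gap
    genus_of_sp = {r.species: r.genus for r in dataset.records}
    congener_gap = _nearest_congener_gap(dataset._centroids, genus_of_sp)
    eligible = [sp for sp in sampled if congener_gap.get(sp, np.inf) > lo_d]
    # at most one deep-split species per genus: two lineage clouds in the
    # same genus can interpenetrate and destroy each other's cohesion
    chosen, used_genera = [], set()
    if eligible and n_deep:
        w = np.array(
            [len(by_species[sp]) * (len(by_species[sp]) - 1) / 2.0 for sp in eligible]
        )
        order = rng.choice(len(eligible), size=len(eligible), replace=False, p=w / w.sum())
        for k in order:
            if len(chosen) == n_deep:
                break
            sp = eligible[int(k)]
            if genus_of_sp[sp] in used_genera:
                continue
            chosen.append(sp)
            used_genera.add(genus_of_sp[sp])
        chosen.sort()
    lo_l, hi_l = config.deep_split_lineages
    for sp in chosen:
        members = by_species[sp]
        centroid = dataset._centroids[sp]
        k = min(_draw(rng, (lo_l, hi_l)), len(members))
        hi_here = min(hi_d, congener_gap.get(sp, np.inf))
        depth = float(rng.uniform(lo_d, hi_here)) / 100.0
        centroids = [mut.mutate(centroid, depth / 2.0, rng) for _ in range(k)]
        assign = np.concatenate(
            [np.arange(k), rng.integers(0, k, size=len(members) - k)]
        )
        rng.shuffle(assign)
        for rec, lin in zip(members, assign):
            seq = _specimen_seq(centroids[int(lin)], mut, rng, config)
            rec.sequence = _decode(seq)
            dataset.truth.specimens.loc[rec.specimen_id, "lineage"] = int(lin) + 1
        dataset.truth.species.loc[sp, ["is_deep_split", "n_lineages", "split_depth_pct"]] = (
            True, k, depth * 100.0,
        )

    # --- shared-haplotype pairs ---------------------------------------
    genus_of = {r.species: r.genus for r in dataset.records}
    deep = set(chosen)
    candidates = []
    species_sorted = sorted(by_species)
    for a_i, sp_a in enumerate(species_sorted):
        for sp_b in species_sorted[a_i + 1 :]:
            if (
                genus_of[sp_a] == genus_of[sp_b]
                and sp_a not in deep
                and sp_b not in deep
            ):
                candidates.append((sp_a, sp_b))
    if config.shared_haplotype_pairs > len(candidates):
        raise ValueError(
            f"cannot place {config.shared_haplotype_pairs} shared-haplotype pairs: "
            f"only {len(candidates)} congeneric non-deep-split pairs available"
        )
    if config.shared_haplotype_pairs:
        picked = rng.choice(len(candidates), size=config.shared_haplotype_pairs, replace=False)
        for k in sorted(picked):
            sp_a, sp_b = candidates[int(k)]
            donor = by_species[sp_a][0]
            donor_centroid = dataset._centroids[sp_a]
            for rec in by_species[sp_b]:
                rec.sequence = _decode(_specimen_seq(donor_centroid, mut, rng, config))
            victim = by_species[sp_b][0]
            victim.sequence = donor.sequence
            dataset.truth.shared_pairs.append((sp_a, sp_b, victim.specimen_id))

    dataset.truth.n_events = mut.events
    dataset.truth.n_third_position_events = mut.third_position_events
    return dataset
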