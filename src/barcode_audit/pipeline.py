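"""Full-audit orchestration: QC -> distances -> summaries -> tree ->
delimitation -> diagnostics, with a run manifest for auditability."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from barcode_audit.seqio import read_specimens, frame_anchor, qc_table, taxonomy_frame, write_specimens
from barcode_audit.distances import DistanceMatrix, pairwise_matrix
from barcode_audit.summaries import (
    barcode_gap_ratio,
    divergence_histogram,
    rank_summary_table,
    summary_frame,
)
from barcode_audit.njtree import nj, bootstrap_support
from barcode_audit.delimit import (
    deep_divergence_flags,
    discrimination_status,
    genus_calibration_table,
    low_divergence_pairs,
    nearest_neighbor_table,
    partition_units,
    subcluster_partition,
)
from barcode_audit.diagnostics import build_site_profiles, classify_nds, combination_discriminator, nd_report


@dataclass
class RunManifest:
    """What a pipeline run saw, chose and produced."""

    version: str
    inputs: dict
    parameters: dict
    counts: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def drop_saturated(dm: DistanceMatrix) -> list[str]:
    """Labels remaining after greedily removing specimens causing undefined
    pairs (each step removes the specimen involved in the most)."""
    remaining = set(dm.labels)
    pairs = [set(p) for p in dm.undefined_pairs]
    while pairs:
        counts: dict[str, int] = {}
        for p in pairs:
            for label in p:
                counts[label] = counts.get(label, 0) + 1
        worst = max(sorted(counts), key=lambda l: counts[l])
        remaining.discard(worst)
        pairs = [p for p in pairs if worst not in p]
    return [l for l in dm.labels if l in remaining]


def run_pipeline(
    fasta,
    meta,
    outdir,
    min_length: int = 500,
    cutoff: float = 0.02,
    n_boot: int = 1000,
    seed: int = 0,
    keep_failures: bool = False,
    subcluster_mode: str = "cutoff",
    force: bool = False,
) -> RunManifest:
    """Run the complete audit and write the report bundle to ``outdir``.

    Outputs: QC table, frame-anchored alignment, distance matrix (TSV and
    PHYLIP), rank divergence summary (raw and subcluster-corrected),
    divergence histogram data, newick tree (with bootstrap supports when
    ``n_boot`` > 0), nearest-neighbour and low-divergence-pair tables,
    deep-divergence flags with subcluster statistics and partition file,
    per-genus calibration table, ND reports for genera containing
    low-divergence pairs, and a JSON manifest.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (use force=True to overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)
    from barcode_audit import __version__

    manifest = RunManifest(
        version=__version__,
        inputs={str(fasta): _sha256(fasta), str(meta): _sha256(meta)},
        parameters={
            "min_length": min_length,
            "cutoff": cutoff,
            "n_boot": n_boot,
            "seed": seed,
            "keep_failures": keep_failures,
            "subcluster_mode": subcluster_mode,
        },
    )
    out: list[Path] = []

    def _emit(frame: pd.DataFrame, name: str, **kw) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=kw.pop("index", False))
        out.append(path)

    # --- QC and frame anchoring ---------------------------------------
    records = read_specimens(fasta, meta)
    anchored, qc_results = frame_anchor(records, min_length=min_length, keep_failures=keep_failures)
    if not anchored:
        raise RuntimeError("qc: every specimen failed quality control")
    _emit(qc_table(qc_results), "qc.tsv")
    write_specimens(anchored, outdir / "aligned.fasta", outdir / "aligned_metadata.tsv")
    out += [outdir / "aligned.fasta", outdir / "aligned_metadata.tsv"]
    manifest.counts["specimens_in"] = len(records)
    manifest.counts["specimens_pass_qc"] = sum(q.passed for q in qc_results)
    manifest.counts["specimens_analyzed"] = len(anchored)
    taxonomy = taxonomy_frame(anchored)
    manifest.counts["species"] = int(taxonomy["species"].nunique())

    # --- distances ----------------------------------------------------
    dm = pairwise_matrix(anchored)
    dm.to_tsv(outdir / "dist.tsv")
    dm.to_phylip(outdir / "dist.phy")
    out += [outdir / "dist.tsv", outdir / "dist.phy"]
    manifest.counts["undefined_pairs"] = len(dm.undefined_pairs)

    # --- rank summaries -----------------------------------------------
    summaries = rank_summary_table(dm, taxonomy)
    _emit(summary_frame(summaries), "rank_summary.tsv")
    hist, below = divergence_histogram(dm, taxonomy, threshold_pct=cutoff * 100.0)
    _emit(hist, "histogram.tsv")
    manifest.counts["pct_below_cutoff"] = {
        k: None if np.isnan(v) else round(v, 2) for k, v in below.items()
    }
    gap = barcode_gap_ratio(summaries)
    manifest.counts["barcode_gap_ratio"] = None if gap is None else round(gap, 2)

    # --- tree ---------------------------------------------------------
    kept = drop_saturated(dm)
    manifest.counts["specimens_on_tree"] = len(kept)
    tree_records = [r for r in anchored if r.specimen_id in set(kept)]
    dm_tree = dm.submatrix(kept)
    if n_boot > 0:
        tree = bootstrap_support(tree_records, n_reps=n_boot, seed=seed)
        manifest.counts["bootstrap_dropped_replicates"] = tree.dropped_replicates
    else:
        tree = nj(dm_tree)
    tree.write(outdir / "tree.nwk")
    out.append(outdir / "tree.nwk")

    # --- delimitation -------------------------------------------------
    nnd = nearest_neighbor_table(dm, taxonomy)
    _emit(pd.DataFrame(nnd), "nnd.tsv")
    pairs = low_divergence_pairs(dm, taxonomy, cutoff=cutoff)
    _emit(
        pd.DataFrame(pairs, columns=["species_a", "species_b", "min_dist_pct"]),
        "low_divergence_pairs.tsv",
    )
    manifest.counts["low_divergence_pairs"] = len(pairs)
    manifest.counts["low_divergence_species"] = len(
        {s for p in pairs for s in p[:2]}
    )
    verdicts, success = discrimination_status(dm_tree, tree, taxonomy.loc[kept])
    _emit(
        pd.DataFrame(
            [
                {
                    "species": v.species,
                    "discriminated": v.discriminated,
                    "failure_mode": v.failure_mode,
                    "offending": ";".join(v.offending),
                }
                for v in verdicts
            ]
        ),
        "discrimination.tsv",
    )
    manifest.counts["discrimination_success_pct"] = round(success * 100.0, 2)

    flags = deep_divergence_flags(dm, taxonomy, cutoff=cutoff)
    _emit(flags, "deep_divergence.tsv")
    manifest.counts["deep_divergence_species"] = len(flags)
    partitions = [
        subcluster_partition(dm, sp, taxonomy, linkage_cutoff=cutoff, mode=subcluster_mode)
        for sp in flags["species"]
    ]
    part_rows, stat_rows = [], []
    for p in partitions:
        for sid, c in sorted(p.assignment.items()):
            part_rows.append({"specimen_id": sid, "species": p.species, "subcluster": c})
        inter = list(p.between_pct.values())
        stat_rows.append(
            {
                "species": p.species,
                "n_subclusters": p.n_subclusters,
                "inter_min_pct": round(min(v[0] for v in inter), 4) if inter else None,
                "inter_max_pct": round(max(v[2] for v in inter), 4) if inter else None,
                "intra_mean_low_pct": _round_opt(min((v for v in p.intra_means_pct.values() if v is not None), default=None)),
                "intra_mean_high_pct": _round_opt(max((v for v in p.intra_means_pct.values() if v is not None), default=None)),
            }
        )
    _emit(pd.DataFrame(part_rows, columns=["specimen_id", "species", "subcluster"]), "partition.tsv")
    _emit(
        pd.DataFrame(
            stat_rows,
            columns=[
                "species", "n_subclusters", "inter_min_pct", "inter_max_pct",
                "intra_mean_low_pct", "intra_mean_high_pct",
            ],
        ),
        "subcluster_stats.tsv",
    )
    units = partition_units(partitions)
    corrected = rank_summary_table(dm, taxonomy, partition=units)
    _emit(summary_frame(corrected), "rank_summary_corrected.tsv")
    cgap = barcode_gap_ratio(corrected)
    manifest.counts["corrected_barcode_gap_ratio"] = None if cgap is None else round(cgap, 2)

    _emit(genus_calibration_table(dm, taxonomy), "genus_calibration.tsv")

    # --- diagnostics for genera containing low-divergence pairs --------
    genus_of = dict(zip(taxonomy.index, taxonomy["genus"]))
    sp_genus = {r.species: r.genus for r in anchored}
    target_genera = sorted({sp_genus[s] for p in pairs for s in p[:2]})
    nd_frames, combo_rows = [], []
    for genus in target_genera:
        members = [r for r in anchored if r.genus == genus]
        if len({r.species for r in members}) < 2:
            continue
        profile = build_site_profiles(members)
        rep = nd_report(profile)
        rep.insert(0, "genus", genus)
        nd_frames.append(rep)
        combo = combination_discriminator(profile)
        for sp in profile.group:
            nds = classify_nds(profile, sp)
            combo_rows.append(
                {
                    "genus": genus,
                    "species": sp,
                    "n_exclusive": len(nds["exclusive"]),
                    "n_partial": len(nds["partial"]),
                    "unique_combination": combo.unique[sp],
                }
            )
    _emit(
        pd.concat(nd_frames, ignore_index=True)
        if nd_frames
        else pd.DataFrame(columns=["genus", "species", "position", "states", "classification"]),
        "nd_report.tsv",
    )
    _emit(
        pd.DataFrame(
            combo_rows,
            columns=["genus", "species", "n_exclusive", "n_partial", "unique_combination"],
        ),
        "nd_summary.tsv",
    )

    manifest.outputs = sorted(str(p.name) for p in out) + ["manifest.json"]
    manifest.write(outdir / "manifest.json")
    return manifest


def _round_opt(v, ndigits: int = 4):
    return None if v is None else round(v, ndigits)
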