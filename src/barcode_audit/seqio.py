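"""Specimen input/output and barcode quality control.

COI barcodes are protein-coding mitochondrial fragments: a clean barcode
reads through in one frame of the vertebrate mitochondrial code with no
internal stop codons and no indels.  This module loads FASTA + metadata
into :class:`SpecimenRecord` objects, finds the reading frame of each
sequence (all six frame/strand combinations are scanned), applies the
standard barcode quality filters (length, stop codons, internal gaps) and
anchors a set of records into a common frame so that downstream distance
computation can treat them as a gap-free alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Stop codons of the vertebrate mitochondrial code (NCBI table 2).
VERTEBRATE_MITO_STOPS = frozenset(
    CodonTable.unambiguous_dna_by_id[2].stop_codons
)

LINEAGE_FIELDS = ("species", "genus", "family", "order", "class")

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")
# IUPAC ambiguity codes other than N carry too little signal for pairwise
# deletion to exploit; they are all normalised to N.
_AMBIGUITY = str.maketrans({c: "N" for c in "RYSWKMBDHVU"})


@dataclass
class SpecimenRecord:
    """One barcode sequence with its full taxonomic lineage.

    ``species`` may be a binomial or an interim "Genus sp. N" label; interim
    labels are treated as full species-rank units throughout the pipeline.
    """

    specimen_id: str
    species: str
    genus: str
    family: str
    order: str
    class_: str
    sequence: str
    site_lat: Optional[float] = None
    site_lon: Optional[float] = None

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if not self.sequence:
            raise ValueError(f"{self.specimen_id}: empty sequence")

    def lineage(self) -> dict:
        return {
            "species": self.species,
            "genus": self.genus,
            "family": self.family,
            "order": self.order,
            "class": self.class_,
        }


@dataclass
class QCResult:
    """Verdict of the barcode quality filters for one specimen.

    ``frame`` is the 0-based offset of the best reading frame on ``strand``
    ('+' or '-'); "best" means fewest internal stop codons.  ``passed`` is
    true iff the sequence is long enough, stop-free in its best frame and
    free of internal gaps.
    """

    record_id: str
    passed: bool
    length_ok: bool
    frame: int
    strand: str
    stop_codons: int
    has_internal_gaps: bool
    ambiguity_fraction: float


def normalize_sequence(seq: str) -> str:
    """Upper-case, map non-N ambiguity codes to N, validate the alphabet."""
    s = seq.upper().translate(_AMBIGUITY)
    bad = set(s) - set("ACGTN-")
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _count_stops(seq: str, frame: int) -> int:
    """Stop codons among the complete codons of ``seq`` read from ``frame``.

    Trailing partial codons are ignored.  Codons containing N or a gap never
    match a stop codon.
    """
    n_codons = (len(seq) - frame) // 3
    count = 0
    for k in range(n_codons):
        codon = seq[frame + 3 * k : frame + 3 * k + 3]
        if codon in VERTEBRATE_MITO_STOPS:
            count += 1
    return count


def best_frame(seq: str) -> tuple[int, str, int]:
    """Return ``(frame, strand, stop_count)`` minimising internal stops.

    Ties prefer the forward strand, then the lowest frame offset.  The scan
    is done on the gap-stripped sequence.
    """
    s = seq.replace("-", "")
    best: tuple[int, str, int] | None = None
    for strand, oriented in (("+", s), ("-", reverse_complement(s))):
        for frame in (0, 1, 2):
            stops = _count_stops(oriented, frame)
            if best is None or stops < best[2]:
                best = (frame, strand, stops)
    assert best is not None
    return best


def qc_record(record: SpecimenRecord, min_length: int = 500) -> QCResult:
    """Apply the barcode quality filters to one specimen.

    A record passes iff its ungapped length is >= ``min_length``, its best
    reading frame (over both strands) contains no stop codon of the
    vertebrate mitochondrial code, and it has no internal gap.
    """
    seq = record.sequence
    ungapped = seq.replace("-", "")
    length_ok = len(ungapped) >= min_length
    has_internal_gaps = "-" in seq.strip("-")
    frame, strand, stops = best_frame(seq)
    ambiguity = ungapped.count("N") / len(ungapped) if ungapped else 0.0
    passed = length_ok and stops == 0 and not has_internal_gaps
    return QCResult(
        record_id=record.specimen_id,
        passed=passed,
        length_ok=length_ok,
        frame=frame,
        strand=strand,
        stop_codons=stops,
        has_internal_gaps=has_internal_gaps,
        ambiguity_fraction=ambiguity,
    )


def read_metadata(metadata_path) -> pd.DataFrame:
    """Read the tab-separated specimen metadata table.

    Required columns: specimen_id, species, genus, family, order, class.
    Optional: lat, lon.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = ["specimen_id", *LINEAGE_FIELDS]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    dup = meta["specimen_id"][meta["specimen_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate specimen IDs in metadata: {sorted(set(dup))}")
    return meta.set_index("specimen_id")


def read_specimens(fasta_path, metadata_path) -> list[SpecimenRecord]:
    """Join a FASTA file against its metadata table into specimen records.

    Every FASTA entry must have a metadata row; metadata rows without a
    FASTA entry are reported with a warning and skipped.
    """
    meta = read_metadata(metadata_path)
    records = []
    seen: set[str] = set()
    unmatched: list[str] = []
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        sid = entry.id
        if sid in seen:
            raise ValueError(f"duplicate specimen ID in FASTA: {sid}")
        seen.add(sid)
        if sid not in meta.index:
            unmatched.append(sid)
            continue
        row = meta.loc[sid]
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                species=row["species"],
                genus=row["genus"],
                family=row["family"],
                order=row["order"],
                class_=row["class"],
                sequence=str(entry.seq),
                site_lat=_maybe_float(row.get("lat")),
                site_lon=_maybe_float(row.get("lon")),
            )
        )
    if unmatched:
        raise ValueError(f"FASTA entries with no metadata row: {unmatched}")
    orphans = sorted(set(meta.index) - seen)
    if orphans:
        warnings.warn(f"metadata rows with no FASTA entry: {orphans}", stacklevel=2)
    return records


def _maybe_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str) and (value == "" or value.lower() == "nan"):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def write_specimens(records: Sequence[SpecimenRecord], fasta_path, metadata_path) -> None:
    """Emit records as FASTA plus the tab-separated metadata table."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.specimen_id, description="")
        for r in records
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    rows = []
    for r in records:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                **r.lineage(),
                "lat": "" if r.site_lat is None else r.site_lat,
                "lon": "" if r.site_lon is None else r.site_lon,
            }
        )
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def taxonomy_frame(records: Iterable[SpecimenRecord]) -> pd.DataFrame:
    """Specimen-indexed lineage table (species..class) used by every summary."""
    rows = {r.specimen_id: r.lineage() for r in records}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "specimen_id"
    return frame


def frame_anchor(
    records: Sequence[SpecimenRecord],
    min_length: int = 500,
    keep_failures: bool = False,
) -> tuple[list[SpecimenRecord], list[QCResult]]:
    """Anchor mutually indel-free barcodes into a common reading frame.

    Each record is oriented to the forward strand, its leading off-frame
    bases are trimmed so every sequence starts on a codon boundary, and all
    sequences are truncated to the shortest common length (floored to a
    whole number of codons).  QC failures are excluded unless
    ``keep_failures`` is set; QC results for all input records are returned
    alongside.

    This presumes the inputs are coamplified fragments of the same locus
    (true of COI barcodes), so that codon phase is the only alignment degree
    of freedom; it deliberately does not handle indels, which fail QC.
    """
    results = [qc_record(r, min_length=min_length) for r in records]
    anchored: list[SpecimenRecord] = []
    kept_qc: list[QCResult] = []
    for rec, qc in zip(records, results):
        if not qc.passed and not keep_failures:
            continue
        seq = rec.sequence.replace("-", "")
        if qc.strand == "-":
            seq = reverse_complement(seq)
        seq = seq[qc.frame :]
        anchored.append(
            SpecimenRecord(
                specimen_id=rec.specimen_id,
                species=rec.species,
                genus=rec.genus,
                family=rec.family,
                order=rec.order,
                class_=rec.class_,
                sequence=seq,
                site_lat=rec.site_lat,
                site_lon=rec.site_lon,
            )
        )
        kept_qc.append(qc)
    if not anchored:
        return [], results
    common = min(len(r.sequence) for r in anchored)
    common -= common % 3
    for r in anchored:
        r.sequence = r.sequence[:common]
    return anchored, results


def qc_table(results: Sequence[QCResult]) -> pd.DataFrame:
    """QC results as a DataFrame ready for TSV export."""
    return pd.DataFrame(
        [
            {
                "specimen_id": q.record_id,
                "passed": q.passed,
                "length_ok": q.length_ok,
                "frame": q.frame,
                "strand": q.strand,
                "stop_codons": q.stop_codons,
                "has_internal_gaps": q.has_internal_gaps,
                "ambiguity_fraction": round(q.ambiguity_fraction, 6),
            }
            for q in results
        ]
    )
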