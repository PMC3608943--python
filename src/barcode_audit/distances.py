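"""Kimura-2-parameter pairwise distances with pairwise deletion.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions.
With P and Q the observed proportions of transitional and transversional
differences over the n sites comparable in a pair (pairwise deletion: a
site is dropped for that pair only if either sequence has N or a gap
there),

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

in substitutions per site.  Pairs for which either logarithm argument is
non-positive are saturated: the distance is undefined and recorded as such
rather than clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd


class SaturatedPairError(ValueError):
    """K2P is undefined for this pair (too many observed differences)."""


class SitePairCounts(NamedTuple):
    comparable_sites: int
    transitions: int
    transversions: int


# Byte-level encoding: A,C,G,T -> 0..3 so that purines are even and
# pyrimidines odd; a mismatch is a transition iff the XOR of the codes is
# even.  Anything else (N, -) encodes to 255 and is invisible to the pair.
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a normalised nucleotide string to the internal byte code."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def site_counts(seq_a: str, seq_b: str) -> SitePairCounts:
    """Comparable sites, transitions and transversions for one pair.

    Positions with N or '-' in either sequence are excluded from all
    counts (pairwise deletion).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences of unequal length ({len(seq_a)} vs {len(seq_b)})"
        )
    a, b = encode(seq_a), encode(seq_b)
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no overlap: zero comparable sites")
    mism = (a != b) & valid
    ts = int((mism & (((a ^ b) & 1) == 0)).sum())
    return SitePairCounts(n, ts, int(mism.sum()) - ts)


def k2p(counts: SitePairCounts) -> float:
    """K2P distance from site-pair counts; raises on saturation."""
    n, ts, tv = counts
    if n <= 0:
        raise ValueError("comparable_sites must be positive")
    p, q = ts / n, tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedPairError(
            f"saturated pair: P={p:.4f}, Q={q:.4f} leave log argument <= 0"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0  # +0.0 kills -0.0


@dataclass
class DistanceMatrix:
    """Symmetric specimen-by-specimen K2P distance matrix.

    Distances are proportions (substitutions/site); reports multiply by
    100.  Saturated or non-overlapping pairs hold NaN and are listed in
    ``undefined_pairs``.
    """

    labels: list[str]
    values: np.ndarray
    undefined_pairs: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def condensed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle pair indices (i, j) and their distances."""
        i, j = np.triu_indices(len(self.labels), 1)
        return i, j, self.values[i, j]

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        sub = self.values[np.ix_(idx, idx)]
        und = {
            p for p in self.undefined_pairs if p <= set(labels)
        }
        return DistanceMatrix(list(labels), sub, und)

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    # --- text formats -------------------------------------------------

    def to_tsv(self, path) -> None:
        frame = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        frame.to_csv(path, sep="\t", float_format="%.8f")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        labels = [str(l) for l in frame.index]
        values = frame.to_numpy(dtype=float)
        i, j = np.triu_indices(len(labels), 1)
        und = {
            frozenset((labels[a], labels[b]))
            for a, b in zip(i, j)
            if np.isnan(values[a, b])
        }
        return cls(labels, values, und)

    def to_phylip(self, path) -> None:
        """Square PHYLIP format; NaN written as -1.0 (no PHYLIP convention)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                vals = " ".join(
                    f"{v:.8f}" if np.isfinite(v) else "-1.00000000" for v in row
                )
                fh.write(f"{label:<12s}{vals}\n")

    @classmethod
    def from_phylip(cls, path) -> "DistanceMatrix":
        """Read the square PHYLIP format written by :meth:`to_phylip`."""
        with open(path) as fh:
            n = int(fh.readline().strip())
            labels, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        values = np.asarray(rows, dtype=float)
        values[values < 0] = np.nan
        i, j = np.triu_indices(n, 1)
        und = {
            frozenset((labels[a], labels[b]))
            for a, b in zip(i, j)
            if np.isnan(values[a, b])
        }
        return cls(labels, values, und)


def k2p_matrix_from_encoded(enc: np.ndarray) -> np.ndarray:
    """K2P matrix over the rows of an encoded (n, L) uint8 array.

    Vectorised over pairs; undefined entries (saturated or zero-overlap)
    are NaN.  This is the kernel shared by :func:`pairwise_matrix` and the
    bootstrap, which resamples columns of the encoded array.
    """
    n = enc.shape[0]
    out = np.zeros((n, n), dtype=float)
    valid = enc < 4
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(n - 1):
            a, va = enc[i], valid[i]
            rest, vrest = enc[i + 1 :], valid[i + 1 :]
            both = va & vrest
            ncomp = both.sum(axis=1)
            mism = (rest != a) & both
            nm = mism.sum(axis=1)
            ts = (mism & (((rest ^ a) & 1) == 0)).sum(axis=1)
            p = ts / ncomp
            q = (nm - ts) / ncomp
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            ok = (ncomp > 0) & (w1 > 0.0) & (w2 > 0.0)
            d = np.where(
                ok,
                -0.5 * np.log(np.where(ok, w1, 1.0))
                - 0.25 * np.log(np.where(ok, w2, 1.0)),
                np.nan,
            )
            d = d + 0.0  # normalise -0.0
            out[i, i + 1 :] = d
            out[i + 1 :, i] = d
    return out


def pairwise_matrix(records: Sequence) -> DistanceMatrix:
    """Full K2P distance matrix over aligned specimen records.

    ``records`` may be :class:`~barcode_audit.seqio.SpecimenRecord` objects
    or ``(label, sequence)`` pairs; all sequences must have equal length.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    labels, seqs = [], []
    for r in records:
        if hasattr(r, "specimen_id"):
            labels.append(r.specimen_id)
            seqs.append(r.sequence)
        else:
            label, seq = r
            labels.append(label)
            seqs.append(seq)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences not aligned: lengths {sorted(lengths)}")
    enc = np.vstack([encode(s) for s in seqs])
    values = k2p_matrix_from_encoded(enc)
    i, j = np.triu_indices(len(labels), 1)
    und = {
        frozenset((labels[a], labels[b]))
        for a, b in zip(i, j)
        if np.isnan(values[a, b])
    }
    return DistanceMatrix(labels, values, und)
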