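"""Raw read handling: locus assignment, primer trimming, pair merging.

Each koala's pooled amplicon reads are sorted into gene targets by
matching both primers at the read starts (IUPAC-aware, substitutions
only), primer-trimmed, length-culled, and merged into full amplicon
interiors by overlap consensus.  The amplicon interior is always
reported on the forward-primer strand; all coordinates are 0-based
half-open.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .loci import IUPAC, LocusSpec

# Read status labels used in processing logs.
MERGED = "merged"
UNASSIGNED = "unassigned"
CULLED = "culled"
UNMERGED = "unmerged"

_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}

# 256-entry lookup: plain base -> its bit; IUPAC code -> union of bits;
# anything else -> 0 (mismatches everything).
_ENCODE = np.zeros(256, dtype=np.uint8)
for _code, _expansion in IUPAC.items():
    _bits = 0
    for _b in _expansion:
        _bits |= _BASE_BITS[_b]
    _ENCODE[ord(_code)] = _bits
    _ENCODE[ord(_code.lower())] = _bits

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Encode a sequence as per-base IUPAC bit sets (uint8 array)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class ReadPair:
    """One paired-end read with Phred qualities (arrays of ints)."""

    read_id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: np.ndarray
    rev_qual: np.ndarray

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"read {self.read_id}: sequence/quality length mismatch")


@dataclass
class MergedRead:
    """A merged amplicon interior with per-base consensus quality."""

    read_id: str
    locus: str
    sequence: str
    support: np.ndarray


def primer_mismatches(read_prefix: str, primer: str) -> int:
    """Substitution count between a primer and the read prefix under it.

    IUPAC degenerate codes in the primer match their expansion set.
    Returns a large count when the read is shorter than the primer.
    """
    if len(read_prefix) < len(primer):
        return len(primer)
    p = encode_bases(primer)
    r = encode_bases(read_prefix[: len(primer)])
    return int(np.count_nonzero((p & r) == 0))


def assign_locus(
    pair: ReadPair,
    loci: Sequence[LocusSpec],
    max_mismatches: int = 2,
) -> str | None:
    """Assign a read pair to the unique locus whose primers match both mates.

    The forward primer must match a prefix of the forward mate and the
    reverse primer a prefix of the reverse mate, each with at most
    ``max_mismatches`` substitutions (no indels).  Returns the locus name,
    or None when no locus — or more than one — matches.
    """
    hits = [
        spec.name
        for spec in loci
        if primer_mismatches(pair.fwd_seq, spec.forward_primer) <= max_mismatches
        and primer_mismatches(pair.rev_seq, spec.reverse_primer) <= max_mismatches
    ]
    if len(hits) == 1:
        return hits[0]
    return None


def trim_and_cull(
    pair: ReadPair,
    locus: LocusSpec,
    min_len: int = 150,
) -> ReadPair | None:
    """Remove primers and 3' read-through; drop pairs with a short mate.

    Each mate loses its leading primer bases, and is then truncated to the
    amplicon interior length so that any read-through into the opposite
    primer's reverse complement (and beyond) is removed.  Pairs in which
    either trimmed mate is strictly shorter than ``min_len`` are culled
    (None).
    """
    interior = locus.interior_length
    f0 = len(locus.forward_primer)
    r0 = len(locus.reverse_primer)
    fwd = pair.fwd_seq[f0 : f0 + interior]
    rev = pair.rev_seq[r0 : r0 + interior]
    if len(fwd) < min_len or len(rev) < min_len:
        return None
    return ReadPair(
        read_id=pair.read_id,
        fwd_seq=fwd,
        rev_seq=rev,
        fwd_qual=pair.fwd_qual[f0 : f0 + interior],
        rev_qual=pair.rev_qual[r0 : r0 + interior],
    )


def merge_pair(
    pair: ReadPair,
    locus: str,
    min_overlap: int = 10,
    max_mismatch_density: float = 0.25,
) -> MergedRead | None:
    """Merge a trimmed pair into one amplicon interior by overlap consensus.

    The reverse mate is reverse-complemented, then every offset of its
    start within the forward mate is considered.  Admissible offsets have
    overlap >= ``min_overlap`` and mismatch fraction <= ``max_mismatch_density``;
    among them the longest overlap wins, ties broken by fewest mismatches,
    then by smallest offset.  At conflicting overlap positions the
    higher-quality base is taken (tie: the forward base).  Returns None
    when no admissible offset exists.
    """
    f_seq = np.frombuffer(pair.fwd_seq.encode("ascii"), dtype=np.uint8)
    rc = revcomp(pair.rev_seq)
    r_seq = np.frombuffer(rc.encode("ascii"), dtype=np.uint8)
    f_qual = np.asarray(pair.fwd_qual)
    r_qual = np.asarray(pair.rev_qual)[::-1]
    lf, lr = len(f_seq), len(r_seq)

    # Offsets grouped by overlap length, longest first.  Within one group
    # all offsets are evaluated so the mismatch-count tie-break is exact;
    # later (shorter) groups are skipped once a winner exists.
    offsets = [(min(lf - o, lr), o) for o in range(0, lf - min_overlap + 1)]
    offsets = [(ov, o) for ov, o in offsets if ov >= min_overlap]
    offsets.sort(key=lambda t: (-t[0], t[1]))

    best: tuple[int, int, int] | None = None  # (-overlap, mismatches, offset)
    i = 0
    while i < len(offsets):
        ov = offsets[i][0]
        group = []
        while i < len(offsets) and offsets[i][0] == ov:
            group.append(offsets[i][1])
            i += 1
        for o in group:
            mism = int(np.count_nonzero(f_seq[o : o + ov] != r_seq[: ov]))
            if mism <= max_mismatch_density * ov:
                cand = (-ov, mism, o)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            break
    if best is None:
        return None

    ov = -best[0]
    o = best[2]
    # Consensus over the overlap region.
    fo_seq, fo_q = f_seq[o : o + ov], f_qual[o : o + ov]
    ro_seq, ro_q = r_seq[:ov], r_qual[:ov]
    take_rev = (fo_seq != ro_seq) & (ro_q > fo_q)
    cons_seq = np.where(take_rev, ro_seq, fo_seq)
    cons_q = np.maximum(fo_q, ro_q)

    parts_seq = [f_seq[:o], cons_seq]
    parts_q = [f_qual[:o], cons_q]
    if o + lr > lf:
        parts_seq.append(r_seq[ov:])
        parts_q.append(r_qual[ov:])
    elif o + lr < lf:  # reverse mate nested inside the forward mate
        parts_seq.append(f_seq[o + lr :])
        parts_q.append(f_qual[o + lr :])
    merged = np.concatenate(parts_seq)
    return MergedRead(
        read_id=pair.read_id,
        locus=locus,
        sequence=merged.tobytes().decode("ascii"),
        support=np.concatenate(parts_q),
    )


# ---------------------------------------------------------------------------
# FASTQ I/O and the per-individual processing loop


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(r1: str | Path, r2: str | Path) -> Iterator[ReadPair]:
    """Iterate synchronized mates from a pair of (optionally gzipped) FASTQs."""
    with _open_maybe_gzip(r1) as fh1, _open_maybe_gzip(r2) as fh2:
        it1 = SeqIO.parse(fh1, "fastq")
        it2 = SeqIO.parse(fh2, "fastq")
        for rec1, rec2 in zip(it1, it2, strict=True):
            yield ReadPair(
                read_id=rec1.id,
                fwd_seq=str(rec1.seq).upper(),
                rev_seq=str(rec2.seq).upper(),
                fwd_qual=np.array(rec1.letter_annotations["phred_quality"]),
                rev_qual=np.array(rec2.letter_annotations["phred_quality"]),
            )


@dataclass
class ProcessingParams:
    max_primer_mismatches: int = 2
    min_read_length: int = 150
    min_overlap: int = 10
    max_mismatch_density: float = 0.25


def process_pairs(
    pairs: Iterable[ReadPair],
    loci: Sequence[LocusSpec],
    params: ProcessingParams | None = None,
) -> tuple[list[MergedRead], list[tuple[str, str, str]]]:
    """Run assign → trim/cull → merge over read pairs.

    Returns the merged reads and a log of ``(read_id, locus, status)``
    rows with status in {merged, unassigned, culled, unmerged}.
    """
    params = params or ProcessingParams()
    by_name = {spec.name: spec for spec in loci}
    merged_reads: list[MergedRead] = []
    log: list[tuple[str, str, str]] = []
    for pair in pairs:
        locus = assign_locus(pair, loci, params.max_primer_mismatches)
        if locus is None:
            log.append((pair.read_id, "", UNASSIGNED))
            continue
        trimmed = trim_and_cull(pair, by_name[locus], params.min_read_length)
        if trimmed is None:
            log.append((pair.read_id, locus, CULLED))
            continue
        merged = merge_pair(
            trimmed, locus, params.min_overlap, params.max_mismatch_density
        )
        if merged is None:
            log.append((pair.read_id, locus, UNMERGED))
            continue
        merged_reads.append(merged)
        log.append((pair.read_id, locus, MERGED))
    return merged_reads, log
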