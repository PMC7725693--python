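"""Allele assignment and genotype calling.

Merged amplicon interiors are matched to the reference database (exact
match first, then global pairwise alignment identity), tallied per
locus, and alleles representing strictly more than 10% of a target's
reads are called present.  Highly duplicated unmatched sequences above
the same threshold are registered as novel alleles and the reads are
re-tallied against the augmented database until no new candidate
appears.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .loci import Allele, ReferenceDatabase
from .reads import MergedRead

# Sentinels for per-read match outcomes.
NOMATCH = "<nomatch>"
AMBIGUOUS = "<ambiguous>"

#: Sentinel for a locus with no reads; distinct from an empty call set so
#: pedigree checks can skip missing loci rather than score them.
NO_DATA = None

DEFAULT_THRESHOLD = 0.10
DEFAULT_MIN_IDENTITY = 0.98
DEFAULT_MIN_COPIES = 10


def match_allele(
    seq: str,
    db: ReferenceDatabase,
    locus: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> str:
    """Match one merged read to the best reference allele at its locus.

    An exact sequence match wins immediately.  Otherwise every allele at
    the locus is aligned globally (edit distance, substitutions and
    indels) and identity is 1 - distance / max(length).  The best allele
    is returned if its identity reaches ``min_identity``; a tie between
    two alleles at the best identity is AMBIGUOUS; a best identity below
    the cutoff is NOMATCH.
    """
    exact = db.find_sequence(locus, seq)
    if exact is not None:
        return exact.label
    alleles = db.alleles_at(locus)  # raises for an unknown locus
    best_label = NOMATCH
    best_identity = -1.0
    tied = False
    for allele in alleles:
        res = edlib.align(seq, allele.sequence, mode="NW", task="distance")
        identity = 1.0 - res["editDistance"] / max(len(seq), len(allele.sequence))
        if identity > best_identity:
            best_identity, best_label, tied = identity, allele.label, False
        elif identity == best_identity:
            tied = True
    if best_identity < min_identity:
        return NOMATCH
    if tied:
        return AMBIGUOUS
    return best_label


@dataclass
class AlleleTally:
    """Per-(individual, locus) read counts by allele plus unmatched sequences."""

    individual: str
    locus: str
    counts: Counter = field(default_factory=Counter)
    unmatched: Counter = field(default_factory=Counter)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values()) + sum(self.unmatched.values())


@dataclass
class KoalaProfile:
    """Called allele sets per locus for one koala (None = no data)."""

    individual: str
    calls: dict[str, frozenset[str] | None] = field(default_factory=dict)


def tally_reads(
    merged: Iterable[MergedRead],
    db: ReferenceDatabase,
    individual: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> dict[str, AlleleTally]:
    """Tally merged reads per locus against the reference database.

    NOMATCH and AMBIGUOUS reads accumulate in ``unmatched`` keyed by exact
    sequence; ambiguous reads never increment allele counts (avoids
    double counting between near-identical alleles).
    """
    tallies: dict[str, AlleleTally] = {}
    cache: dict[tuple[str, str], str] = {}
    for read in merged:
        tally = tallies.setdefault(
            read.locus, AlleleTally(individual=individual, locus=read.locus)
        )
        key = (read.locus, read.sequence)
        label = cache.get(key)
        if label is None:
            label = match_allele(read.sequence, db, read.locus, min_identity)
            cache[key] = label
        if label in (NOMATCH, AMBIGUOUS):
            tally.unmatched[read.sequence] += 1
        else:
            tally.counts[label] += 1
    return tallies


def call_alleles(
    tally: AlleleTally,
    threshold: float = DEFAULT_THRESHOLD,
    max_alleles: int | None = None,
) -> frozenset[str] | None:
    """Call alleles present at strictly more than ``threshold`` of reads.

    A read fraction exactly at the threshold is NOT called.  Returns
    NO_DATA (None) when the tally holds no reads.  ``max_alleles`` is the
    locus's biological ceiling; exceeding it only warns, since the data
    cap the result.
    """
    total = tally.total_reads
    if total == 0:
        return NO_DATA
    called = frozenset(
        label for label, n in tally.counts.items() if n / total > threshold
    )
    if max_alleles is not None and len(called) > max_alleles:
        warnings.warn(
            f"{tally.individual} {tally.locus}: {len(called)} alleles called, "
            f"locus maximum is {max_alleles}",
            stacklevel=2,
        )
    return called


def detect_novel(
    tally: AlleleTally,
    db: ReferenceDatabase,
    threshold: float = DEFAULT_THRESHOLD,
    min_copies: int = DEFAULT_MIN_COPIES,
) -> list[Allele]:
    """Register highly duplicated unmatched sequences as novel alleles.

    An exact-duplicate cluster qualifies when its read count exceeds
    ``threshold`` of the locus total AND reaches ``min_copies`` reads
    (guards tiny-depth pathologies).  Smaller clusters are left as noise.
    """
    total = tally.total_reads
    if total == 0:
        return []
    novel: list[Allele] = []
    for seq, n in sorted(tally.unmatched.items(), key=lambda kv: (-kv[1], kv[0])):
        if n / total > threshold and n >= min_copies:
            if db.find_sequence(tally.locus, seq) is None:
                novel.append(db.register_novel(tally.locus, seq))
    return novel


@dataclass
class GenotypingParams:
    threshold: float = DEFAULT_THRESHOLD
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_novel_copies: int = DEFAULT_MIN_COPIES
    max_rounds: int = 3


def genotype_individual(
    merged: Sequence[MergedRead],
    db: ReferenceDatabase,
    individual: str,
    params: GenotypingParams | None = None,
) -> tuple[KoalaProfile, dict[str, AlleleTally]]:
    """Tally, discover novel alleles, re-tally, and call one koala.

    Novel-allele discovery and re-tallying iterate until no new candidate
    appears (at most ``max_rounds`` rounds); each round is deterministic
    given the read multiset.  Novel alleles are added to ``db`` and so
    become visible to subsequently genotyped individuals, mirroring the
    running reference list of the original workflow.
    """
    params = params or GenotypingParams()
    tallies = tally_reads(merged, db, individual, params.min_identity)
    for _ in range(params.max_rounds):
        new = [
            allele
            for tally in tallies.values()
            for allele in detect_novel(
                tally, db, params.threshold, params.min_novel_copies
            )
        ]
        if not new:
            break
        tallies = tally_reads(merged, db, individual, params.min_identity)
    profile = KoalaProfile(individual=individual)
    for locus, tally in tallies.items():
        spec = db.loci[locus]
        profile.calls[locus] = call_alleles(
            tally, params.threshold, spec.max_alleles_per_individual
        )
    return profile, tallies


# ---------------------------------------------------------------------------
# Profile table I/O (one row per koala, alleles semicolon-joined and sorted)


def write_profiles(
    profiles: Sequence[KoalaProfile],
    path: str | Path,
    locus_order: Sequence[str],
) -> None:
    rows = []
    for p in profiles:
        row: dict[str, str] = {"individual": p.individual}
        for locus in locus_order:
            calls = p.calls.get(locus, NO_DATA)
            row[locus] = "NA" if calls is NO_DATA else ";".join(sorted(calls))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> list[KoalaProfile]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("NA")
    loci = [c for c in df.columns if c != "individual"]
    profiles = []
    for _, row in df.iterrows():
        calls: dict[str, frozenset[str] | None] = {}
        for locus in loci:
            cell = row[locus]
            calls[locus] = NO_DATA if cell == "NA" else frozenset(cell.split(";"))
        profiles.append(KoalaProfile(individual=row["individual"], calls=calls))
    return profiles


def write_tallies(
    tallies: Mapping[str, AlleleTally],
    db: ReferenceDatabase,
    path: str | Path,
) -> None:
    """Per-locus tally TSV: individual, locus, allele, count, fraction, provenance."""
    rows = []
    for locus in sorted(tallies):
        tally = tallies[locus]
        total = tally.total_reads
        for label, n in sorted(tally.counts.items()):
            allele = db.get(locus, label)
            rows.append(
                {
                    "individual": tally.individual,
                    "locus": locus,
                    "allele": label,
                    "count": n,
                    "fraction": round(n / total, 6),
                    "provenance": allele.provenance if allele else "unknown",
                }
            )
        n_unmatched = sum(tally.unmatched.values())
        if n_unmatched:
            rows.append(
                {
                    "individual": tally.individual,
                    "locus": locus,
                    "allele": "<unmatched>",
                    "count": n_unmatched,
                    "fraction": round(n_unmatched / total, 6),
                    "provenance": "unmatched",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
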