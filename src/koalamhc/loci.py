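"""Locus configuration and reference allele database.

The six gene targets (class I UA and UC, class II DAB, DBB, DCB and DMB)
are each defined by an exon-2 primer pair, an amplicon size and a genome
copy number.  Allele sequences are stored primer-trimmed (amplicon
interior only) so that merged, trimmed reads can be compared to them
directly.  The UA primer pair also amplifies the paralogous UB gene; the
UA target is therefore treated as one pooled UA+UB target and no attempt
is made to assign alleles to a gene of origin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

#: IUPAC nucleotide codes and their expansion sets.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_PRIMER_RE = re.compile(r"^[ACGTRYSWKMBDHVN]+$")
_SEQ_RE = re.compile(r"^[ACGT]+$")

#: Minimum trimmed amplicon/read length retained by the pipeline (bp).
MIN_AMPLICON_INTERIOR = 150


class LocusTableError(ValueError):
    """Raised for malformed or inconsistent locus configuration tables."""


class ReferenceError(ValueError):
    """Raised for invalid reference-database content."""


@dataclass(frozen=True)
class LocusSpec:
    """One PCR gene target.

    ``amplicon_length`` includes both primers; ``genome_copies`` is the
    number of gene loci in the genome hit by the primary target (1 or 3).
    ``coamplified_paralog`` names a paralogous gene also amplified by the
    same primers (UB for the UA target), which adds one more diploid gene
    to the pooled target.
    """

    name: str
    mhc_class: str
    forward_primer: str
    reverse_primer: str
    amplicon_length: int
    genome_copies: int
    coamplified_paralog: str | None = None

    def __post_init__(self) -> None:
        for p in (self.forward_primer, self.reverse_primer):
            if not p or not _PRIMER_RE.match(p):
                raise LocusTableError(
                    f"locus {self.name!r}: primer {p!r} is empty or contains "
                    "non-IUPAC characters"
                )
        if self.mhc_class not in ("I", "II"):
            raise LocusTableError(f"locus {self.name!r}: class must be I or II")
        if self.amplicon_length <= len(self.forward_primer) + len(self.reverse_primer):
            raise LocusTableError(
                f"locus {self.name!r}: amplicon shorter than its primers"
            )
        if self.genome_copies not in (1, 3):
            raise LocusTableError(
                f"locus {self.name!r}: genome_copies must be 1 or 3"
            )

    @property
    def interior_length(self) -> int:
        """Amplicon length with both primers removed."""
        return self.amplicon_length - len(self.forward_primer) - len(self.reverse_primer)

    @property
    def amplified_genes(self) -> int:
        """Number of diploid genes pooled into this target."""
        return self.genome_copies + (1 if self.coamplified_paralog else 0)

    @property
    def max_alleles_per_individual(self) -> int:
        """Upper bound on distinct alleles one koala can carry at this target."""
        return 2 * self.amplified_genes


@dataclass(frozen=True)
class Allele:
    """A named exon-2 allele sequence (primer-trimmed interior)."""

    locus: str
    label: str
    sequence: str
    provenance: str = "reference"  # "reference" or "novel"

    def __post_init__(self) -> None:
        if not _SEQ_RE.match(self.sequence):
            raise ReferenceError(
                f"allele {self.locus}*{self.label}: sequence contains "
                "non-ACGT characters"
            )
        if len(self.sequence) < MIN_AMPLICON_INTERIOR:
            raise ReferenceError(
                f"allele {self.locus}*{self.label}: sequence shorter than "
                f"{MIN_AMPLICON_INTERIOR} bp"
            )
        if self.provenance not in ("reference", "novel"):
            raise ReferenceError(f"bad provenance {self.provenance!r}")

    @property
    def full_label(self) -> str:
        return f"{self.locus}*{self.label}"


class ReferenceDatabase:
    """Known alleles per locus, indexed by (locus, label) and (locus, sequence).

    Novel alleles discovered during genotyping are registered with
    provisional labels ``novel-001``, ``novel-002``, ... counted per
    locus; the ``novel-`` namespace never collides with published names.
    """

    def __init__(self, loci: Iterable[LocusSpec]):
        self.loci: dict[str, LocusSpec] = {}
        for spec in loci:
            if spec.name in self.loci:
                raise LocusTableError(f"duplicate locus {spec.name!r}")
            self.loci[spec.name] = spec
        self._by_label: dict[tuple[str, str], Allele] = {}
        self._by_seq: dict[tuple[str, str], Allele] = {}
        self._novel_counter: dict[str, int] = {}

    # -- content ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self._by_label)

    def __iter__(self) -> Iterator[Allele]:
        return iter(self._by_label.values())

    def alleles_at(self, locus: str) -> list[Allele]:
        if locus not in self.loci:
            raise ReferenceError(f"unknown locus {locus!r}")
        return [a for (loc, _), a in self._by_label.items() if loc == locus]

    def get(self, locus: str, label: str) -> Allele | None:
        return self._by_label.get((locus, label))

    def find_sequence(self, locus: str, sequence: str) -> Allele | None:
        return self._by_seq.get((locus, sequence))

    def add(self, allele: Allele) -> Allele:
        if allele.locus not in self.loci:
            raise ReferenceError(
                f"allele {allele.full_label}: locus not in configuration"
            )
        key = (allele.locus, allele.label)
        if key in self._by_label:
            raise ReferenceError(f"duplicate allele {allele.full_label}")
        skey = (allele.locus, allele.sequence)
        if skey in self._by_seq:
            raise ReferenceError(
                f"sequence already stored at {allele.locus} as "
                f"{self._by_seq[skey].full_label}"
            )
        self._by_label[key] = allele
        self._by_seq[skey] = allele
        return allele

    def register_novel(self, locus: str, sequence: str) -> Allele:
        """Add a newly discovered sequence under a provisional label."""
        existing = self.find_sequence(locus, sequence)
        if existing is not None:
            raise ReferenceError(
                f"sequence already present at {locus} as {existing.full_label}"
            )
        n = self._novel_counter.get(locus, 0) + 1
        self._novel_counter[locus] = n
        allele = Allele(locus, f"novel-{n:03d}", sequence, provenance="novel")
        return self.add(allele)

    # -- I/O -------------------------------------------------------------

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(a.sequence), id=a.full_label, description="")
            for a in sorted(self, key=lambda a: (a.locus, a.label))
        ]
        SeqIO.write(records, str(path), "fasta")


def load_locus_table(path: str | Path) -> list[LocusSpec]:
    """Parse a tab-separated locus configuration table.

    Expected header: ``locus  class  fwd_primer  rev_primer  amplicon_bp
    genome_copies`` with an optional trailing ``coamplified_paralog``
    column.
    """
    specs: list[LocusSpec] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise LocusTableError(f"{path}: no loci")
        cols = header.rstrip("\n").split("\t")
        required = ["locus", "class", "fwd_primer", "rev_primer",
                    "amplicon_bp", "genome_copies"]
        if cols[: len(required)] != required:
            raise LocusTableError(f"{path}: unexpected header {cols!r}")
        has_paralog = len(cols) > 6 and cols[6] == "coamplified_paralog"
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise LocusTableError(f"{path}:{lineno}: expected ≥6 fields")
            name = fields[0]
            if name in seen:
                raise LocusTableError(f"{path}:{lineno}: duplicate locus {name!r}")
            seen.add(name)
            try:
                amplicon = int(fields[4])
                copies = int(fields[5])
            except ValueError as exc:
                raise LocusTableError(f"{path}:{lineno}: {exc}") from exc
            paralog = None
            if has_paralog and len(fields) > 6 and fields[6].strip():
                paralog = fields[6].strip()
            specs.append(
                LocusSpec(
                    name=name,
                    mhc_class=fields[1],
                    forward_primer=fields[2].upper(),
                    reverse_primer=fields[3].upper(),
                    amplicon_length=amplicon,
                    genome_copies=copies,
                    coamplified_paralog=paralog,
                )
            )
    if not specs:
        raise LocusTableError(f"{path}: no loci")
    return specs


def default_loci() -> list[LocusSpec]:
    """The packaged six-locus configuration (study primers and sizes)."""
    with resources.as_file(
        resources.files("koalamhc.data").joinpath("loci.tsv")
    ) as p:
        return load_locus_table(p)


_HEADER_RE = re.compile(r"^([A-Za-z0-9]+)\*(\S+)$")


def parse_allele_name(name: str) -> tuple[str, str]:
    """Split a ``LOCUS*LABEL`` FASTA identifier into (locus, label)."""
    m = _HEADER_RE.match(name)
    if not m:
        raise ReferenceError(f"cannot parse allele name {name!r} (want LOCUS*LABEL)")
    return m.group(1), m.group(2)


def load_reference(
    fasta: str | Path,
    loci: Iterable[LocusSpec],
) -> tuple[ReferenceDatabase, list[str]]:
    """Load a reference allele FASTA against a locus configuration.

    Headers follow the ``>LOCUS*LABEL [description]`` dialect; anything
    after the first whitespace is ignored.  Records naming a locus that
    is not configured are rejected and reported (second return value)
    rather than raising.
    """
    db = ReferenceDatabase(loci)
    rejected: list[str] = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        locus, label = parse_allele_name(rec.id)
        if locus not in db.loci:
            rejected.append(rec.id)
            continue
        db.add(Allele(locus, label, str(rec.seq).upper()))
    return db, rejected
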