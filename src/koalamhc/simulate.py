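"""Ground-truth simulator: allele pools, pedigrees, and paired-end reads.

Emulates the study design: six gene targets with amplicons of 200-397 bp,
2x250 bp overlapping paired reads, uniform per-base substitution errors,
and diploid inheritance over each target's gene copies.  The pooled
UA+UB target is simulated as two independent single-copy genes whose
reads share the UA locus label, reproducing the observed 1-3 distinct
UA alleles per koala.  Reads always overlap under this geometry, so an
unmerged pair downstream signals a defect rather than an expected state.
"""

from __future__ import annotations

import gzip
import io
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype import KoalaProfile, write_profiles
from .loci import IUPAC, Allele, LocusSpec, ReferenceDatabase, default_loci
from .pedigree import FamilyUnit
from .reads import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the sequenced design: 250 bp mates, 500 reads per
    target per koala, and a modest Illumina-like substitution rate.
    """

    loci: Sequence[LocusSpec] = field(default_factory=default_loci)
    alleles_per_locus: int = 6
    n_founders: int = 4
    n_trios: int = 4
    n_pairs: int = 4
    depth_per_locus: int = 500
    read_length: int = 250
    substitution_error: float = 0.002
    allele_freqs: Mapping[str, Sequence[float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_per_locus < 1:
            raise ValueError("depth must be >= 1")
        if not (0 <= self.substitution_error < 0.1):
            raise ValueError("substitution error must be in [0, 0.1)")
        if self.allele_freqs is not None:
            for locus, freqs in self.allele_freqs.items():
                if abs(sum(freqs) - 1.0) > 1e-9:
                    raise ValueError(f"{locus}: allele frequencies must sum to 1")
        for spec in self.loci:
            if spec.interior_length < 150:
                raise ValueError(f"{spec.name}: amplicon interior shorter than 150 bp")
            min_read = spec.amplicon_length - self.read_length + 10
            if self.read_length < min_read:
                import warnings

                warnings.warn(
                    f"{spec.name}: {self.read_length} bp mates may not overlap "
                    f"on a {spec.amplicon_length} bp amplicon",
                    stacklevel=2,
                )


@dataclass
class TruthSet:
    """Everything the simulator knows: sequences, genotypes, families."""

    pools: dict[str, dict[str, str]]              # locus -> label -> interior seq
    genotypes: dict[str, dict[str, tuple[str, ...]]]  # ind -> locus -> chromosomes
    families: list[FamilyUnit]
    hidden_parents: dict[int, str]                # family_id -> ungenotyped parent

    def expected_calls(self, individual: str) -> dict[str, frozenset[str]]:
        """Distinct-label call sets implied by the diploid assignment."""
        return {
            locus: frozenset(chroms)
            for locus, chroms in self.genotypes[individual].items()
        }

    def visible_individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for fam in self.families:
            for m in fam.members:
                seen.setdefault(m)
        return list(seen)


def _class_label(spec: LocusSpec, i: int) -> str:
    # class I labels carry the two-field form, class II labels are bare numbers
    return f"{i:02d}:01" if spec.mhc_class == "I" else f"{i:02d}"


def simulate_alleles(
    config: SimConfig, rng: np.random.Generator
) -> dict[str, dict[str, str]]:
    """Random allele pools, one per locus, pairwise Hamming distance >= 5.

    Sequences have exactly the amplicon interior length of their locus.
    Deterministic given the generator state.
    """
    pools: dict[str, dict[str, str]] = {}
    for spec in config.loci:
        length = spec.interior_length
        seqs: list[np.ndarray] = []
        attempts = 0
        while len(seqs) < config.alleles_per_locus:
            attempts += 1
            if attempts > 100 * config.alleles_per_locus:
                raise RuntimeError(
                    f"{spec.name}: cannot satisfy pairwise distance constraint"
                )
            cand = _BASES[rng.integers(0, 4, size=length)]
            if all(int(np.count_nonzero(cand != s)) >= 5 for s in seqs):
                seqs.append(cand)
        pools[spec.name] = {
            _class_label(spec, i + 1): s.tobytes().decode("ascii")
            for i, s in enumerate(seqs)
        }
    return pools


def _draw_genotype(
    spec: LocusSpec,
    labels: list[str],
    freqs: np.ndarray,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    # one maternal + one paternal allele per amplified gene
    k = 2 * spec.amplified_genes
    idx = rng.choice(len(labels), size=k, p=freqs)
    return tuple(labels[i] for i in idx)


def _child_genotype(
    spec: LocusSpec,
    dam: tuple[str, ...],
    sire: tuple[str, ...],
    rng: np.random.Generator,
) -> tuple[str, ...]:
    # per gene copy, inherit one uniformly chosen chromosome from each parent
    chroms: list[str] = []
    for g in range(spec.amplified_genes):
        m = dam[2 * g + rng.integers(0, 2)]
        p = sire[2 * g + rng.integers(0, 2)]
        chroms.extend([m, p])
    return tuple(chroms)


def simulate_pedigree(
    config: SimConfig,
    pools: dict[str, dict[str, str]],
    rng: np.random.Generator,
) -> TruthSet:
    """Draw founders, trios and single-parent pairs with Mendelian truth.

    Pair families have two simulated parents but expose only one in the
    pedigree (alternating dam/sire), as in the study's parent-joey pairs.
    """
    if config.n_founders < 2:
        raise ValueError("need at least two founders")
    genotypes: dict[str, dict[str, tuple[str, ...]]] = {}
    freqs = {}
    for spec in config.loci:
        labels = list(pools[spec.name])
        if config.allele_freqs and spec.name in config.allele_freqs:
            f = np.asarray(config.allele_freqs[spec.name], dtype=float)
        else:
            f = np.full(len(labels), 1.0 / len(labels))
        freqs[spec.name] = (labels, f)

    def new_founder(name: str) -> None:
        genotypes[name] = {
            spec.name: _draw_genotype(spec, *freqs[spec.name], rng)
            for spec in config.loci
        }

    def new_child(name: str, dam: str, sire: str) -> None:
        genotypes[name] = {
            spec.name: _child_genotype(
                spec, genotypes[dam][spec.name], genotypes[sire][spec.name], rng
            )
            for spec in config.loci
        }

    for i in range(config.n_founders):
        new_founder(f"founder{i + 1:03d}")

    families: list[FamilyUnit] = []
    hidden: dict[int, str] = {}
    fam_id = 0
    for i in range(config.n_trios):
        fam_id += 1
        dam, sire, joey = (f"trio{fam_id:03d}_{r}" for r in ("dam", "sire", "joey"))
        new_founder(dam)
        new_founder(sire)
        new_child(joey, dam, sire)
        families.append(FamilyUnit(fam_id, joey=joey, dam=dam, sire=sire))
    for i in range(config.n_pairs):
        fam_id += 1
        dam, sire, joey = (f"pair{fam_id:03d}_{r}" for r in ("dam", "sire", "joey"))
        new_founder(dam)
        new_founder(sire)
        new_child(joey, dam, sire)
        if i % 2 == 0:
            families.append(FamilyUnit(fam_id, joey=joey, dam=dam))
            hidden[fam_id] = sire
        else:
            families.append(FamilyUnit(fam_id, joey=joey, sire=sire))
            hidden[fam_id] = dam
    return TruthSet(pools=pools, genotypes=genotypes, families=families,
                    hidden_parents=hidden)


@contextmanager
def _text_sink(path: Path, gz: bool):
    """Open a text sink; gzip output is byte-reproducible (fixed mtime)."""
    if gz:
        with open(path, "wb") as raw, gzip.GzipFile(
            fileobj=raw, mode="wb", mtime=0
        ) as gzf, io.TextIOWrapper(gzf) as writer:
            yield writer
    else:
        with open(path, "w") as writer:
            yield writer


def _realize_primer(primer: str) -> str:
    """Fix degenerate primer positions to one concrete base (first expansion)."""
    return "".join(IUPAC[c][0] for c in primer)


def _inject_errors(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    if hits.size == 0:
        return seq
    out = seq.copy()
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def simulate_reads(
    truth: TruthSet,
    config: SimConfig,
    outdir: str | Path,
    rng: np.random.Generator,
    individuals: Sequence[str] | None = None,
    withhold: Sequence[str] = (),
    gzip_output: bool = True,
) -> dict[str, tuple[Path, Path]]:
    """Write one FASTQ pair per koala plus truth tables and the reference.

    Per locus, ``depth_per_locus`` read pairs are allocated multinomially
    with uniform weights over the individual's chromosomes.  The forward
    read runs from the amplicon 5' end (primer included), the reverse
    read from the 3' end of the reverse complement; both carry fixed Q35
    qualities with substitutions injected at the configured rate.  Loci
    are interleaved into a single FASTQ pair per individual.

    ``withhold`` lists ``LOCUS*LABEL`` alleles excluded from the written
    reference FASTA (their reads are still simulated), for novel-allele
    recovery experiments.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if individuals is None:
        individuals = truth.visible_individuals()
    by_name = {spec.name: spec for spec in config.loci}

    # reference FASTA (optionally with alleles withheld)
    withheld = set(withhold)
    db = ReferenceDatabase(config.loci)
    for locus in sorted(truth.pools):
        for label, seq in truth.pools[locus].items():
            if f"{locus}*{label}" in withheld:
                continue
            db.add(Allele(locus, label, seq))
    ref_path = outdir / "reference.fasta"
    db.write_fasta(ref_path)

    qual_char = chr(35 + 33)  # fixed Q35
    fastqs: dict[str, tuple[Path, Path]] = {}
    for ind in individuals:
        suffix = ".fastq.gz" if gzip_output else ".fastq"
        p1 = outdir / f"{ind}_R1{suffix}"
        p2 = outdir / f"{ind}_R2{suffix}"
        with _text_sink(p1, gzip_output) as f1, _text_sink(p2, gzip_output) as f2:
            for spec in config.loci:
                chroms = truth.genotypes[ind][spec.name]
                alloc = rng.multinomial(
                    config.depth_per_locus,
                    np.full(len(chroms), 1.0 / len(chroms)),
                )
                fp = _realize_primer(spec.forward_primer)
                rp = _realize_primer(spec.reverse_primer)
                serial = 0
                for label, n_reads in zip(chroms, alloc):
                    interior = truth.pools[spec.name][label]
                    amplicon = fp + interior + revcomp(rp)
                    fwd_t = np.frombuffer(
                        amplicon[: config.read_length].encode(), dtype=np.uint8
                    )
                    rev_t = np.frombuffer(
                        revcomp(amplicon)[: config.read_length].encode(),
                        dtype=np.uint8,
                    )
                    for _ in range(n_reads):
                        serial += 1
                        rid = f"{ind}:{spec.name}:{serial}"
                        fwd = _inject_errors(fwd_t, config.substitution_error, rng)
                        rev = _inject_errors(rev_t, config.substitution_error, rng)
                        fs = fwd.tobytes().decode("ascii")
                        rs = rev.tobytes().decode("ascii")
                        f1.write(f"@{rid}/1\n{fs}\n+\n{qual_char * len(fs)}\n")
                        f2.write(f"@{rid}/2\n{rs}\n+\n{qual_char * len(rs)}\n")
        fastqs[ind] = (p1, p2)

    # truth genotype table (same dialect as the genotyping output)
    locus_order = [spec.name for spec in config.loci]
    profiles = [
        KoalaProfile(individual=ind, calls=dict(truth.expected_calls(ind)))
        for ind in individuals
    ]
    write_profiles(profiles, outdir / "truth_genotypes.tsv", locus_order)

    rows = [
        {
            "family_id": fam.family_id,
            "joey": fam.joey,
            "dam": fam.dam or "",
            "sire": fam.sire or "",
        }
        for fam in truth.families
    ]
    pd.DataFrame(rows).to_csv(outdir / "pedigree.tsv", sep="\t", index=False)
    return fastqs


def simulate_dataset(
    config: SimConfig,
    outdir: str | Path,
    withhold: Sequence[str] = (),
    gzip_output: bool = True,
) -> TruthSet:
    """Convenience wrapper: pools, pedigree and reads from one seed."""
    rng = np.random.default_rng(config.seed)
    pools = simulate_alleles(config, rng)
    truth = simulate_pedigree(config, pools, rng)
    simulate_reads(truth, config, outdir, rng, withhold=withhold,
                   gzip_output=gzip_output)
    return truth
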