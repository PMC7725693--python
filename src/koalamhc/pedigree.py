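"""Mendelian validation of genotype profiles within family units.

A joey must inherit an allele from each parent, and every joey allele
must be present in at least one parent.  For trios (both parents
genotyped) the rule is: joey ⊆ dam ∪ sire, joey ∩ dam ≠ ∅ and
joey ∩ sire ≠ ∅.  For single-parent pairs only the shared-allele
condition against the genotyped parent is testable: alleles the joey
does not share with that parent are attributed to the unknown parent
and not flagged.  Incongruent cases carry one discrepancy class, with
precedence NEITHER_PARENT > MISSING_PARENTAL > EXTRA_ALLELE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genotype import NO_DATA, KoalaProfile
from .stats import round_half_up

CONGRUENT = "CONGRUENT"
INCONGRUENT = "INCONGRUENT"
SKIPPED = "SKIPPED"

NONE = "NONE"
MISSING_PARENTAL = "MISSING_PARENTAL"
EXTRA_ALLELE = "EXTRA_ALLELE"
NEITHER_PARENT = "NEITHER_PARENT"

TRIO = "TRIO"
PAIR = "PAIR"


@dataclass(frozen=True)
class FamilyUnit:
    """A joey with one or both genotyped parents."""

    family_id: int
    joey: str
    dam: str | None = None
    sire: str | None = None

    def __post_init__(self) -> None:
        if not self.joey:
            raise ValueError("family unit without a joey")
        if self.dam is None and self.sire is None:
            raise ValueError(f"family {self.family_id}: no genotyped parent")

    @property
    def kind(self) -> str:
        return TRIO if (self.dam and self.sire) else PAIR

    @property
    def members(self) -> list[str]:
        return [m for m in (self.joey, self.dam, self.sire) if m]


@dataclass(frozen=True)
class CongruenceResult:
    family_id: int
    locus: str
    status: str
    discrepancy: str = NONE


def check_family_locus(
    joey_alleles: frozenset[str] | set[str],
    dam_alleles: frozenset[str] | set[str] | None,
    sire_alleles: frozenset[str] | set[str] | None,
) -> tuple[str, str]:
    """Score one family at one locus; returns (status, discrepancy)."""
    if not joey_alleles:
        raise ValueError("joey allele set is empty")
    joey = frozenset(joey_alleles)
    if dam_alleles is not None and sire_alleles is not None:
        dam, sire = frozenset(dam_alleles), frozenset(sire_alleles)
        shares_dam = bool(joey & dam)
        shares_sire = bool(joey & sire)
        if shares_dam and shares_sire and joey <= (dam | sire):
            return CONGRUENT, NONE
        if not shares_dam and not shares_sire:
            return INCONGRUENT, NEITHER_PARENT
        if not shares_dam or not shares_sire:
            return INCONGRUENT, MISSING_PARENTAL
        return INCONGRUENT, EXTRA_ALLELE
    parent = dam_alleles if dam_alleles is not None else sire_alleles
    if parent is None:
        raise ValueError("no parent allele set given")
    if joey & frozenset(parent):
        return CONGRUENT, NONE
    return INCONGRUENT, MISSING_PARENTAL


@dataclass
class CongruenceReport:
    """Per-locus and overall congruence over a set of family units."""

    results: list[CongruenceResult]
    locus_order: list[str]

    @property
    def scored(self) -> list[CongruenceResult]:
        return [r for r in self.results if r.status != SKIPPED]

    def per_locus(self) -> dict[str, tuple[int, int]]:
        """locus -> (congruent, scored total)."""
        out: dict[str, tuple[int, int]] = {}
        for locus in self.locus_order:
            scored = [r for r in self.scored if r.locus == locus]
            ok = sum(r.status == CONGRUENT for r in scored)
            out[locus] = (ok, len(scored))
        return out

    def per_locus_pct(self) -> dict[str, int]:
        """Percent congruent per locus, rounded to the nearest integer."""
        return {
            locus: round_half_up(100 * ok / total) if total else 100
            for locus, (ok, total) in self.per_locus().items()
        }

    @property
    def overall(self) -> tuple[int, int]:
        ok = sum(r.status == CONGRUENT for r in self.scored)
        return ok, len(self.scored)

    @property
    def overall_pct(self) -> int:
        ok, total = self.overall
        return round_half_up(100 * ok / total) if total else 100

    def discrepancy_tally(self) -> dict[str, int]:
        tally = {MISSING_PARENTAL: 0, EXTRA_ALLELE: 0, NEITHER_PARENT: 0}
        for r in self.results:
            if r.status == INCONGRUENT:
                tally[r.discrepancy] += 1
        return tally

    def incongruent(self) -> list[CongruenceResult]:
        return [r for r in self.results if r.status == INCONGRUENT]


def congruence_summary(
    families: Iterable[FamilyUnit],
    profiles: Iterable[KoalaProfile] | Mapping[str, KoalaProfile],
    locus_order: Sequence[str] | None = None,
) -> CongruenceReport:
    """Check every family at every locus and summarize.

    A (family, locus) comparison is SKIPPED when any member has NO_DATA
    there; skipped comparisons do not enter totals.  Raises for a family
    member without a profile.
    """
    if isinstance(profiles, Mapping):
        by_name = dict(profiles)
    else:
        by_name = {p.individual: p for p in profiles}
    families = list(families)
    for fam in families:
        for member in fam.members:
            if member not in by_name:
                raise KeyError(f"no profile for individual {member!r}")
    if locus_order is None:
        seen: dict[str, None] = {}
        for p in by_name.values():
            for locus in p.calls:
                seen.setdefault(locus)
        locus_order = list(seen)

    results: list[CongruenceResult] = []
    for fam in families:
        joey_calls = by_name[fam.joey].calls
        dam_calls = by_name[fam.dam].calls if fam.dam else None
        sire_calls = by_name[fam.sire].calls if fam.sire else None
        for locus in locus_order:
            joey = joey_calls.get(locus, NO_DATA)
            dam = dam_calls.get(locus, NO_DATA) if dam_calls is not None else None
            sire = sire_calls.get(locus, NO_DATA) if sire_calls is not None else None
            missing = joey is NO_DATA
            if fam.dam and dam is NO_DATA:
                missing = True
            if fam.sire and sire is NO_DATA:
                missing = True
            if missing:
                results.append(CongruenceResult(fam.family_id, locus, SKIPPED))
                continue
            status, disc = check_family_locus(joey, dam, sire)
            results.append(CongruenceResult(fam.family_id, locus, status, disc))
    return CongruenceReport(results=results, locus_order=list(locus_order))


# ---------------------------------------------------------------------------
# TSV I/O


def read_pedigree(path: str | Path) -> list[FamilyUnit]:
    """Read a ``family_id, joey, dam, sire`` table (empty cell = unknown)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    families = []
    for _, row in df.iterrows():
        families.append(
            FamilyUnit(
                family_id=int(row["family_id"]),
                joey=row["joey"],
                dam=row["dam"] or None,
                sire=row["sire"] or None,
            )
        )
    return families


def write_report(report: CongruenceReport, path: str | Path) -> None:
    """Result rows plus a summary block, as one TSV."""
    rows = [
        {
            "family_id": r.family_id,
            "locus": r.locus,
            "status": r.status,
            "discrepancy": r.discrepancy,
        }
        for r in report.results
    ]
    with open(path, "w") as fh:
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
        fh.write("\n# summary\n")
        for locus, (ok, total) in report.per_locus().items():
            fh.write(
                f"# {locus}\t{ok}/{total}\t{report.per_locus_pct()[locus]}%\n"
            )
        ok, total = report.overall
        fh.write(f"# overall\t{ok}/{total}\t{report.overall_pct}%\n")
        for cls, n in report.discrepancy_tally().items():
            fh.write(f"# {cls}\t{n}\n")
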