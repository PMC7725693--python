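"""Loaders for the packaged study tables.

The packaged data re-types the published captive-population genotype
tables: the six-locus configuration, per-individual called allele sets
for 36 family units (18 trios + 18 single-parent pairs), the pedigree,
and the list of family×locus cells the publication flagged as
Mendelian-incongruent.  Individuals appearing in several families
(e.g. Byron, Mooloolah) are deduplicated by name after an exact
consistency check.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .genotype import KoalaProfile
from .loci import LocusSpec, default_loci
from .pedigree import FamilyUnit

LOCUS_ORDER = ["UA", "UC", "DAB", "DBB", "DCB", "DMB"]

# Curation guard: the fixture tables were transcribed once and are frozen.
FIXTURE_SHA256 = {
    "family_profiles.tsv":
        "7c883ffec459c76c4695f597c2348e31cdc0271c73e319274b0339e5f1f5dda7",
    "pedigree.tsv":
        "7f5f26d0abddda7480d537beb5642a76f67be5fd0adfaf3c0c284caf0cbfb062",
    "expected_discrepancies.tsv":
        "1ee27820952ced039e5a43e67325ba90b80760a847fdadddd85c76c07b84383b",
}


class FixtureError(ValueError):
    """Raised when packaged data fails its own consistency check."""


def _data_path(name: str):
    return resources.files("koalamhc.data").joinpath(name)


def fixture_checksum(name: str) -> str:
    return hashlib.sha256(_data_path(name).read_bytes()).hexdigest()


@dataclass
class FixtureTables:
    loci: list[LocusSpec]
    family_rows: pd.DataFrame          # one row per (family, relationship)
    profiles: dict[str, KoalaProfile]  # deduplicated by individual name
    families: list[FamilyUnit]
    expected_discrepancies: list[tuple[int, str, str]]  # (family, locus, class)


def load_fixture_tables() -> FixtureTables:
    """Load and cross-validate all packaged study tables."""
    loci = default_loci()
    with resources.as_file(_data_path("family_profiles.tsv")) as p:
        rows = pd.read_csv(p, sep="\t", dtype=str)
    profiles: dict[str, KoalaProfile] = {}
    for _, row in rows.iterrows():
        calls = {
            locus: frozenset(row[locus].split(";")) for locus in LOCUS_ORDER
        }
        name = row["name"]
        if name in profiles:
            if profiles[name].calls != calls:
                raise FixtureError(
                    f"individual {name!r} has inconsistent profiles across families"
                )
        else:
            profiles[name] = KoalaProfile(individual=name, calls=calls)

    with resources.as_file(_data_path("pedigree.tsv")) as p:
        ped = pd.read_csv(p, sep="\t", dtype=str).fillna("")
    families = [
        FamilyUnit(
            family_id=int(r["family_id"]),
            joey=r["joey"],
            dam=r["dam"] or None,
            sire=r["sire"] or None,
        )
        for _, r in ped.iterrows()
    ]

    # pedigree must agree with the per-family profile rows
    by_family = {
        (int(r["family_id"]), r["relationship"]): r["name"]
        for _, r in rows.iterrows()
    }
    for fam in families:
        if by_family.get((fam.family_id, "joey")) != fam.joey:
            raise FixtureError(f"family {fam.family_id}: joey mismatch")
        for rel, member in (("dam", fam.dam), ("sire", fam.sire)):
            if by_family.get((fam.family_id, rel)) != member:
                raise FixtureError(f"family {fam.family_id}: {rel} mismatch")
        for member in fam.members:
            if member not in profiles:
                raise FixtureError(f"family {fam.family_id}: no profile for {member!r}")

    with resources.as_file(_data_path("expected_discrepancies.tsv")) as p:
        disc = pd.read_csv(p, sep="\t", dtype=str)
    expected = [
        (int(r["family_id"]), r["locus"], r["discrepancy"])
        for _, r in disc.iterrows()
    ]
    return FixtureTables(
        loci=loci,
        family_rows=rows,
        profiles=profiles,
        families=families,
        expected_discrepancies=expected,
    )
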