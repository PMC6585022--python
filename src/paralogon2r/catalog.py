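"""Gene-family catalog for the Hsa 1/2/8/20 paralogon.

Models the curated catalog of human multigene families with three- or
four-fold representation on human chromosomes 1, 2, 8 and 20, and
classifies each family by the number of distinct target chromosomes its
members occupy (its *fold*).  Members located off the target chromosomes
(translocated copies such as STK26 on X) stay in the family for
phylogenetics but do not contribute to fold.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Optional

import pandas as pd

#: The tetra-paralogon under study.
DEFAULT_TARGET = frozenset({"1", "2", "8", "20"})

_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}
_BAND_RE = re.compile(r"^(2[0-2]|1[0-9]|[1-9]|X|Y)((?:[pq]|cen|ter).*)?$", re.IGNORECASE)


class CatalogError(ValueError):
    pass


def parse_cytoband(band: str) -> str:
    """Chromosome token of a cytogenetic band (``"20q13.33"`` -> ``"20"``).

    The chromosome is the maximal leading token before the first arm
    letter; arm/band suffixes (including ranges like ``1p36.13-p36.12``)
    are discarded.  Bare chromosome names are accepted.
    """
    m = _BAND_RE.match(band.strip())
    if not m:
        raise CatalogError(f"malformed cytogenetic band: {band!r}")
    chrom = m.group(1).upper()
    if chrom not in _CHROMS:
        raise CatalogError(f"malformed cytogenetic band: {band!r}")
    return chrom


@dataclass(frozen=True)
class GeneMember:
    gene_symbol: str
    cytoband: str
    accession: str = ""

    @property
    def chromosome(self) -> str:
        return parse_cytoband(self.cytoband)


@dataclass
class GeneFamilyRecord:
    family_name: str
    members: list
    source_study: str = "present"

    def __post_init__(self):
        if len(self.members) < 2:
            raise CatalogError(f"{self.family_name}: a family needs at least 2 members")
        symbols = [m.gene_symbol for m in self.members]
        if len(set(symbols)) != len(symbols):
            raise CatalogError(f"{self.family_name}: duplicate member gene symbols")
        if self.source_study not in ("present", "previous"):
            raise CatalogError(f"{self.family_name}: bad source_study {self.source_study!r}")

    @property
    def chromosomes(self) -> list:
        return [m.chromosome for m in self.members]


@dataclass(frozen=True)
class FoldClassification:
    family_name: str
    fold: int
    label: str

    @staticmethod
    def label_for(fold: int, target_size: int = 4) -> str:
        if fold == target_size:
            return "quadruplicated"
        if fold == target_size - 1:
            return "triplicated"
        return "below-threshold"


def fold_classification(
    family: GeneFamilyRecord, target: Iterable[str] = DEFAULT_TARGET
) -> FoldClassification:
    """Classify a family by its distinct-chromosome count on ``target``."""
    target = frozenset(target)
    if not target:
        raise CatalogError("target chromosome set is empty")
    fold = len(set(family.chromosomes) & target)
    return FoldClassification(family.family_name, fold, FoldClassification.label_for(fold, len(target)))


def catalog_summary(
    catalog: Iterable[GeneFamilyRecord], target: Iterable[str] = DEFAULT_TARGET
) -> dict:
    """Counts of families by fold label and source, plus member tallies.

    Both the total member count and the count of members sitting on the
    target chromosomes are reported, since translocated members belong to
    the family but not to the paralogon.
    """
    target = frozenset(target)
    out = {
        "n_families": 0,
        "n_members": 0,
        "n_members_on_target": 0,
        "quadruplicated": 0,
        "triplicated": 0,
        "below-threshold": 0,
        "present": 0,
        "previous": 0,
    }
    for fam in catalog:
        out["n_families"] += 1
        out["n_members"] += len(fam.members)
        out["n_members_on_target"] += sum(1 for c in fam.chromosomes if c in target)
        out[fold_classification(fam, target).label] += 1
        out[fam.source_study] += 1
    return out


def fold_table(catalog: Iterable[GeneFamilyRecord], target=DEFAULT_TARGET) -> pd.DataFrame:
    rows = []
    for fam in sorted(catalog, key=lambda f: f.family_name):
        fc = fold_classification(fam, target)
        rows.append(
            {
                "family": fam.family_name,
                "n_members": len(fam.members),
                "chromosomes": ",".join(sorted(set(fam.chromosomes), key=_chrom_key)),
                "fold": fc.fold,
                "label": fc.label,
                "source_study": fam.source_study,
            }
        )
    return pd.DataFrame(rows)


def _chrom_key(c: str):
    return (0, int(c)) if c.isdigit() else (1, c)


def read_members_tsv(source, source_study: str = "present") -> list:
    """Read a member-level catalog TSV (family, gene, cytoband, accession)."""
    df = pd.read_csv(StringIO(source) if "\t" in str(source) else source, sep="\t")
    families = []
    for name, grp in df.groupby("family", sort=True):
        members = [
            GeneMember(r.gene, r.cytoband, getattr(r, "accession", "") or "")
            for r in grp.itertuples(index=False)
        ]
        families.append(GeneFamilyRecord(name, members, source_study))
    return families


def load_catalog() -> list:
    """The packaged present-study catalog (25 families, 125 genes)."""
    pkg = importlib.resources.files("paralogon2r.data")
    return read_members_tsv((pkg / "catalog_members.tsv").read_text())


def load_catalog_family_info() -> pd.DataFrame:
    """Per-family metadata: full name and included taxon/sequence counts."""
    pkg = importlib.resources.files("paralogon2r.data")
    return pd.read_csv(StringIO((pkg / "catalog_families.tsv").read_text()), sep="\t")


def load_previous_families() -> list:
    """Previous-study families named in the published co-duplication grouping.

    Only four of the eleven previously analyzed families are named in the
    present source; their member tables live in the earlier companion
    study, so members here are chromosome placeholders.
    """
    pkg = importlib.resources.files("paralogon2r.data")
    df = pd.read_csv(StringIO((pkg / "previous_families.tsv").read_text()), sep="\t")
    families = []
    for row in df.itertuples(index=False):
        chroms = [c.strip() for c in row.chromosomes.split(",")]
        members = [GeneMember(f"{row.family}@chr{c}", c) for c in chroms]
        families.append(GeneFamilyRecord(row.family, members, "previous"))
    return families
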