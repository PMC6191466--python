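"""Clone detection, synonym/homonym classification, ploidy calls, dedup.

Two accessions are treated as the same genotype (clones) when their allele
sets are identical at every locus that is non-missing in both, provided
enough loci could be compared; groups are the transitive closure of that
relation.  Within a clone group, identical names mean redundant duplicates,
two known names on one genotype is a synonymy, and an unknown accession
matching a known one is thereby identified.  Across groups, one name on two
distinct genotypes is a homonymy.

An accession is called polyploid when it shows a third distinct allele at a
minimum number of loci (default 3) — single-locus third alleles are treated
as artifacts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .genotype_io import GenotypeTable

__all__ = [
    "CloneReport",
    "PloidyCall",
    "HomonymReport",
    "find_identical_profiles",
    "classify_relations",
    "classify_ploidy",
    "deduplicate",
    "normalize_name",
]

UNKNOWN_NAMES = {"unknown", ""}


@dataclass
class CloneReport:
    groups: list[list[str]]                 # only groups of size >= 2
    representatives: list[str]
    pair_labels: dict[tuple[str, str], str] = field(default_factory=dict)
    potential_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    match_support: dict[tuple[str, str], int] = field(default_factory=dict)
    removed_ids: list[str] = field(default_factory=list)


@dataclass
class PloidyCall:
    accession_id: str
    n_loci_with_third_allele: int
    classification: str  # "D" or "P"


@dataclass
class HomonymReport:
    name: str
    accession_ids: list[str]
    n_distinct_profiles: int


def normalize_name(name: str) -> str:
    """Case-fold and strip numeric-id prefixes and collection codes."""
    n = name.strip().casefold()
    n = re.sub(r"^c\d{2}[_\s]+", "", n)    # collection code prefix
    n = re.sub(r"^\d+[_\s]+", "", n)       # numeric accession prefix
    n = re.sub(r"\s+", " ", n)
    return n


def _pair_match(table: GenotypeTable, a: str, b: str) -> tuple[bool, int]:
    """(identical at all mutually typed loci, number of such loci)."""
    compared = 0
    for locus in table.loci:
        ca = table.calls[(a, locus)]
        cb = table.calls[(b, locus)]
        if ca.is_missing or cb.is_missing:
            continue
        compared += 1
        if ca.sizes != cb.sizes:
            return False, compared
    return True, compared


def find_identical_profiles(table: GenotypeTable,
                            min_compared_loci: int = 15) -> CloneReport:
    """Group accessions with identical multilocus profiles.

    Pairs identical at every mutually non-missing locus join a group when
    at least ``min_compared_loci`` loci could be compared; identical pairs
    with fewer compared loci are listed as potential matches only.
    Grouping is by transitive closure; representatives prefer accessions
    with a known status (LV/CV) and break ties by accession id.
    """
    ids = table.accession_ids
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pair_support: dict[tuple[str, str], int] = {}
    potential: list[tuple[str, str, int]] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            same, compared = _pair_match(table, a, b)
            if not same:
                continue
            if compared >= min_compared_loci:
                pair_support[(a, b)] = compared
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
            elif compared > 0:
                potential.append((a, b, compared))

    by_root: dict[str, list[str]] = {}
    for i in ids:
        by_root.setdefault(find(i), []).append(i)
    groups = sorted(
        [sorted(g) for g in by_root.values() if len(g) > 1]
    )
    reps = []
    for g in groups:
        known = [i for i in g if table.record(i).status in ("LV", "CV")]
        reps.append(min(known) if known else min(g))
    return CloneReport(
        groups=groups,
        representatives=reps,
        match_support=pair_support,
        potential_pairs=potential,
    )


def classify_relations(
    report: CloneReport, table: GenotypeTable
) -> tuple[CloneReport, list[HomonymReport]]:
    """Label clone pairs as duplicate/synonym/unknown-identified; find homonyms.

    Within a group: same normalized name -> duplicate; two different known
    names -> synonym; a UA member matching a known member -> the unknown is
    identified (it inherits the known name).  Across groups, a shared
    normalized name on distinct profiles is a homonym.
    """
    labels: dict[tuple[str, str], str] = {}
    for g in report.groups:
        for i, a in enumerate(g):
            for b in g[i + 1:]:
                ra, rb = table.record(a), table.record(b)
                na, nb = normalize_name(ra.name), normalize_name(rb.name)
                a_unknown = ra.status == "UA" or na in UNKNOWN_NAMES
                b_unknown = rb.status == "UA" or nb in UNKNOWN_NAMES
                if a_unknown != b_unknown:
                    labels[(a, b)] = "unknown-identified"
                elif na == nb:
                    labels[(a, b)] = "duplicate"
                elif a_unknown and b_unknown:
                    labels[(a, b)] = "duplicate"  # both unnamed, same profile
                else:
                    labels[(a, b)] = "synonym"
    report.pair_labels = labels

    # homonyms: same name across different profile groups
    group_of = {}
    for gi, g in enumerate(report.groups):
        for a in g:
            group_of[a] = gi
    next_gi = len(report.groups)
    by_name: dict[str, list[str]] = {}
    for acc in table.accession_ids:
        n = normalize_name(table.record(acc).name)
        if n in UNKNOWN_NAMES:
            continue
        if acc not in group_of:
            group_of[acc] = next_gi
            next_gi += 1
        by_name.setdefault(n, []).append(acc)
    homonyms = []
    for name, accs in sorted(by_name.items()):
        profiles = {group_of[a] for a in accs}
        if len(profiles) >= 2:
            homonyms.append(
                HomonymReport(name, sorted(accs), len(profiles))
            )
    return report, homonyms


def classify_ploidy(table: GenotypeTable,
                    min_loci: int = 3) -> list[PloidyCall]:
    """Polyploid call: a third distinct allele at >= ``min_loci`` loci."""
    out = []
    for acc in table.accession_ids:
        n3 = sum(
            1 for locus in table.loci
            if len(table.calls[(acc, locus)].sizes) >= 3
        )
        out.append(
            PloidyCall(acc, n3, "P" if n3 >= min_loci else "D")
        )
    return out


def deduplicate(
    table: GenotypeTable, report: CloneReport
) -> tuple[GenotypeTable, list[str]]:
    """Keep one representative per clone group; return (table, removed ids)."""
    removed: list[str] = []
    for g, rep in zip(report.groups, report.representatives):
        removed.extend(i for i in g if i != rep)
    keep = [i for i in table.accession_ids if i not in set(removed)]
    report.removed_ids = sorted(removed)
    return table.subset(keep), sorted(removed)
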