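"""Per-group variable-site extraction and site-level statistics.

A variable site is an alignment column (mapped to a reference coordinate)
where a group's samples carry at least two distinct nucleotides among
``{A, C, G, T}``. ``'N'`` (ambiguity) and ``'-'`` (gap) are missing data:
they are excluded from allele counts, and a column whose ambiguity leaves
fewer than two observed nucleotides is dropped.

Minor-allele frequency (MAF) is computed within the group: minor count over
counted (non-missing) alleles. Substitutions are classed as transitions
(purine<->purine or pyrimidine<->pyrimidine) or transversions; a
multi-allelic site contributes one class per (major, minor) pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import NUCLEOTIDES, AlignedCohort, INSERTION
from .annotation import GenomeAnnotation
from .errors import GroupError

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def classify_substitution(allele_a: str, allele_b: str) -> str:
    """``"transition"`` if both alleles are purines or both pyrimidines, else ``"transversion"``."""
    if allele_a == allele_b:
        raise ValueError(f"substitution needs two distinct alleles, got {allele_a!r} twice")
    for a in (allele_a, allele_b):
        if a not in NUCLEOTIDES:
            raise ValueError(f"not a nucleotide: {a!r}")
    same_class = ({allele_a, allele_b} <= PURINES) or ({allele_a, allele_b} <= PYRIMIDINES)
    return "transition" if same_class else "transversion"


@dataclass
class VariableSite:
    """One polymorphic reference position within one altitude group."""

    position: int
    allele_counts: dict[str, int]
    major_allele: str
    minor_alleles: list[str]  # descending count, ties lexicographic
    maf: float  # top minor count / counted alleles
    regions: list[str] = field(default_factory=list)

    @property
    def n_alleles(self) -> int:
        return len(self.allele_counts)

    @property
    def substitution_classes(self) -> dict[tuple[str, str], str]:
        return {
            (self.major_allele, m): classify_substitution(self.major_allele, m)
            for m in self.minor_alleles
        }

    @property
    def n_counted(self) -> int:
        return sum(self.allele_counts.values())


def _call_alleles(
    counts: dict[str, int], reference_allele: str | None
) -> tuple[str, list[str]]:
    """Major/minor calls with ties broken toward the reference, else lexicographic."""
    top = max(counts.values())
    tied = sorted(a for a, c in counts.items() if c == top)
    if reference_allele in tied:
        major = reference_allele
    else:
        major = tied[0]
    minors = sorted(
        (a for a in counts if a != major), key=lambda a: (-counts[a], a)
    )
    return major, minors


def extract_variable_sites(
    cohort: AlignedCohort,
    group: int,
    annotation: GenomeAnnotation | None = None,
) -> list[VariableSite]:
    """Variable sites of one altitude group, ordered by reference position.

    Insertion columns (no reference coordinate) are skipped; missing data
    ('N'/'-') is excluded from counts; columns with fewer than two observed
    nucleotide alleles are not variable sites.
    """
    sub = cohort.group_matrix(group)  # raises GroupError when empty
    sites: list[VariableSite] = []
    for col in range(cohort.n_columns):
        position = int(cohort.column_to_ref[col])
        if position == INSERTION:
            continue
        column = sub[:, col]
        counts = {
            nt: int(n)
            for nt, n in zip(*np.unique(column, return_counts=True))
            if nt in NUCLEOTIDES
        }
        if len(counts) < 2:
            continue
        major, minors = _call_alleles(counts, cohort.ref_allele(position))
        counted = sum(counts.values())
        site = VariableSite(
            position=position,
            allele_counts=counts,
            major_allele=major,
            minor_alleles=minors,
            maf=counts[minors[0]] / counted,
            regions=annotation.features_at(position) if annotation else [],
        )
        sites.append(site)
    sites.sort(key=lambda s: s.position)
    return sites


def annotate_region(position: int, annotation: GenomeAnnotation) -> list[str]:
    """Every feature covering *position* (overlaps double-listed), else ``["intergenic"]``."""
    return annotation.features_at(position)


@dataclass
class SiteStats:
    """Group-level summary over a set of variable sites.

    Coding/non-coding tallies double-count sites in overlapping features,
    so ``n_coding + n_noncoding >= n_variable_sites``. ``ts_tv_ratio`` is
    ``inf`` when no transversion was observed.
    """

    n_variable_sites: int
    n_coding: int
    n_noncoding: int
    n_transitions: int
    n_transversions: int
    n_triallelic: int
    n_quadallelic: int

    @property
    def ts_tv_ratio(self) -> float:
        if self.n_transversions == 0:
            return math.inf
        return self.n_transitions / self.n_transversions


def site_statistics(
    sites: list[VariableSite], annotation: GenomeAnnotation | None = None
) -> SiteStats:
    """Tabulate the per-group site summary (counts, Ts:Tv, multi-allelic sites).

    "Coding" means located in a protein-coding gene; control region, tRNA,
    rRNA and intergenic positions count as non-coding. A site overlapping
    both a coding and a non-coding feature contributes to both tallies.
    """
    if not sites:
        raise GroupError("site_statistics needs a non-empty site list")
    n_ts = n_tv = n_coding = n_noncoding = n_tri = n_quad = 0
    for site in sites:
        for cls in site.substitution_classes.values():
            if cls == "transition":
                n_ts += 1
            else:
                n_tv += 1
        if site.n_alleles == 3:
            n_tri += 1
        elif site.n_alleles == 4:
            n_quad += 1
        regions = site.regions
        if annotation is not None:
            coding = any(annotation.is_coding(r) for r in regions)
            noncoding = any(not annotation.is_coding(r) for r in regions)
            n_coding += coding
            n_noncoding += noncoding
    return SiteStats(
        n_variable_sites=len(sites),
        n_coding=n_coding,
        n_noncoding=n_noncoding,
        n_transitions=n_ts,
        n_transversions=n_tv,
        n_triallelic=n_tri,
        n_quadallelic=n_quad,
    )


def sites_to_frame(sites: list[VariableSite], group: int) -> pd.DataFrame:
    """Flat TSV-ready table of one group's variable sites."""
    rows = []
    for s in sites:
        rows.append(
            {
                "position": s.position,
                "group": group,
                "major": s.major_allele,
                "minors": ",".join(s.minor_alleles),
                "counts": ",".join(f"{a}:{c}" for a, c in sorted(s.allele_counts.items())),
                "maf": s.maf,
                "classes": ",".join(s.substitution_classes.values()),
                "regions": ",".join(s.regions),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "position", "group", "major", "minors", "counts", "maf", "classes", "regions",
        ],
    )
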