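"""Aligned-cohort input: FASTA + metadata reading, reference mapping, grouping.

Sequences are assumed to be pre-aligned (e.g. with Clustal Omega or MAFFT)
and linearized at reference position 1; this module never aligns. Alignment
columns are mapped to 1-based reference (rCRS) coordinates via the cumulative
non-gap count of a designated reference record; columns where the reference
holds a gap are insertions relative to the reference and are excluded from
variable-site extraction.

Ambiguous IUPAC nucleotides (anything outside ``{A, C, G, T, -}``) are
normalized to ``'N'`` on input and treated as missing data everywhere
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, ConfigurationError, GroupError, MetadataError

VALID_CHARS = frozenset("ACGT-N")
NUCLEOTIDES = ("A", "C", "G", "T")

#: sentinel in ``column_to_ref`` for insertion columns (reference gap)
INSERTION = -1


@dataclass(frozen=True)
class GroupScheme:
    """Half-open altitude bins [low, high) in metres.

    ``boundaries`` are the interior cut points; ``len(boundaries) + 1``
    groups result, numbered from 1. The default follows the eight-group
    500 m stratification from sea level to the Tibetan plateau, with the
    top group collecting everything at or above 4000 m. An altitude equal
    to a cut point falls in the upper bin (half-open convention).
    """

    boundaries: tuple[float, ...] = (500, 1000, 1500, 2000, 2500, 3000, 4000)
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ConfigurationError("altitude boundaries must be strictly increasing")
        if not self.labels:
            object.__setattr__(
                self,
                "labels",
                tuple(f"group{i}" for i in range(1, len(self.boundaries) + 2)),
            )
        if len(self.labels) != len(self.boundaries) + 1:
            raise ConfigurationError(
                f"{len(self.boundaries) + 1} groups need "
                f"{len(self.boundaries) + 1} labels, got {len(self.labels)}"
            )

    @property
    def n_groups(self) -> int:
        return len(self.boundaries) + 1

    def group_of(self, altitude_m: float) -> int:
        """1-based group index for an altitude; altitudes on a cut point go up."""
        if not np.isfinite(altitude_m) or altitude_m < 0:
            raise MetadataError(f"invalid altitude {altitude_m!r}: must be >= 0 m")
        return int(np.searchsorted(self.boundaries, altitude_m, side="right")) + 1


@dataclass
class AlignedCohort:
    """An aligned sample matrix with group labels and a reference coordinate map.

    ``matrix`` is ``(n_samples, n_columns)`` of single characters over
    ``{A, C, G, T, N, -}``; ``column_to_ref[k]`` is the 1-based reference
    position of alignment column ``k`` or :data:`INSERTION`.
    """

    sample_ids: list[str]
    groups: np.ndarray  # (n_samples,) int, 1-based group index
    matrix: np.ndarray  # (n_samples, n_columns) dtype '<U1'
    column_to_ref: np.ndarray  # (n_columns,) int
    reference: np.ndarray | None = None  # reference row (same width), if known
    reference_id: str | None = None
    scheme: GroupScheme = field(default_factory=GroupScheme)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.sample_ids), len(self.column_to_ref)):
            raise AlignmentError("matrix shape inconsistent with ids / coordinate map")
        if len(self.groups) != len(self.sample_ids):
            raise MetadataError("every sample needs a group assignment")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def group_labels(self) -> list[int]:
        return sorted(set(int(g) for g in self.groups))

    def group_mask(self, group: int) -> np.ndarray:
        return self.groups == group

    def group_sample_ids(self, group: int) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.groups) if g == group]

    def group_matrix(self, group: int) -> np.ndarray:
        mask = self.group_mask(group)
        if not mask.any():
            raise GroupError(f"group {group} has no samples")
        return self.matrix[mask]

    def ref_allele(self, position: int) -> str | None:
        """Reference nucleotide at a 1-based reference position, if a reference row exists."""
        if self.reference is None:
            return None
        cols = np.nonzero(self.column_to_ref == position)[0]
        if len(cols) == 0:
            return None
        base = str(self.reference[cols[0]])
        return base if base in NUCLEOTIDES else None


def normalize_sequence(seq: str) -> np.ndarray:
    """Uppercase and map every non-``ACGT-`` character to ``'N'``."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1").astype("<U1")
    good = np.isin(arr, list(VALID_CHARS))
    arr[~good] = "N"
    return arr


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the ``sample_id<TAB>altitude_m`` table."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "altitude_m"}.issubset(meta.columns):
        raise MetadataError(
            f"metadata {path}: needs columns sample_id, altitude_m, "
            f"got {list(meta.columns)}"
        )
    return meta


def assign_altitude_groups(
    metadata: pd.DataFrame, scheme: GroupScheme | None = None
) -> dict[str, int]:
    """Map each sample id to its 1-based altitude group under *scheme*."""
    scheme = scheme or GroupScheme()
    out: dict[str, int] = {}
    for row in metadata.itertuples():
        altitude = float(row.altitude_m)
        out[str(row.sample_id)] = scheme.group_of(altitude)
    return out


def read_alignment(
    fasta_path: str | Path,
    metadata_path: str | Path,
    scheme: GroupScheme | None = None,
    reference_id: str | None = None,
) -> AlignedCohort:
    """Load an aligned multi-FASTA plus metadata into an :class:`AlignedCohort`.

    A record whose id equals *reference_id* is kept as the reference row
    (used for coordinate mapping and major-allele tie-breaks) and excluded
    from the sample matrix and all group statistics; it needs no metadata
    entry. Every other record must appear in the metadata table.
    """
    scheme = scheme or GroupScheme()
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"{fasta_path}: no FASTA records")
    width = len(records[0].seq)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    reference_row: np.ndarray | None = None
    for rec in records:
        if len(rec.seq) != width:
            raise AlignmentError(
                f"{fasta_path}: record {rec.id} has length {len(rec.seq)}, "
                f"expected {width} (inputs must be aligned)"
            )
        row = normalize_sequence(str(rec.seq))
        if reference_id is not None and rec.id == reference_id:
            reference_row = row
            continue
        ids.append(rec.id)
        rows.append(row)
    if reference_id is not None and reference_row is None:
        raise ConfigurationError(
            f"reference record {reference_id!r} not found in {fasta_path}"
        )

    metadata = read_metadata(metadata_path)
    group_of = assign_altitude_groups(metadata, scheme)
    groups = np.empty(len(ids), dtype=int)
    for k, sample in enumerate(ids):
        if sample not in group_of:
            raise MetadataError(f"sample {sample!r} missing from {metadata_path}")
        groups[k] = group_of[sample]

    cohort = AlignedCohort(
        sample_ids=ids,
        groups=groups,
        matrix=np.vstack(rows),
        column_to_ref=np.arange(1, width + 1),
        reference=reference_row,
        reference_id=reference_id,
        scheme=scheme,
    )
    if reference_row is not None:
        cohort = map_to_reference(cohort)
    return cohort


def map_to_reference(
    cohort: AlignedCohort, reference: np.ndarray | None = None
) -> AlignedCohort:
    """Fill ``column_to_ref`` from the reference row's cumulative non-gap count.

    Columns where the reference holds ``'-'`` are insertions relative to the
    reference and receive :data:`INSERTION`; the k-th non-gap reference
    column maps to reference position k (1-based).
    """
    ref = cohort.reference if reference is None else reference
    if ref is None:
        raise ConfigurationError("no reference row available for coordinate mapping")
    if len(ref) != cohort.n_columns:
        raise AlignmentError("reference length does not match alignment width")
    non_gap = ref != "-"
    coords = np.cumsum(non_gap)
    column_to_ref = np.where(non_gap, coords, INSERTION).astype(int)
    cohort.column_to_ref = column_to_ref
    cohort.reference = ref
    return cohort


def group_sizes(cohort: AlignedCohort) -> Mapping[int, int]:
    labels, counts = np.unique(cohort.groups, return_counts=True)
    return {int(g): int(c) for g, c in zip(labels, counts)}
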