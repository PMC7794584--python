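"""Genome feature annotation for mapping variant positions to genes.

The human mitochondrial genome (rCRS, NC_012920.1; 16,569 bp, 1-based
coordinates) is annotated with 13 protein-coding genes, 22 tRNAs, 2 rRNAs
and the non-coding control region (D-loop), which wraps the origin and is
represented here as the union of its two segments, 16024-16569 and 1-576.
Several gene pairs overlap (ATP8/ATP6, ND4L/ND4, ATP6/CO3 at their shared
boundary); positions in an overlap belong to *every* covering feature, so
downstream tallies double-count them deliberately.

A feature table is a list of ``Feature(name, start, end, kind)`` intervals,
1-based inclusive. Multiple rows may share a name (the control region uses
two). Positions covered by no feature are labelled ``"intergenic"``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ConfigurationError

INTERGENIC = "intergenic"

#: feature kinds considered protein-coding for coding/non-coding tallies
CODING_KINDS = frozenset({"protein"})


@dataclass(frozen=True)
class Feature:
    name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    kind: str = "protein"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ConfigurationError(
                f"feature {self.name}: invalid interval [{self.start}, {self.end}]"
            )

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


class GenomeAnnotation:
    """Interval lookup from 1-based genome positions to feature labels."""

    def __init__(self, features: Iterable[Feature], length: int):
        self.features = list(features)
        self.length = int(length)
        if self.length < 1:
            raise ConfigurationError("annotation length must be >= 1")
        self._kind_of = {f.name: f.kind for f in self.features}

    def features_at(self, position: int) -> list[str]:
        """Every feature label covering *position*, or ``["intergenic"]``.

        Order follows the feature table; duplicate names (multi-segment
        features such as the control region) are reported once.
        """
        if not 1 <= position <= self.length:
            raise ValueError(
                f"position {position} outside reference [1, {self.length}]"
            )
        seen: list[str] = []
        for f in self.features:
            if f.contains(position) and f.name not in seen:
                seen.append(f.name)
        return seen if seen else [INTERGENIC]

    def kind_of(self, feature_name: str) -> str:
        if feature_name == INTERGENIC:
            return INTERGENIC
        return self._kind_of[feature_name]

    def is_coding(self, feature_name: str) -> bool:
        return self.kind_of(feature_name) in CODING_KINDS

    @property
    def feature_names(self) -> list[str]:
        out: list[str] = []
        for f in self.features:
            if f.name not in out:
                out.append(f.name)
        return out

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, length: int) -> "GenomeAnnotation":
        if "kind" not in frame.columns:
            frame = frame.assign(
                kind=[
                    "control_region" if str(g).upper() in ("CR", "D-LOOP") else "protein"
                    for g in frame["gene"]
                ]
            )
        feats = [
            Feature(str(r.gene), int(r.start), int(r.end), str(r.kind))
            for r in frame.itertuples()
        ]
        return cls(feats, length)

    @classmethod
    def from_tsv(cls, path: str | Path, length: int) -> "GenomeAnnotation":
        """Read a ``gene<TAB>start<TAB>end[<TAB>kind]`` table (1-based inclusive)."""
        frame = pd.read_csv(path, sep="\t")
        required = {"gene", "start", "end"}
        if not required.issubset(frame.columns):
            raise ConfigurationError(
                f"annotation {path}: needs columns {sorted(required)}, "
                f"got {list(frame.columns)}"
            )
        return cls.from_frame(frame, length)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(f.name, f.start, f.end, f.kind) for f in self.features],
            columns=["gene", "start", "end", "kind"],
        ).to_csv(path, sep="\t", index=False)


RCRS_LENGTH = 16_569


def rcrs_annotation() -> GenomeAnnotation:
    """The embedded rCRS (NC_012920.1) feature table: 37 genes + control region."""
    ref = importlib.resources.files("mtcooc.data").joinpath("rcrs_annotation.tsv")
    with importlib.resources.as_file(ref) as path:
        return GenomeAnnotation.from_tsv(path, RCRS_LENGTH)
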