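"""Synthetic aligned cohorts with planted co-occurrence structure.

The generator emulates the statistical fingerprint of an altitude-stratified
mitochondrial cohort: eight altitude groups, planted perfectly co-occurring
variant pairs with local / mixed / global scope, independent singleton
variants, a hypervariable control-region analogue (elevated variant rate
and minor-allele frequency), a ~90% transition bias, occasional ambiguity
codes, and tri-allelic sites. Every planted variant is recorded in a truth
manifest so downstream stages can be checked exactly.

Two constructions make truth-based tests sharp at C_th = 1:

* planted pairs in the same group receive *disjoint* carrier sets, and
  every allele-level carrier set within a group is kept *distinct* from
  all others — since C = 1 holds only when two carrier sets coincide, the
  master network at C_th = 1 then contains exactly the planted pairs;
* ambiguity codes are injected only at positions with no planted variant
  (default), so masking never perturbs carrier sets at variant positions.

Seeded pseudo-randomness is the only source of randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .alignment import AlignedCohort, GroupScheme
from .annotation import Feature, GenomeAnnotation
from .errors import ConfigurationError

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
AMBIGUITY_CODES = tuple("RYSWKMBDHV")
REFERENCE_ID = "REF"

N_GROUPS = 8


@dataclass(frozen=True)
class PlantedPair:
    """A perfectly co-occurring variant pair planted into scoped groups."""

    position_i: int
    position_j: int
    carrier_fraction: float = 0.1
    scope: str = "global"  # "global" | "local" | "mixed"
    groups: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.scope not in ("global", "local", "mixed"):
            raise ConfigurationError(f"unknown scope {self.scope!r}")
        if self.scope == "local" and len(self.groups) != 1:
            raise ConfigurationError("local scope needs exactly one group")
        if self.scope == "mixed" and len(self.groups) < 2:
            raise ConfigurationError("mixed scope needs at least two groups")
        if not 0.0 < self.carrier_fraction <= 1.0:
            raise ConfigurationError(
                f"carrier_fraction {self.carrier_fraction} outside (0, 1]"
            )
        if self.position_i == self.position_j:
            raise ConfigurationError("pair positions must differ")

    def scope_groups(self, n_groups: int = N_GROUPS) -> tuple[int, ...]:
        if self.scope == "global":
            return tuple(range(1, n_groups + 1))
        if self.scope == "mixed" and len(self.groups) >= n_groups:
            raise ConfigurationError("mixed scope must exclude at least one group")
        return tuple(sorted(self.groups))


def default_planted_pairs(genome_length: int = 2000) -> list[PlantedPair]:
    """20 planted pairs: 4 global, 8 mixed (lower/higher-altitude blocks), 8 local.

    The mixed pairs split between groups 1-4 and groups 5-8, planting the
    two-block sharing structure that drives the similarity bifurcation seen
    in altitude-stratified cohorts. Positions scale with the genome length
    and stay outside the hotspot block.
    """

    def at(p2000: int) -> int:
        return max(1, round(p2000 * genome_length / 2000))

    pairs: list[PlantedPair] = []
    pos = 210
    for _ in range(4):
        pairs.append(PlantedPair(at(pos), at(pos + 30), scope="global"))
        pos += 60
    for block in ((1, 2, 3, 4), (5, 6, 7, 8)):
        for _ in range(4):
            pairs.append(PlantedPair(at(pos), at(pos + 30), scope="mixed", groups=block))
            pos += 60
    pos = 930
    for g in range(1, N_GROUPS + 1):
        pairs.append(PlantedPair(at(pos), at(pos + 15), scope="local", groups=(g,)))
        pos += 60
    return pairs


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the package's reference conditions."""

    genome_length: int = 2000
    group_sizes: tuple[int, ...] = (30,) * N_GROUPS
    planted_pairs: list[PlantedPair] | None = None  # None -> scaled default set
    singleton_rate: float = 0.02  # per-position variant probability outside the hotspot
    hotspot_interval: tuple[int, int] | None = None  # None -> first tenth (CR analogue)
    hotspot_multiplier: float = 5.0
    hotspot_maf_range: tuple[float, float] = (0.2, 0.45)
    transition_fraction: float = 0.9
    triallelic_rate: float = 0.02
    ambiguous_rate: float = 0.001
    ambiguous_anywhere: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_pairs is None:
            self.planted_pairs = default_planted_pairs(self.genome_length)
        if self.hotspot_interval is None:
            self.hotspot_interval = (1, max(1, self.genome_length // 10))

    def validate(self) -> None:
        if len(self.group_sizes) != N_GROUPS:
            raise ConfigurationError(
                f"expected {N_GROUPS} altitude groups, got {len(self.group_sizes)}"
            )
        if any(s < 1 for s in self.group_sizes):
            raise ConfigurationError("every group needs at least one sample")
        if self.genome_length < 1:
            raise ConfigurationError("genome_length must be positive")
        if not 0.0 <= self.transition_fraction <= 1.0:
            raise ConfigurationError("transition_fraction outside [0, 1]")
        seen: set[int] = set()
        for pair in self.planted_pairs:
            for p in (pair.position_i, pair.position_j):
                if not 1 <= p <= self.genome_length:
                    raise ConfigurationError(f"planted position {p} outside genome")
                if p in seen:
                    raise ConfigurationError(f"planted position {p} used twice")
                seen.add(p)
            for g in pair.scope_groups():
                n_car = round(pair.carrier_fraction * self.group_sizes[g - 1])
                if n_car < 1:
                    raise ConfigurationError(
                        f"pair ({pair.position_i}, {pair.position_j}): "
                        f"carrier_fraction {pair.carrier_fraction} yields zero "
                        f"carriers in group {g}"
                    )


def toy_annotation(genome_length: int) -> GenomeAnnotation:
    """Contiguous labelled blocks: a CR analogue, an overlapping gene pair, a tRNA.

    GENE1/GENE2 overlap by ~2% of the genome to exercise double counting.
    """
    L = genome_length
    if L < 50:
        raise ConfigurationError("toy annotation needs a genome of at least 50 positions")
    cr_end = L // 10
    feats = [
        Feature("CR", 1, cr_end, "control_region"),
        Feature("GENE1", cr_end + 1, int(0.28 * L), "protein"),
        Feature("GENE2", int(0.26 * L) + 1, int(0.48 * L), "protein"),
        Feature("GENE3", int(0.48 * L) + 1, int(0.70 * L), "protein"),
        Feature("TRNA1", int(0.70 * L) + 1, int(0.73 * L), "tRNA"),
        Feature("GENE4", int(0.73 * L) + 1, L, "protein"),
    ]
    return GenomeAnnotation(feats, L)


# --------------------------------------------------------------------- truth


@dataclass
class PairTruth:
    position_i: int
    position_j: int
    minor_i: str
    minor_j: str
    scope: str
    groups: tuple[int, ...]
    carriers: dict[int, list[str]]  # group -> carrier sample ids


@dataclass
class SingletonTruth:
    position: int
    group: int
    alleles: dict[str, list[str]]  # minor allele -> carrier sample ids


@dataclass
class TruthManifest:
    """Ground truth of everything the generator planted."""

    seed: int
    genome_length: int
    group_sizes: tuple[int, ...]
    pairs: list[PairTruth]
    singletons: list[SingletonTruth]
    gene_of: dict[int, str]  # variant position -> toy feature label(s)
    ambiguous_cells: list[tuple[str, int, str]]  # (sample_id, position, code)

    def pair_positions(self) -> set[int]:
        return {p for t in self.pairs for p in (t.position_i, t.position_j)}

    def in_scope_pairs(self, group: int) -> set[tuple[int, int]]:
        """The planted position pairs active (carried) in one group."""
        return {
            (min(t.position_i, t.position_j), max(t.position_i, t.position_j))
            for t in self.pairs
            if group in t.carriers
        }

    def variable_positions(self, group: int) -> set[int]:
        """Every position planted as a variant in one group."""
        out = {p for t in self.pairs if group in t.carriers
               for p in (t.position_i, t.position_j)}
        out |= {s.position for s in self.singletons if s.group == group}
        return out

    def scope_of_pair(self, i: int, j: int) -> str:
        for t in self.pairs:
            if {t.position_i, t.position_j} == {i, j}:
                return t.scope
        raise KeyError(f"no planted pair ({i}, {j})")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "genome_length": self.genome_length,
            "group_sizes": list(self.group_sizes),
            "pairs": [
                {**asdict(t), "groups": list(t.groups),
                 "carriers": {str(g): c for g, c in t.carriers.items()}}
                for t in self.pairs
            ],
            "singletons": [asdict(s) for s in self.singletons],
            "gene_of": {str(p): g for p, g in self.gene_of.items()},
            "ambiguous_cells": [list(c) for c in self.ambiguous_cells],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        validate_manifest(payload)
        return cls(
            seed=payload["seed"],
            genome_length=payload["genome_length"],
            group_sizes=tuple(payload["group_sizes"]),
            pairs=[
                PairTruth(
                    position_i=t["position_i"], position_j=t["position_j"],
                    minor_i=t["minor_i"], minor_j=t["minor_j"],
                    scope=t["scope"], groups=tuple(t["groups"]),
                    carriers={int(g): list(c) for g, c in t["carriers"].items()},
                )
                for t in payload["pairs"]
            ],
            singletons=[
                SingletonTruth(
                    position=s["position"], group=s["group"],
                    alleles={a: list(c) for a, c in s["alleles"].items()},
                )
                for s in payload["singletons"]
            ],
            gene_of={int(p): g for p, g in payload["gene_of"].items()},
            ambiguous_cells=[tuple(c) for c in payload["ambiguous_cells"]],
        )


def validate_manifest(payload: dict) -> None:
    """Schema check for a manifest JSON payload; raises ``ConfigurationError``."""
    required = {
        "seed", "genome_length", "group_sizes", "pairs", "singletons",
        "gene_of", "ambiguous_cells",
    }
    missing = required - payload.keys()
    if missing:
        raise ConfigurationError(f"manifest missing keys: {sorted(missing)}")
    L = payload["genome_length"]
    for t in payload["pairs"]:
        for key in ("position_i", "position_j", "minor_i", "minor_j", "scope", "carriers"):
            if key not in t:
                raise ConfigurationError(f"pair entry missing {key!r}")
        if not (1 <= t["position_i"] <= L and 1 <= t["position_j"] <= L):
            raise ConfigurationError("pair position outside genome")
    for s in payload["singletons"]:
        if not 1 <= s["position"] <= L:
            raise ConfigurationError("singleton position outside genome")


# ----------------------------------------------------------------- generator


def _mutate(base: str, transition_fraction: float, rng: np.random.Generator) -> str:
    """Substitute *base*, choosing the transition partner with the given bias."""
    if rng.random() < transition_fraction:
        return TRANSITION_PARTNER[base]
    others = [b for b in "ACGT" if b != base and b != TRANSITION_PARTNER[base]]
    return others[int(rng.integers(len(others)))]


def _altitudes(scheme: GroupScheme) -> list[float]:
    """A representative altitude inside each bin of *scheme*."""
    b = scheme.boundaries
    mids = [b[0] / 2.0]
    mids += [(b[k - 1] + b[k]) / 2.0 for k in range(1, len(b))]
    mids.append(b[-1] + 250.0)
    return mids


def generate_cohort(config: SynthConfig) -> tuple[AlignedCohort, TruthManifest]:
    """Emit an aligned cohort plus its truth manifest, deterministically."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    n_groups = len(config.group_sizes)

    reference = rng.choice(list("ACGT"), size=L).astype("<U1")
    sample_ids: list[str] = []
    groups: list[int] = []
    group_rows: dict[int, list[int]] = {}
    for g, size in enumerate(config.group_sizes, start=1):
        group_rows[g] = list(range(len(sample_ids), len(sample_ids) + size))
        sample_ids += [f"G{g}S{k:02d}" for k in range(size)]
        groups += [g] * size
    matrix = np.tile(reference, (len(sample_ids), 1))

    used_sets: dict[int, set[frozenset[int]]] = {g: set() for g in group_rows}
    pair_pool: dict[int, list[int]] = {g: list(rows) for g, rows in group_rows.items()}
    annotation = toy_annotation(L)
    gene_of: dict[int, str] = {}

    def note_gene(position: int) -> None:
        gene_of[position] = ",".join(annotation.features_at(position))

    # planted pairs: disjoint carrier sets within each group
    pair_truths: list[PairTruth] = []
    for pair in config.planted_pairs:
        minor_i = _mutate(str(reference[pair.position_i - 1]), config.transition_fraction, rng)
        minor_j = _mutate(str(reference[pair.position_j - 1]), config.transition_fraction, rng)
        carriers: dict[int, list[str]] = {}
        for g in pair.scope_groups(n_groups):
            size = config.group_sizes[g - 1]
            n_car = round(pair.carrier_fraction * size)
            pool = pair_pool[g]
            if n_car > len(pool):
                raise ConfigurationError(
                    f"group {g}: not enough unassigned samples for disjoint "
                    f"carrier sets (need {n_car}, have {len(pool)})"
                )
            chosen = sorted(
                rng.choice(pool, size=n_car, replace=False).tolist()
            )
            pair_pool[g] = [s for s in pool if s not in chosen]
            used_sets[g].add(frozenset(chosen))
            rows = np.array(chosen)
            matrix[rows, pair.position_i - 1] = minor_i
            matrix[rows, pair.position_j - 1] = minor_j
            carriers[g] = [sample_ids[s] for s in chosen]
        pair_truths.append(
            PairTruth(
                position_i=pair.position_i, position_j=pair.position_j,
                minor_i=minor_i, minor_j=minor_j, scope=pair.scope,
                groups=pair.scope_groups(n_groups), carriers=carriers,
            )
        )
        note_gene(pair.position_i)
        note_gene(pair.position_j)

    # singleton variants: carrier sets kept distinct from every other set
    planted_positions = {p for t in pair_truths for p in (t.position_i, t.position_j)}
    singleton_truths: list[SingletonTruth] = []
    hot_lo, hot_hi = config.hotspot_interval

    def draw_carriers(g: int, n_car: int) -> list[int] | None:
        rows = group_rows[g]
        n_car = min(n_car, len(rows) - 1)  # keep the site polymorphic
        if n_car < 1:
            return None
        for _ in range(30):
            chosen = frozenset(rng.choice(rows, size=n_car, replace=False).tolist())
            if chosen not in used_sets[g]:
                return sorted(chosen)
        return None

    for position in range(1, L + 1):
        if position in planted_positions:
            continue
        in_hotspot = hot_lo <= position <= hot_hi
        rate = config.singleton_rate * (config.hotspot_multiplier if in_hotspot else 1.0)
        if rng.random() >= min(rate, 1.0):
            continue
        u = rng.random()
        if u < 0.7:
            scoped = [int(rng.integers(1, n_groups + 1))]
        elif u < 0.9:
            k = int(rng.integers(2, n_groups))
            scoped = sorted(
                rng.choice(np.arange(1, n_groups + 1), size=k, replace=False).tolist()
            )
        else:
            scoped = list(range(1, n_groups + 1))
        minor = _mutate(str(reference[position - 1]), config.transition_fraction, rng)
        realized = False
        for g in scoped:
            size = config.group_sizes[g - 1]
            if in_hotspot:
                maf = rng.uniform(*config.hotspot_maf_range)
                n_car = max(1, round(maf * size))
            else:
                n_car = int(rng.integers(1, 4))
            chosen = draw_carriers(g, n_car)
            if chosen is None:
                continue
            alleles: dict[str, list[int]] = {minor: chosen}
            if len(chosen) >= 2 and rng.random() < config.triallelic_rate:
                second_options = [
                    b for b in "ACGT" if b not in (minor, str(reference[position - 1]))
                ]
                second = second_options[int(rng.integers(len(second_options)))]
                half = len(chosen) // 2
                part_a, part_b = chosen[:half], chosen[half:]
                if (
                    frozenset(part_a) not in used_sets[g]
                    and frozenset(part_b) not in used_sets[g]
                ):
                    alleles = {minor: part_b, second: part_a}
            for allele, rows_a in alleles.items():
                used_sets[g].add(frozenset(rows_a))
                matrix[np.array(rows_a), position - 1] = allele
            singleton_truths.append(
                SingletonTruth(
                    position=position, group=g,
                    alleles={a: [sample_ids[s] for s in r] for a, r in alleles.items()},
                )
            )
            realized = True
        if realized:
            note_gene(position)

    # ambiguity codes, by default only where nothing was planted
    variant_positions = planted_positions | {s.position for s in singleton_truths}
    ambiguous_cells: list[tuple[str, int, str]] = []
    if config.ambiguous_rate > 0:
        eligible = np.ones(L, dtype=bool)
        if not config.ambiguous_anywhere:
            eligible[[p - 1 for p in variant_positions]] = False
        u = rng.random(matrix.shape)
        hit_rows, hit_cols = np.nonzero((u < config.ambiguous_rate) & eligible[None, :])
        for r, c in zip(hit_rows.tolist(), hit_cols.tolist()):
            code = AMBIGUITY_CODES[int(rng.integers(len(AMBIGUITY_CODES)))]
            ambiguous_cells.append((sample_ids[r], c + 1, code))
            matrix[r, c] = "N"  # in-memory cohorts are already normalized

    cohort = AlignedCohort(
        sample_ids=sample_ids,
        groups=np.array(groups, dtype=int),
        matrix=matrix,
        column_to_ref=np.arange(1, L + 1),
        reference=reference,
        reference_id=REFERENCE_ID,
    )
    manifest = TruthManifest(
        seed=config.seed,
        genome_length=L,
        group_sizes=tuple(config.group_sizes),
        pairs=pair_truths,
        singletons=singleton_truths,
        gene_of=gene_of,
        ambiguous_cells=ambiguous_cells,
    )
    return cohort, manifest


# ------------------------------------------------------------------ fixtures


def _wrap(seq: str, width: int = 70) -> str:
    return "\n".join(seq[k : k + width] for k in range(0, len(seq), width))


def cohort_fasta_text(cohort: AlignedCohort, manifest: TruthManifest | None = None) -> str:
    """Multi-FASTA text: reference record first, ambiguity codes reinstated."""
    raw = {(s, p): code for s, p, code in (manifest.ambiguous_cells if manifest else [])}
    chunks = []
    if cohort.reference is not None:
        chunks.append(f">{cohort.reference_id or REFERENCE_ID}\n"
                      f"{_wrap(''.join(cohort.reference))}\n")
    for k, sample in enumerate(cohort.sample_ids):
        row = cohort.matrix[k].copy()
        for (s, p), code in raw.items():
            if s == sample:
                row[p - 1] = code
        chunks.append(f">{sample}\n{_wrap(''.join(row))}\n")
    return "".join(chunks)


def write_fixture(
    cohort: AlignedCohort, manifest: TruthManifest, directory: str | Path
) -> dict[str, Path]:
    """Emit FASTA + metadata TSV + toy annotation TSV + manifest JSON."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": directory / "cohort.fasta",
            "metadata": directory / "metadata.tsv",
            "annotation": directory / "annotation.tsv",
            "manifest": directory / "manifest.json",
        }
        paths["fasta"].write_text(cohort_fasta_text(cohort, manifest))
        altitude = _altitudes(cohort.scheme)
        lines = ["sample_id\taltitude_m"]
        for sample, g in zip(cohort.sample_ids, cohort.groups):
            lines.append(f"{sample}\t{altitude[int(g) - 1]:g}")
        paths["metadata"].write_text("\n".join(lines) + "\n")
        toy_annotation(manifest.genome_length).to_tsv(paths["annotation"])
        manifest.to_json(paths["manifest"])
    except OSError as err:
        raise OSError(f"could not write fixture under {directory}: {err}") from err
    return paths
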