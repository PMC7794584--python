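"""Independent brute-force oracles used to cross-check the pipeline.

Everything here recomputes results with plain loops and explicit set
arithmetic, deliberately sharing no code path with the package internals.
"""

from __future__ import annotations

import numpy as np

from mtcooc.alignment import AlignedCohort

NUC = "ACGT"


def make_cohort(
    rows: list[str], groups: list[int] | None = None, reference: str | None = None
) -> AlignedCohort:
    """Wrap explicit sequence strings into a cohort (identity coordinate map)."""
    matrix = np.array([list(r) for r in rows], dtype="<U1")
    n, width = matrix.shape
    return AlignedCohort(
        sample_ids=[f"s{k}" for k in range(n)],
        groups=np.array(groups if groups is not None else [1] * n),
        matrix=matrix,
        column_to_ref=np.arange(1, width + 1),
        reference=np.array(list(reference), dtype="<U1") if reference else None,
        reference_id="REF" if reference else None,
    )


def brute_counts(matrix: np.ndarray, col: int) -> dict[str, int]:
    out: dict[str, int] = {}
    for s in range(matrix.shape[0]):
        ch = str(matrix[s, col])
        if ch in NUC:
            out[ch] = out.get(ch, 0) + 1
    return out


def brute_major_minors(
    counts: dict[str, int], ref_allele: str | None
) -> tuple[str, list[str]]:
    top = max(counts.values())
    tied = sorted(a for a in counts if counts[a] == top)
    major = ref_allele if ref_allele in tied else tied[0]
    return major, [a for a in counts if a != major]


def brute_master_edges(
    matrix: np.ndarray, c_th: float = 1.0, reference: np.ndarray | None = None
) -> set[tuple[int, int, str, str]]:
    """Exhaustive allele-level master edges as (pos_i, pos_j, x, y), 1-based.

    Enumerates every column pair, every minor-allele pair and every sample
    directly: an edge requires at least one sample jointly carrying both
    minor alleles and C = N(xy)^2 / (N(x) N(y)) >= c_th, with samples
    missing data at either column left out of all three counts.
    """
    n, width = matrix.shape
    site_cols: list[int] = []
    minors: dict[int, list[str]] = {}
    for col in range(width):
        counts = brute_counts(matrix, col)
        if len(counts) >= 2:
            ref = str(reference[col]) if reference is not None else None
            if ref is not None and ref not in NUC:
                ref = None
            _, mins = brute_major_minors(counts, ref)
            site_cols.append(col)
            minors[col] = mins
    edges: set[tuple[int, int, str, str]] = set()
    for a, i in enumerate(site_cols):
        for j in site_cols[a + 1 :]:
            for x in minors[i]:
                for y in minors[j]:
                    n_x = n_y = n_xy = 0
                    for s in range(n):
                        ai, aj = str(matrix[s, i]), str(matrix[s, j])
                        if ai not in NUC or aj not in NUC:
                            continue
                        n_x += ai == x
                        n_y += aj == y
                        n_xy += ai == x and aj == y
                    if n_xy == 0 or n_x == 0 or n_y == 0:
                        continue
                    if n_xy * n_xy / (n_x * n_y) >= c_th:
                        edges.add((i + 1, j + 1, x, y))
    return edges


def brute_column_to_ref(reference_row: str) -> list[int]:
    """Cumulative non-gap count oracle for reference coordinate mapping."""
    out, pos = [], 0
    for ch in reference_row:
        if ch == "-":
            out.append(-1)
        else:
            pos += 1
            out.append(pos)
    return out


def brute_jaccard(a: set, b: set) -> float:
    inter = sum(1 for x in a if x in b)
    union = len(a) + len(b) - inter
    return inter / union


def random_matrix(
    rng: np.random.Generator,
    n_samples: int,
    n_cols: int,
    alphabet: str = "AACGT-N",
) -> np.ndarray:
    """Random character matrix biased toward 'A' with occasional missing data."""
    return rng.choice(list(alphabet), size=(n_samples, n_cols)).astype("<U1")
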