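"""Mutation-effect matrices and the binomial failed-detection model.

The library's six randomized positions form two 3-nt halves of the T1
pseudoknot, which pair antiparallel (half-A position 0 with half-B
position 2, etc.).  Relative to a reference genotype this yields 18
single mutants (6 positions x 3 alternative bases) and a 9 x 9 grid of
double mutants with one mutation in each half; with columns ordered as
the Watson-Crick partners of the rows, the grid diagonal holds the
compensatory double mutants that preserve base pairing.

Detection of rare genotypes is modelled as Binomial(n, P): with n
sequencing trials and per-trial detection probability P, the chance of
zero detections is (1-P)^n, estimated here both in closed form and by
Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqmodel import DNA_BASES
from .readproc import GenotypeTable

__all__ = [
    "MutantActivityMatrix",
    "DetectionModel",
    "WC_COMPLEMENT",
    "mutant_matrix",
    "correlate_with_reference",
    "failed_detection_prob_exact",
    "failed_detection_prob_mc",
]

WC_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _mutate(genotype: str, pos: int, alt: str) -> str:
    return genotype[:pos] + alt + genotype[pos + 1 :]


def _label(ref: str, pos: int, alt: str) -> str:
    return f"{ref}{pos + 1}{alt}"


@dataclass(frozen=True)
class MutantActivityMatrix:
    """Single- and double-mutant activity grid around a reference genotype.

    ``singles`` has 18 rows (position, ref, alt, genotype, w); ``doubles``
    is a 9 x 9 frame (half-A mutation rows x half-B mutation columns)
    whose diagonal holds the compensatory pairings.  Genotypes never
    observed carry NaN, not zero.
    """

    reference: str
    singles: pd.DataFrame
    doubles: pd.DataFrame
    reference_w: float | None

    @property
    def half_a(self) -> str:
        return self.reference[:3]

    @property
    def half_b(self) -> str:
        return self.reference[3:]

    def genotype_values(self) -> dict[str, float]:
        """All non-missing genotype -> w entries (reference + mutants)."""
        out: dict[str, float] = {}
        if self.reference_w is not None and not math.isnan(self.reference_w):
            out[self.reference] = self.reference_w
        for _, row in self.singles.iterrows():
            if not math.isnan(row["w"]):
                out[row["genotype"]] = row["w"]
        for r in self.doubles.index:
            for c in self.doubles.columns:
                v = self.doubles.loc[r, c]
                g = self._double_genotypes[(r, c)]
                if not math.isnan(v):
                    out[g] = v
        return out

    # populated by mutant_matrix; maps (row label, col label) -> genotype
    @property
    def _double_genotypes(self) -> dict[tuple[str, str], str]:
        return self.__dict__["_dg"]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format heatmap export: row mutation, column mutation, w."""
        rows = []
        for r in self.doubles.index:
            for c in self.doubles.columns:
                rows.append(
                    {
                        "row_mutation": r,
                        "col_mutation": c,
                        "genotype": self._double_genotypes[(r, c)],
                        "w": self.doubles.loc[r, c],
                    }
                )
        return pd.DataFrame(rows)


def _alts(ref: str) -> list[str]:
    return [b for b in DNA_BASES if b != ref]


def mutant_matrix(table: GenotypeTable, reference: str) -> MutantActivityMatrix:
    """Reindex a genotype table into the single/double mutant grid.

    Pure reindexing: every cell's w equals the table's w for that
    genotype (NaN when the genotype was never observed).  Rows are the
    nine half-A mutations in (position, alt) order; columns are their
    Watson-Crick compensatory partners (antiparallel position, WC
    complement of the row's alternative), so compensatory double
    mutants fall on the diagonal.
    """
    if len(reference) != 6:
        raise ValueError(f"reference genotype must be 6 nt, got {reference!r}")
    if any(b not in DNA_BASES for b in reference):
        raise ValueError(f"reference genotype must be ACGT, got {reference!r}")

    def w_of(g: str) -> float:
        v = table.w(g)
        return float("nan") if v is None else v

    single_rows = []
    for pos in range(6):
        for alt in _alts(reference[pos]):
            g = _mutate(reference, pos, alt)
            single_rows.append(
                {
                    "position": pos,
                    "ref": reference[pos],
                    "alt": alt,
                    "genotype": g,
                    "w": w_of(g),
                }
            )
    singles = pd.DataFrame(single_rows)

    # rows: half-A mutations (genotype positions 0..2)
    row_muts = [
        (pos, alt) for pos in range(3) for alt in _alts(reference[pos])
    ]
    # column order = compensatory partner of each row: the antiparallel
    # paired position (0<->2 across halves) with the WC complement base
    col_muts = [
        (5 - pos, WC_COMPLEMENT[alt]) for pos, alt in row_muts
    ]
    row_labels = [_label(reference[p], p, a) for p, a in row_muts]
    col_labels = [_label(reference[p], p, a) for p, a in col_muts]
    grid = np.full((9, 9), np.nan)
    dg: dict[tuple[str, str], str] = {}
    for i, (pa, aa) in enumerate(row_muts):
        for j, (pb, ab) in enumerate(col_muts):
            g = _mutate(_mutate(reference, pa, aa), pb, ab)
            grid[i, j] = w_of(g)
            dg[(row_labels[i], col_labels[j])] = g
    doubles = pd.DataFrame(grid, index=row_labels, columns=col_labels)

    matrix = MutantActivityMatrix(
        reference=reference,
        singles=singles,
        doubles=doubles,
        reference_w=w_of(reference),
    )
    matrix.__dict__["_dg"] = dg
    return matrix


def correlate_with_reference(
    mine: MutantActivityMatrix, reference_table: dict[str, float]
) -> tuple[float, int]:
    """Pearson r between measured and reference activities.

    Computed over genotypes present and non-missing in both (pairwise
    complete).  Returns (r, number of shared genotypes); raises if
    fewer than 3 are shared or either vector has zero variance.
    """
    ours = mine.genotype_values()
    shared = sorted(set(ours) & set(reference_table))
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared genotypes; need at least 3"
        )
    x = np.array([ours[g] for g in shared])
    y = np.array([reference_table[g] for g in shared])
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in an activity vector; r undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r), len(shared)


@dataclass(frozen=True)
class DetectionModel:
    """Binomial model for detecting a rare sequence in n reads."""

    n: int = 689_334
    p: float = 4.45e-6
    iterations: int = 200_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("detection probability must be in [0, 1]")
        if self.n < 1 or self.iterations < 1:
            raise ValueError("n and iterations must be >= 1")


def failed_detection_prob_exact(n: int, p: float) -> float:
    """Closed-form probability of zero detections, (1-p)^n, in log space."""
    if p >= 1.0:
        return 0.0
    return math.exp(n * math.log1p(-p))


def failed_detection_prob_mc(model: DetectionModel) -> float:
    """Monte-Carlo estimate of the zero-detection probability.

    Each iteration draws once from Binomial(n, P) (distributionally
    identical to n Bernoulli trials); the estimate is the fraction of
    iterations with zero detections.  Seeded and reproducible.
    """
    if model.seed is None:
        raise ValueError("a seed is mandatory for the Monte-Carlo model")
    rng = np.random.default_rng(model.seed)
    draws = rng.binomial(model.n, model.p, size=model.iterations)
    return float((draws == 0).mean())
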