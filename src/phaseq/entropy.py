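"""Per-cycle nucleotide composition and Shannon entropy.

At each sequencing cycle the base-composition distribution p = (p_A,
p_C, p_G, p_T) has Shannon entropy H = -sum_i p_i log2 p_i, in bits: 2
bits when all four bases are equally likely, 0 when a single base
occurs in every read.  Low per-cycle entropy over the early cycles is
what breaks Illumina cluster identification on low-diversity amplicons.

Two routes compute the same profile: a Monte-Carlo read simulation
(:func:`simulate_run` + :func:`freq_matrix_from_reads`) and an exact
analytic mixture over read classes (:func:`analytic_freq_matrix`), which
serves as the closed-form oracle the simulation converges to.  A PhiX
spike-in is modelled, by default, as a fraction of reads with iid
uniform random bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqmodel import (
    DNA_BASES,
    IUPAC_DNA,
    AmpliconTemplate,
    PhasedInsertSet,
    ReadLayout,
    compose_read,
)

__all__ = [
    "NucleotideFrequencyMatrix",
    "EntropyProfile",
    "PhiXModel",
    "ReadSet",
    "shannon_entropy",
    "freq_matrix_from_reads",
    "analytic_freq_matrix",
    "mix_with_phix",
    "entropy_profile",
    "condition_components",
    "simulate_run",
    "filter_window_summary",
]

# base <-> uint8 code tables; codes 0..3 = ACGT, 4 = ambiguous (N etc.)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(DNA_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CHAR = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _decode_rows(mat: np.ndarray) -> list[str]:
    b = _CHAR[mat]
    width = mat.shape[1]
    return [s.decode() for s in b.view(f"S{width}").ravel()]


@dataclass(frozen=True)
class PhiXModel:
    """PhiX spike-in model: a fraction of reads drawn as random bases.

    ``mode="iid"`` approximates PhiX with iid uniform bases;
    ``mode="genome"`` samples read-length windows from a provided
    genome sequence instead.
    """

    fraction: float = 0.0
    mode: str = "iid"
    genome: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"PhiX fraction {self.fraction} outside [0, 1]")
        if self.mode not in ("iid", "genome"):
            raise ValueError(f"unknown PhiX mode {self.mode!r}")
        if self.mode == "genome" and not self.genome:
            raise ValueError("genome mode requires a genome sequence")


@dataclass(frozen=True)
class NucleotideFrequencyMatrix:
    """Per-cycle proportions of the four canonical bases.

    ``probs`` has one row per read position and one column per base
    (A, C, G, T); each row sums to 1.
    """

    probs: np.ndarray
    n_reads: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("frequency matrix must be (read_length, 4)")
        if (p < -1e-12).any() or np.abs(p.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("each row must be a probability vector over ACGT")

    @property
    def read_length(self) -> int:
        return self.probs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(DNA_BASES))
        df.index.name = "position"
        return df


@dataclass(frozen=True)
class EntropyProfile:
    """Per-position Shannon entropy (bits) with mean +/- population SD."""

    h: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        object.__setattr__(self, "h", h)
        if (h < -1e-9).any() or (h > 2.0 + 1e-9).any():
            raise ValueError("entropy values must lie in [0, 2] bits")
        object.__setattr__(self, "mean", float(h.mean()))
        object.__setattr__(self, "sd", float(h.std()))  # population SD

    def summary(self) -> str:
        return f"{self.mean:.2f} ± {self.sd:.2f} (µ ± σ)"


def shannon_entropy(p: Sequence[float]) -> float:
    """Shannon entropy, in bits, of a base-composition 4-vector.

    Zero proportions contribute zero (0 * log 0 := 0).
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (4,):
        raise ValueError("expected a 4-vector of base proportions")
    if (p < -1e-12).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _row_entropy(probs: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, -probs * np.log2(np.where(probs > 0, probs, 1.0)), 0.0)
    return terms.sum(axis=1)


@dataclass(frozen=True)
class ReadSet:
    """Simulated reads as a dense (n_reads, read_length) code matrix."""

    codes: np.ndarray  # uint8, 0..3 = ACGT

    @property
    def n_reads(self) -> int:
        return self.codes.shape[0]

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    def to_strings(self) -> list[str]:
        return _decode_rows(self.codes)


def freq_matrix_from_reads(
    reads: "ReadSet | Iterable[str]", read_length: int | None = None
) -> NucleotideFrequencyMatrix:
    """Count per-cycle base proportions from observed reads.

    Accepts a :class:`ReadSet` (fast path) or any iterable of equal
    length ACGT strings.  Ambiguous bases (N) are excluded from the
    affected position's count, and the row is renormalized over the
    reads that called a canonical base there.
    """
    if isinstance(reads, ReadSet):
        mat = reads.codes
    else:
        rows = [_encode(r) for r in reads]
        if not rows:
            raise ValueError("no reads supplied")
        L = len(rows[0])
        if any(len(r) != L for r in rows):
            raise ValueError("ragged read lengths; all reads must be equal length")
        mat = np.vstack(rows)
    if read_length is not None and mat.shape[1] != read_length:
        raise ValueError(
            f"reads have length {mat.shape[1]}, expected {read_length}"
        )
    L = mat.shape[1]
    counts = np.empty((L, 5), dtype=np.int64)
    for j in range(L):
        counts[j] = np.bincount(mat[:, j], minlength=5)
    acgt = counts[:, :4].astype(float)
    denom = acgt.sum(axis=1, keepdims=True)
    if (denom == 0).any():
        raise ValueError("a position has no unambiguous base calls")
    return NucleotideFrequencyMatrix(acgt / denom, n_reads=mat.shape[0])


def analytic_freq_matrix(
    components: Sequence[tuple[str, float]], read_length: int
) -> NucleotideFrequencyMatrix:
    """Exact per-cycle base proportions of a mixture of read classes.

    Each component is a (sequence, proportion) pair; the sequence may
    carry IUPAC degenerate codes, which contribute their uniform base
    mixture (N -> 1/4 each) at that cycle.  No sampling is involved:
    this is the closed form the read simulation converges to.
    """
    props = np.array([p for _, p in components], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("component proportions must sum to 1")
    probs = np.zeros((read_length, 4))
    for seq, p in components:
        if len(seq) < read_length:
            raise ValueError(
                f"component of length {len(seq)} is shorter than "
                f"read_length {read_length}; pad via compose_read"
            )
        for j in range(read_length):
            bases = IUPAC_DNA.get(seq[j])
            if bases is None:
                raise ValueError(f"unknown code {seq[j]!r} at position {j}")
            w = p / len(bases)
            for b in bases:
                probs[j, DNA_BASES.index(b)] += w
    return NucleotideFrequencyMatrix(probs)


def mix_with_phix(
    m: NucleotideFrequencyMatrix, phix: PhiXModel
) -> NucleotideFrequencyMatrix:
    """Mix a library frequency matrix with a PhiX read fraction.

    In iid mode each row becomes (1-f) * row + f * (1/4, 1/4, 1/4, 1/4);
    in genome mode the PhiX component is the genome's own positional
    composition over uniformly placed read-length windows.
    """
    f = phix.fraction
    if phix.mode == "iid":
        phix_rows = np.full((m.read_length, 4), 0.25)
    else:
        genome = phix.genome or ""
        if len(genome) < m.read_length:
            raise ValueError("PhiX genome shorter than the read length")
        g = _encode(genome)
        n_windows = len(genome) - m.read_length + 1
        csum = np.zeros((len(genome) + 1, 4))
        for b in range(4):
            csum[1:, b] = np.cumsum(g == b)
        phix_rows = np.empty((m.read_length, 4))
        for j in range(m.read_length):
            phix_rows[j] = (csum[j + n_windows] - csum[j]) / n_windows
    return NucleotideFrequencyMatrix(
        (1.0 - f) * m.probs + f * phix_rows, n_reads=m.n_reads
    )


def entropy_profile(m: NucleotideFrequencyMatrix) -> EntropyProfile:
    """Per-position entropy of a frequency matrix, with mean and SD.

    The SD is the population standard deviation across positions.
    """
    return EntropyProfile(_row_entropy(m.probs))


def condition_components(
    template: AmpliconTemplate,
    inserts: PhasedInsertSet | None,
    layout: ReadLayout,
    cleaved_fraction: float = 0.0,
) -> list[tuple[str, float]]:
    """Read classes (composed sequence, proportion) for one library condition.

    Without inserts the library is the bare low-diversity construct (a
    single uncleaved read class); with inserts each insert-length class
    contributes its mixing proportion, split between uncleaved and
    cleaved products when ``cleaved_fraction`` > 0.
    """
    if not 0.0 <= cleaved_fraction <= 1.0:
        raise ValueError("cleaved_fraction outside [0, 1]")
    if inserts is None:
        classes: list[tuple[str, str, float]] = [("", "", 1.0)]
    else:
        classes = [
            (ins, inserts.anchor, p)
            for ins, p in zip(inserts.inserts, inserts.proportions)
        ]
    out: list[tuple[str, float]] = []
    for ins, anchor, p in classes:
        if cleaved_fraction < 1.0:
            out.append(
                (compose_read(template, ins, anchor, False, layout), p * (1 - cleaved_fraction))
            )
        if cleaved_fraction > 0.0:
            out.append(
                (compose_read(template, ins, anchor, True, layout), p * cleaved_fraction)
            )
    return out


def simulate_run(
    template: AmpliconTemplate,
    inserts: PhasedInsertSet | None,
    layout: ReadLayout,
    phix: PhiXModel | None = None,
    cleaved_fraction: float = 0.0,
    n_reads: int = 1_000_000,
    seed: int | None = None,
) -> ReadSet:
    """Simulate a sequencing run of the library (plus optional PhiX).

    Each read picks an insert class by its mixing proportion, a
    cleavage state with probability ``cleaved_fraction``, and uniform
    bases at the randomized template positions; a ``phix.fraction``
    share of reads is replaced by the PhiX model.  Byte-identical
    output for identical seeds.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible simulation")
    phix = phix or PhiXModel(0.0)
    rng = np.random.default_rng(seed)
    L = layout.read_length

    components = condition_components(template, inserts, layout, cleaved_fraction)
    seqs = [_encode(s) for s, _ in components]
    props = np.array([p for _, p in components])

    is_phix = rng.random(n_reads) < phix.fraction
    comp_idx = rng.choice(len(components), size=n_reads, p=props)

    codes = np.empty((n_reads, L), dtype=np.uint8)
    for ci, base in enumerate(seqs):
        mask = (~is_phix) & (comp_idx == ci)
        n = int(mask.sum())
        if n == 0:
            continue
        codes[mask] = base
        degen = np.where(base == 4)[0]
        if degen.size:
            codes[np.ix_(np.where(mask)[0], degen)] = rng.integers(
                0, 4, size=(n, degen.size), dtype=np.uint8
            )
    n_phix = int(is_phix.sum())
    if n_phix:
        if phix.mode == "iid":
            codes[is_phix] = rng.integers(0, 4, size=(n_phix, L), dtype=np.uint8)
        else:
            g = _encode(phix.genome or "")
            starts = rng.integers(0, len(g) - L + 1, size=n_phix)
            codes[is_phix] = np.stack([g[s : s + L] for s in starts])
    return ReadSet(codes)


@dataclass(frozen=True)
class WindowSummary:
    window: int
    threshold: float
    h: np.ndarray
    min: float
    mean: float
    flagged_cycles: tuple[int, ...]


def filter_window_summary(
    profile: EntropyProfile, window: int = 25, threshold: float = 1.0
) -> WindowSummary:
    """Entropy over the early cycles the instrument's cluster filter sees.

    Reports min and mean entropy over the first ``window`` cycles and
    flags cycles whose entropy falls below ``threshold`` bits.
    """
    if window > profile.h.size:
        raise ValueError("window exceeds the read length")
    h = profile.h[:window]
    flagged = tuple(int(i) for i in np.where(h < threshold)[0])
    return WindowSummary(
        window=window,
        threshold=threshold,
        h=h,
        min=float(h.min()),
        mean=float(h.mean()),
        flagged_cycles=flagged,
    )


def profile_to_tsv(m: NucleotideFrequencyMatrix, path: str | Path) -> None:
    """Serialize a frequency matrix with per-position entropy as TSV."""
    df = m.to_frame()
    df["H"] = _row_entropy(m.probs)
    df.to_csv(path, sep="\t")
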