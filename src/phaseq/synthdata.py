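"""Ground-truthed synthetic sequencing runs.

Emulates the phased 5'-RACE library on an Illumina single-end run: each
read draws a genotype, cleaves with that genotype's true activity w,
picks a phased insert by its mixing proportion, is composed as
insert + anchor + (transcript | product) + linker context, then
receives iid substitution errors and constant-quality Phred strings.  A
configurable fraction of reads is replaced by PhiX (iid uniform bases
by default).  Truth tables record every read's insert, cleavage state
and genotype, plus the per-genotype true w, so downstream demultiplexing
and quantification can be checked against exact ground truth.

Not emulated: indels, quality-dependent error rates, optical artefacts
and the instrument's cluster filter — recovery tests exercise the
bookkeeping and the estimator, not instrument physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .entropy import PhiXModel, ReadSet, _encode
from .seqmodel import (
    AmpliconTemplate,
    PhasedInsertSet,
    ReadLayout,
    compose_read,
    enumerate_genotypes,
)

__all__ = [
    "SyntheticRunSpec",
    "RunTruth",
    "beta_activities",
    "compensatory_pattern_activities",
    "generate_run",
    "expected_read_depth",
]

_CHAR = np.frombuffer(b"ACGT", dtype=np.uint8)


def beta_activities(
    template: AmpliconTemplate, seed: int, a: float = 2.0, b: float = 2.0
) -> dict[str, float]:
    """True activities drawn iid from Beta(a, b) for every genotype."""
    rng = np.random.default_rng(seed)
    genotypes = enumerate_genotypes(template)
    return {g: float(w) for g, w in zip(genotypes, rng.beta(a, b, len(genotypes)))}


def compensatory_pattern_activities(
    template: AmpliconTemplate,
    reference: str,
    high: float = 0.9,
    low: float = 0.05,
) -> dict[str, float]:
    """Activity pattern mimicking a pseudoknot: Watson-Crick pairing is active.

    A genotype is active (w = high) when all three cross-half base
    pairs (position i with position 5 - i, antiparallel) are
    Watson-Crick; inactive (w = low) otherwise.  The reference genotype
    and its compensatory double mutants are therefore high while most
    other mutants are low.
    """
    if len(template.degenerate_positions) != 6:
        raise ValueError(
            "the pseudoknot pairing pattern needs the full 6-position library"
        )
    wc = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
    out = {}
    for g in enumerate_genotypes(template):
        paired = all((g[i], g[5 - i]) in wc for i in range(3))
        out[g] = high if paired else low
    del reference  # pairing structure, not identity, defines the pattern
    return out


@dataclass(frozen=True)
class SyntheticRunSpec:
    """Specification of one ground-truthed synthetic run.

    ``activities`` maps genotype -> true fraction cleaved w; build it
    with :func:`beta_activities` (default realism) or
    :func:`compensatory_pattern_activities`.  ``error_rate`` is the iid
    per-base substitution probability, ``quality`` the constant Phred
    score written for every base.
    """

    template: AmpliconTemplate
    inserts: PhasedInsertSet | None
    activities: Mapping[str, float]
    n_reads: int = 100_000
    error_rate: float = 0.0
    phix: PhiXModel = field(default_factory=lambda: PhiXModel(0.0))
    quality: int = 37
    layout: ReadLayout | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        for g, w in self.activities.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"activity of {g} outside [0, 1]")


@dataclass(frozen=True)
class RunTruth:
    """Ground truth for one generated run."""

    reads: pd.DataFrame  # read_id, insert_id, cleaved, genotype, is_phix
    activities: dict[str, float]

    def to_tsvs(self, prefix: str | Path) -> tuple[Path, Path]:
        prefix = Path(prefix)
        reads_path = prefix.with_name(prefix.name + ".reads.tsv")
        w_path = prefix.with_name(prefix.name + ".activities.tsv")
        self.reads.to_csv(reads_path, sep="\t", index=False)
        pd.DataFrame(
            sorted(self.activities.items()), columns=["genotype", "w_true"]
        ).to_csv(w_path, sep="\t", index=False)
        return reads_path, w_path


def generate_run(
    spec: SyntheticRunSpec, fastq_path: str | Path | None = None
) -> tuple[list[tuple[str, str, str]], RunTruth]:
    """Generate a synthetic run and its exact truth tables.

    Returns the FASTQ records (id, sequence, quality) — also written to
    ``fastq_path`` if given (gzip by .gz suffix) — and a
    :class:`RunTruth`.  Identical seeds give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    template = spec.template
    layout = spec.layout or ReadLayout(read_length=150, adapter_stub="A" * 60)
    L = layout.read_length
    n = spec.n_reads

    genotypes = sorted(spec.activities)
    w_true = np.array([spec.activities[g] for g in genotypes])
    geno_codes = np.stack([_encode(g) for g in genotypes]) if genotypes[0] else None
    degen = np.array(template.degenerate_positions, dtype=int)

    # per-read draws
    is_phix = rng.random(n) < spec.phix.fraction
    gidx = rng.integers(0, len(genotypes), size=n)
    cleaved = rng.random(n) < w_true[gidx]
    if spec.inserts is not None:
        iidx = rng.choice(len(spec.inserts), size=n, p=spec.inserts.proportions)
        insert_of = spec.inserts.inserts
        anchor = spec.inserts.anchor
    else:
        iidx = np.zeros(n, dtype=int)
        insert_of = ("",)
        anchor = "GGG"

    # composed class templates (degenerate positions coded 4)
    base: dict[tuple[int, bool], np.ndarray] = {}
    npos: dict[tuple[int, bool], tuple[np.ndarray, np.ndarray]] = {}
    for ii in range(len(insert_of)):
        for cl in (False, True):
            s = compose_read(template, insert_of[ii], anchor, cl, layout)
            base[(ii, cl)] = _encode(s)
            offset = len(insert_of[ii]) + len(anchor) - (
                template.cleavage_site if cl else 0
            )
            cyc = degen + offset
            keep = (cyc >= 0) & (cyc < L)  # genotype positions inside the read
            npos[(ii, cl)] = (cyc[keep], keep)

    codes = np.empty((n, L), dtype=np.uint8)
    for (ii, cl), arr in base.items():
        mask = (~is_phix) & (iidx == ii) & (cleaved == cl)
        rows = np.where(mask)[0]
        if rows.size == 0:
            continue
        codes[rows] = arr
        cols, keep = npos[(ii, cl)]
        if cols.size and geno_codes is not None:
            codes[np.ix_(rows, cols)] = geno_codes[gidx[rows]][:, keep]
    n_phix = int(is_phix.sum())
    if n_phix:
        codes[is_phix] = rng.integers(0, 4, size=(n_phix, L), dtype=np.uint8)

    # iid substitution errors: shift to one of the three other bases
    if spec.error_rate > 0:
        err = rng.random((n, L)) < spec.error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        codes[err] = (codes[err] + shift) % 4

    seqs = ReadSet(codes).to_strings()
    qual = chr(spec.quality + 33) * L
    ids = [f"read_{i:07d}" for i in range(n)]
    records = [(rid, s, qual) for rid, s in zip(ids, seqs)]
    if fastq_path is not None:
        from .readproc import write_fastq

        write_fastq(records, fastq_path)

    truth = RunTruth(
        reads=pd.DataFrame(
            {
                "read_id": ids,
                "insert_id": np.where(
                    is_phix, -1, iidx if spec.inserts is not None else -1
                ),
                "cleaved": np.where(is_phix, False, cleaved),
                "genotype": np.where(
                    is_phix, "", np.array(genotypes, dtype=object)[gidx]
                ),
                "is_phix": is_phix,
            }
        ),
        activities=dict(spec.activities),
    )
    return records, truth


def expected_read_depth(n_reads: int, n_genotypes: int) -> tuple[float, float]:
    """Mean reads per genotype and the chance a genotype draws zero reads.

    Under uniform genotype sampling the depth of one genotype is
    Binomial(n_reads, 1/n_genotypes): mean n_reads/n_genotypes, zero
    with probability (1 - 1/n_genotypes)^n_reads.
    """
    if n_reads < 1 or n_genotypes < 1:
        raise ValueError("n_reads and n_genotypes must be positive")
    mean = n_reads / n_genotypes
    p_zero = (1.0 - 1.0 / n_genotypes) ** n_reads if n_genotypes > 1 else 0.0
    return mean, p_zero
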