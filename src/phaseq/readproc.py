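"""FASTQ ingestion, demultiplexing, classification and genotype counting.

A read from the phased 5'-RACE library is, in sequencing orientation:
phased insert + GGG anchor + (full transcript | cleaved product) +
linker context.  Processing is therefore:

1. demultiplex: identify which phased insert prefixes the read (the
   insert set is prefix-free, so at zero mismatches the match is
   unique), consume insert + anchor;
2. classify: the trimmed read starts either with the transcript leader
   (uncleaved) or directly at the cleavage-site sequence (cleaved);
3. genotype: read the bases at the randomized positions (offset by the
   cleavage site for cleaved reads);
4. count: per-genotype cleaved/uncleaved tallies and the fraction
   cleaved w = N_cleaved / (N_cleaved + N_uncleaved).

Reads are handled as DNA in read orientation; the architecture is
single-end and fixed, so no reverse-complement search is performed.  No
quality filter is applied by default; an optional mean-Q threshold is
available.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .seqmodel import (
    DNA_BASES,
    AmpliconTemplate,
    PhasedInsertSet,
    TemplateError,
)

__all__ = [
    "ProcessedRead",
    "GenotypeTable",
    "read_fastq",
    "write_fastq",
    "demux_and_trim",
    "classify_read",
    "process_read",
    "count_genotypes",
    "quantify",
]

UNASSIGNED = "unassigned"


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a Phred+33 FASTQ file.

    Plain or gzipped input is accepted (by .gz suffix).  Malformed
    records raise with the offending record's position.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_maybe_gzip(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield title.split()[0] if title else "", seq, qual
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, sequence, quality) records as 4-line FASTQ (gzip by suffix)."""
    with _open_maybe_gzip(path, "wt") as fh:
        for rid, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(f"{rid}: sequence/quality length mismatch")
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


@dataclass(frozen=True)
class ProcessedRead:
    read_id: str
    insert_id: int | None  # index into the insert set, None = unassigned
    trimmed: str
    category: str  # "cleaved" | "uncleaved" | "unassigned"
    genotype: str | None


def _hamming_prefix(seq: str, probe: str) -> int:
    """Mismatches of ``probe`` against the start of ``seq`` (len(probe) if short)."""
    if len(seq) < len(probe):
        return len(probe)
    return sum(a != b for a, b in zip(seq, probe))


def demux_and_trim(
    seq: str, inserts: PhasedInsertSet, max_mismatch: int = 0
) -> tuple[int | None, str]:
    """Assign a read to its phased insert and strip insert + anchor.

    The insert region may carry up to ``max_mismatch`` substitutions;
    the anchor is always matched exactly.  Ties at equal mismatch count
    are broken toward the longest insert (longer matches are less
    likely by chance).  Returns (insert index or None, trimmed read).
    """
    best: tuple[int, int, int] | None = None  # (mismatches, -length, index)
    for idx, ins in enumerate(inserts.inserts):
        mm = _hamming_prefix(seq, ins)
        if mm > max_mismatch:
            continue
        if seq[len(ins) : len(ins) + len(inserts.anchor)] != inserts.anchor:
            continue
        key = (mm, -len(ins), idx)
        if best is None or key < best:
            best = key
    if best is None:
        return None, seq
    idx = best[2]
    cut = len(inserts.inserts[idx]) + len(inserts.anchor)
    return idx, seq[cut:]


def _match_with_wildcards(seq: str, probe: str, max_mismatch: int) -> bool:
    """Prefix match where N in the probe matches any base."""
    if len(seq) < len(probe):
        return False
    mm = sum(p != "N" and s != p for s, p in zip(seq, probe))
    return mm <= max_mismatch


def classify_read(
    trimmed: str,
    template: AmpliconTemplate,
    max_mismatch_prefix: int = 0,
    probe_extra: int = 4,
) -> str:
    """Classify a trimmed read as cleaved, uncleaved or unassigned.

    Uncleaved reads begin with the transcript start (leader present),
    cleaved reads begin directly at the cleavage-site sequence.  The
    comparison uses a probe of leader length + ``probe_extra`` bases;
    randomized template positions are wildcards.
    """
    cs = template.cleavage_site
    k = cs + probe_extra
    leader_probe = template.sequence[: min(k, len(template.sequence))]
    product_probe = template.product[: min(k, len(template.product))]
    if product_probe and leader_probe.startswith(product_probe) or (
        cs > 0 and template.product.startswith(template.leader)
    ):
        raise TemplateError(
            "leader and cleaved product are not distinguishable prefixes"
        )
    if cs == 0:
        raise TemplateError(
            "template without a leader cannot separate cleaved from uncleaved"
        )
    if _match_with_wildcards(trimmed, leader_probe, max_mismatch_prefix):
        return "uncleaved"
    if _match_with_wildcards(trimmed, product_probe, max_mismatch_prefix):
        return "cleaved"
    return UNASSIGNED


def _genotype_of(trimmed: str, template: AmpliconTemplate, category: str) -> str | None:
    offset = template.cleavage_site if category == "cleaved" else 0
    bases = []
    for pos in template.degenerate_positions:
        j = pos - offset
        if j < 0 or j >= len(trimmed):
            return None
        b = trimmed[j]
        if b not in DNA_BASES:
            return None
        bases.append(b)
    return "".join(bases)


def process_read(
    read_id: str,
    seq: str,
    inserts: PhasedInsertSet,
    template: AmpliconTemplate,
    max_mismatch: int = 0,
    max_mismatch_prefix: int = 0,
) -> ProcessedRead:
    """Run one read through demultiplexing, classification and genotyping."""
    insert_id, trimmed = demux_and_trim(seq, inserts, max_mismatch)
    if insert_id is None:
        return ProcessedRead(read_id, None, seq, UNASSIGNED, None)
    category = classify_read(trimmed, template, max_mismatch_prefix)
    if category == UNASSIGNED:
        return ProcessedRead(read_id, insert_id, trimmed, UNASSIGNED, None)
    genotype = _genotype_of(trimmed, template, category)
    return ProcessedRead(read_id, insert_id, trimmed, category, genotype)


@dataclass
class GenotypeTable:
    """Per-genotype cleaved/uncleaved counts and the fraction cleaved w."""

    counts: dict[str, list[int]] = field(default_factory=dict)  # g -> [nc, nu]
    unassigned: int = 0
    dropped: Counter = field(default_factory=Counter)  # reason -> n
    per_insert: Counter = field(default_factory=Counter)
    total_reads: int = 0

    def add(self, read: ProcessedRead) -> None:
        self.total_reads += 1
        if read.insert_id is not None:
            self.per_insert[read.insert_id] += 1
        if read.category == UNASSIGNED:
            self.unassigned += 1
            return
        if read.genotype is None:
            self.dropped["ambiguous_genotype"] += 1
            return
        nc_nu = self.counts.setdefault(read.genotype, [0, 0])
        nc_nu[0 if read.category == "cleaved" else 1] += 1

    @property
    def assigned(self) -> int:
        return self.total_reads - self.unassigned - sum(self.dropped.values())

    def w(self, genotype: str) -> float | None:
        """Fraction cleaved for one genotype; None if never observed."""
        if genotype not in self.counts:
            return None
        nc, nu = self.counts[genotype]
        return nc / (nc + nu)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "genotype": g,
                "n_cleaved": nc,
                "n_uncleaved": nu,
                "w": nc / (nc + nu),
            }
            for g, (nc, nu) in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["genotype", "n_cleaved", "n_uncleaved", "w"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t")
        table = cls()
        for _, row in df.iterrows():
            table.counts[str(row["genotype"])] = [
                int(row["n_cleaved"]),
                int(row["n_uncleaved"]),
            ]
        table.total_reads = int(df["n_cleaved"].sum() + df["n_uncleaved"].sum())
        return table

    def summary(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "assigned": self.assigned,
            "unassigned": self.unassigned,
            "dropped": dict(self.dropped),
            "per_insert": {str(k): v for k, v in sorted(self.per_insert.items())},
            "n_genotypes_observed": len(self.counts),
        }

    def save_summary(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _mean_quality(qual: str) -> float:
    return sum(ord(q) - 33 for q in qual) / len(qual)


def count_genotypes(
    reads: Iterable[ProcessedRead], template: AmpliconTemplate
) -> GenotypeTable:
    """Tally a stream of processed reads into a genotype table."""
    del template  # genotype extraction already happened per read
    table = GenotypeTable()
    for read in reads:
        table.add(read)
    return table


def quantify(
    fastq: str | Path | Iterable[tuple[str, str, str]],
    inserts: PhasedInsertSet,
    template: AmpliconTemplate,
    max_mismatch: int = 0,
    max_mismatch_prefix: int = 0,
    min_mean_q: float | None = None,
) -> GenotypeTable:
    """Full pipeline: FASTQ (path or record stream) -> GenotypeTable.

    ``min_mean_q`` optionally drops reads below a mean Phred quality
    (off by default; the counting itself applies no quality filter).
    """
    records = read_fastq(fastq) if isinstance(fastq, (str, Path)) else fastq
    table = GenotypeTable()
    for rid, seq, qual in records:
        if min_mean_q is not None and _mean_quality(qual) < min_mean_q:
            table.total_reads += 1
            table.dropped["low_quality"] += 1
            continue
        table.add(
            process_read(rid, seq, inserts, template, max_mismatch, max_mismatch_prefix)
        )
    return table
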