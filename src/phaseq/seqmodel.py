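"""Domain types for phased-insert amplicon libraries.

The library construct is stored in transcript orientation (RNA sense,
written as DNA, 5'->3'): a short leader, the ribozyme body with its
randomized (N) positions, and a fixed 3' linker used as the reverse
transcription primer binding site.  Self-cleaving variants cut at
``cleavage_site``, so a cleaved molecule's read begins at that offset
while an uncleaved read begins at position 0.

Sequenced reads are composed as::

    [phased insert?] + [anchor (GGG)] + [transcript or cleaved product] + linker + adapter stub

All coordinates are 0-based, half-open; cycle 0 is the first sequenced
base.  Reads shorter than the machine read length are padded by
continuing into the linker and then a fixed adapter stub (the stub is
repeated if exhausted); longer compositions are truncated at the read
length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "DNA_BASES",
    "IUPAC_DNA",
    "AmpliconTemplate",
    "PhasedInsertSet",
    "ReadLayout",
    "compose_read",
    "expand_degenerate",
    "enumerate_genotypes",
    "homopolymer_phase_report",
    "read_fasta",
    "write_fasta",
    "load_template",
    "save_template",
]

DNA_BASES = "ACGT"

# IUPAC nucleotide codes -> the set of canonical bases they stand for.
IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


class TemplateError(ValueError):
    """Raised for invalid template / insert-set configurations."""


@dataclass(frozen=True)
class AmpliconTemplate:
    """A library construct in transcript orientation.

    Parameters
    ----------
    name : str
        Identifier for the construct.
    sequence : str
        Full transcript 5'->3' over the IUPAC DNA alphabet.  The leader
        (bases before ``cleavage_site``) is lost from cleaved molecules.
    cleavage_site : int
        0-based offset at which the cleaved product begins.
    linker : str
        Fixed 3' tail (primer-binding region) appended after the
        transcript in every read.
    """

    name: str
    sequence: str
    cleavage_site: int
    linker: str = ""
    degenerate_positions: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "linker", self.linker.upper())
        degen = []
        for i, base in enumerate(seq):
            if base not in IUPAC_DNA:
                raise TemplateError(
                    f"{self.name}: unknown IUPAC code {base!r} at position {i}"
                )
            if base not in DNA_BASES:
                degen.append(i)
        object.__setattr__(self, "degenerate_positions", tuple(degen))
        if not 0 <= self.cleavage_site < len(seq):
            raise TemplateError(
                f"{self.name}: cleavage_site {self.cleavage_site} outside "
                f"[0, {len(seq)})"
            )

    @property
    def leader(self) -> str:
        """Bases upstream of the cleavage site (absent from cleaved reads)."""
        return self.sequence[: self.cleavage_site]

    @property
    def product(self) -> str:
        """The cleaved product: transcript from the cleavage site on."""
        return self.sequence[self.cleavage_site :]

    def n_genotypes(self) -> int:
        k = 1
        for i in self.degenerate_positions:
            k *= len(IUPAC_DNA[self.sequence[i]])
        return k


@dataclass(frozen=True)
class PhasedInsertSet:
    """A set of variable-length phased inserts plus the fixed anchor.

    The anchor is the read-side image of the template-switching oligo's
    three riboguanosines: it follows every insert in a read.  Insert
    lengths must be strictly increasing (the phasing requirement) and no
    insert may be a prefix of another (unambiguous demultiplexing).
    """

    inserts: tuple[str, ...]
    proportions: tuple[float, ...] = ()
    anchor: str = "GGG"

    def __post_init__(self) -> None:
        ins = tuple(s.upper() for s in self.inserts)
        object.__setattr__(self, "inserts", ins)
        object.__setattr__(self, "anchor", self.anchor.upper())
        if not self.proportions:
            object.__setattr__(
                self, "proportions", tuple(1.0 / len(ins) for _ in ins)
            )
        if len(self.proportions) != len(ins):
            raise TemplateError("one mixing proportion per insert required")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise TemplateError("insert proportions must sum to 1")
        for s in ins:
            if any(b not in DNA_BASES for b in s):
                raise TemplateError(f"insert {s!r} contains non-ACGT bases")
        lengths = [len(s) for s in ins]
        if any(b <= a for a, b in zip(lengths, lengths[1:])):
            raise TemplateError(
                f"insert lengths must be strictly increasing, got {lengths}"
            )
        for a, b in itertools.permutations(ins, 2):
            if b.startswith(a):
                raise TemplateError(
                    f"insert {a!r} is a prefix of {b!r}; set is not "
                    "prefix-free"
                )

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.inserts)

    def __len__(self) -> int:
        return len(self.inserts)


@dataclass(frozen=True)
class ReadLayout:
    """How a sequencing read is assembled from the construct.

    ``adapter_stub`` is the fixed context a read runs into after the
    linker; it is repeated if the read length is still not reached.
    """

    read_length: int = 150
    adapter_stub: str = ""

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise TemplateError("read_length must be positive")


def compose_read(
    template: AmpliconTemplate,
    insert: str,
    anchor: str,
    cleaved: bool,
    layout: ReadLayout,
) -> str:
    """Compose the full-cycle read for one molecule class.

    Degenerate codes in the template are preserved (the caller decides
    whether to treat them analytically or to sample them).  The result
    has exactly ``layout.read_length`` characters: the composition is
    truncated, or padded into the linker and then the (repeated) adapter
    stub.
    """
    start = template.cleavage_site if cleaved else 0
    body = insert + anchor + template.sequence[start:] + template.linker
    L = layout.read_length
    if len(body) < L:
        stub = layout.adapter_stub
        if not stub:
            raise TemplateError(
                f"composed read is {len(body)} < read_length {L} and the "
                "layout has no adapter stub to pad with"
            )
        reps = -(-(L - len(body)) // len(stub))
        body += stub * reps
    return body[:L]


# ---------------------------------------------------------------------------
# Operations on templates


def expand_degenerate(template: AmpliconTemplate, rng: np.random.Generator) -> str:
    """Draw one concrete ACGT sequence from a degenerate template.

    Each degenerate position is drawn uniformly from the bases its IUPAC
    code allows (N -> uniform over ACGT).
    """
    seq = list(template.sequence)
    for i in template.degenerate_positions:
        choices = IUPAC_DNA[seq[i]]
        seq[i] = choices[rng.integers(len(choices))]
    return "".join(seq)


def enumerate_genotypes(template: AmpliconTemplate) -> list[str]:
    """All genotypes (bases at the randomized positions), lexicographic.

    Only fully randomized (N) positions are supported; a template with k
    N positions yields 4**k genotypes.  A template without degenerate
    positions has the single empty genotype.
    """
    for i in template.degenerate_positions:
        code = template.sequence[i]
        if code != "N":
            raise TemplateError(
                f"degenerate code {code!r} at position {i} is not supported; "
                "only N positions can be enumerated"
            )
    k = len(template.degenerate_positions)
    return ["".join(combo) for combo in itertools.product(DNA_BASES, repeat=k)]


def _maximal_runs(seq: str, min_run: int) -> list[tuple[int, int, str]]:
    """(start, length, base) for every maximal homopolymer run >= min_run."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j - i, seq[i]))
        i = j
    return runs


def homopolymer_phase_report(
    template: AmpliconTemplate,
    inserts: PhasedInsertSet | None,
    min_run: int = 5,
    layout: ReadLayout | None = None,
    filter_window: int = 25,
):
    """Where homopolymer runs land, per phased insert, in uncleaved reads.

    Illumina's cluster filter uses roughly the first ``filter_window``
    cycles; a long homopolymer starting inside that window in every read
    is exactly what phasing is meant to break up, so such runs are
    flagged.  The report includes a baseline row (no insert, anchor
    only) plus one row per insert.

    Returns a :class:`pandas.DataFrame` with columns
    ``insert_id, insert_length, base, run_length, cycle, in_filter_window``.
    """
    import pandas as pd

    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    layout = layout or ReadLayout(
        read_length=10 ** 9, adapter_stub="A"
    )  # effectively unpadded/untruncated
    anchor = inserts.anchor if inserts is not None else "GGG"
    rows = []
    cases: list[tuple[object, str]] = [(None, "")]
    if inserts is not None:
        cases += list(enumerate(inserts.inserts))
    for insert_id, ins in cases:
        read = ins + anchor + template.sequence + template.linker
        read = read[: layout.read_length]
        for start, length, base in _maximal_runs(read, min_run):
            rows.append(
                {
                    "insert_id": insert_id,
                    "insert_length": len(ins),
                    "base": base,
                    "run_length": length,
                    "cycle": start,
                    "in_filter_window": start < filter_window,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "insert_id",
            "insert_length",
            "base",
            "run_length",
            "cycle",
            "in_filter_window",
        ],
    )


# ---------------------------------------------------------------------------
# I/O: FASTA for sequences, YAML sidecar for template metadata


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (name, sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def save_template(template: AmpliconTemplate, fasta: str | Path, meta: str | Path) -> None:
    """Write a template as FASTA plus a YAML sidecar.

    The sidecar records ``cleavage_site`` and ``degenerate_positions``
    as 0-based offsets into the FASTA sequence, and the linker.
    """
    write_fasta([(template.name, template.sequence)], fasta)
    with open(meta, "w") as fh:
        yaml.safe_dump(
            {
                "name": template.name,
                "cleavage_site": template.cleavage_site,
                "degenerate_positions": list(template.degenerate_positions),
                "linker": template.linker,
                "coordinates": "0-based",
            },
            fh,
        )


def load_template(fasta: str | Path, meta: str | Path) -> AmpliconTemplate:
    records = read_fasta(fasta)
    if len(records) != 1:
        raise TemplateError(f"expected exactly one template record in {fasta}")
    name, seq = records[0]
    with open(meta) as fh:
        info = yaml.safe_load(fh)
    tpl = AmpliconTemplate(
        name=info.get("name", name),
        sequence=seq,
        cleavage_site=int(info["cleavage_site"]),
        linker=info.get("linker", ""),
    )
    declared = info.get("degenerate_positions")
    if declared is not None and tuple(declared) != tpl.degenerate_positions:
        raise TemplateError(
            "degenerate_positions in sidecar do not match the FASTA sequence"
        )
    return tpl
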