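"""Synthetic twister-style library fixture.

The sequences here are a SYNTHETIC stand-in construct, generated once
(seed 20193) to match the documented architecture of a self-cleaving
twister ribozyme screening library, not the published oligonucleotides:

* transcript = 5-nt leader + 54-nt ribozyme body, starting with GG so
  that the GGG anchor of the template-switching oligo produces a
  five-guanosine homopolymer at the beginning of every uncleaved read;
* cleavage site at offset 5 (the leader is lost from cleaved products);
* six fully randomized (N) positions in two distal 3-nt blocks — the
  two halves of the T1 pseudoknot — giving 4^6 = 4096 genotypes, with
  wild-type genotype CCCGGG (three consecutive C-G pairs);
* a fixed 25-nt 3' linker (reverse-transcription primer site) and a
  60-nt adapter stub that 150-cycle reads run into;
* four phased inserts of 9/12/15/18 nt, column-balanced over the first
  nine cycles and mixed in equal proportions, generated by the design
  module from a fixed seed.
"""

from __future__ import annotations

from .design import DesignConstraints, design_phased_inserts
from .seqmodel import AmpliconTemplate, PhasedInsertSet, ReadLayout

__all__ = [
    "REFERENCE_GENOTYPE",
    "twister_template",
    "twister_insert_set",
    "twister_layout",
    "reduced_template",
]

_TRANSCRIPT = "GGCATTGGGCTATNNNCGACCTATTCGCCATGACGGTTCAAGTGCNNNACTCGCAACGG"
_CLEAVAGE_SITE = 5
_LINKER = "ACAATGACGCCAGACTACCACTCCA"
_ADAPTER_STUB = "CATCGCTCATGGCAATGGTAGGGTATCTTTGAATCAGGGTGTGCGTGAGCCACTGTACGA"
_INSERT_SEED = 20193

#: Wild-type bases at the six randomized pseudoknot positions.
REFERENCE_GENOTYPE = "CCCGGG"


def twister_template() -> AmpliconTemplate:
    """The synthetic twister-style construct (6 N positions, 4096 genotypes)."""
    return AmpliconTemplate(
        name="twister-synthetic",
        sequence=_TRANSCRIPT,
        cleavage_site=_CLEAVAGE_SITE,
        linker=_LINKER,
    )


def twister_insert_set() -> PhasedInsertSet:
    """Four balanced phased inserts (9/12/15/18 nt), equal proportions."""
    return design_phased_inserts(DesignConstraints(seed=_INSERT_SEED))


def twister_layout(read_length: int = 150) -> ReadLayout:
    """Single-end layout: 150 cycles, padding into the adapter stub."""
    return ReadLayout(read_length=read_length, adapter_stub=_ADAPTER_STUB)


def reduced_template(n_positions: int = 2) -> AmpliconTemplate:
    """A reduced-diversity variant for fast end-to-end checks.

    Keeps the first ``n_positions`` randomized sites (alternating
    between the two pseudoknot halves) and fixes the rest to their
    wild-type base, shrinking the genotype space from 4096 to
    4**n_positions without changing the read architecture.
    """
    full = twister_template()
    if not 1 <= n_positions <= 6:
        raise ValueError("n_positions must be in 1..6")
    # order sites so both halves stay represented at n_positions >= 2
    order = [0, 3, 1, 4, 2, 5]
    keep = {full.degenerate_positions[i] for i in order[:n_positions]}
    seq = list(full.sequence)
    for gi, pos in enumerate(full.degenerate_positions):
        if pos not in keep:
            seq[pos] = REFERENCE_GENOTYPE[gi]
    return AmpliconTemplate(
        name=f"twister-synthetic-{n_positions}N",
        sequence="".join(seq),
        cleavage_site=full.cleavage_site,
        linker=full.linker,
    )
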