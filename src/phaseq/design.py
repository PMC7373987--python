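"""Design of column-balanced phased insert sets.

A phased insert set restores per-cycle base diversity in a low-diversity
library by shifting otherwise identical reads out of register.  Within
the balance window (by default the shortest insert length) the inserts
are designed so that, column by column, each canonical base occupies
exactly k/4 of the k inserts; an equal-proportion mixture of such a set
then has the maximum positional entropy of 2 bits at every windowed
cycle.  Tail cycles of the longer inserts only need diversity, not exact
balance, so they are filled greedily with mutually distinct bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqmodel import DNA_BASES, PhasedInsertSet

__all__ = ["DesignConstraints", "DesignError", "design_phased_inserts", "validate_balance"]


class DesignError(RuntimeError):
    """Raised when no insert set satisfies the constraints."""


@dataclass(frozen=True)
class DesignConstraints:
    """Constraints for :func:`design_phased_inserts`.

    lengths
        Distinct insert lengths, strictly increasing.  Default
        ``(9, 12, 15, 18)``; the number of inserts must be a multiple of
        four for exact column balance.
    balance_window
        Cycles over which columns must be exactly balanced; defaults to
        the shortest insert length.
    max_homopolymer
        Longest run allowed within any single insert.
    forbidden_prefixes / forbidden_suffixes
        Sequences disallowed at insert boundaries.  The default suffix
        "G" keeps an insert from extending the downstream GGG anchor
        into a longer homopolymer.
    """

    lengths: tuple[int, ...] = (9, 12, 15, 18)
    balance_window: int | None = None
    max_homopolymer: int = 2
    forbidden_prefixes: tuple[str, ...] = ()
    forbidden_suffixes: tuple[str, ...] = ("G",)
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if len(self.lengths) < 4 or len(self.lengths) % 4:
            raise DesignError(
                "exact balance needs the number of inserts to be a "
                f"multiple of four, got {len(self.lengths)}"
            )
        if any(b <= a for a, b in zip(self.lengths, self.lengths[1:])):
            raise DesignError("insert lengths must be strictly increasing")
        window = self.balance_window
        if window is None:
            object.__setattr__(self, "balance_window", min(self.lengths))
        elif window > min(self.lengths):
            raise DesignError(
                "balance_window cannot exceed the shortest insert length"
            )


def _violates(seq: str, c: DesignConstraints, final: bool) -> bool:
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > c.max_homopolymer:
            return True
    if any(seq.startswith(p) for p in c.forbidden_prefixes):
        return True
    if final and any(seq.endswith(s) for s in c.forbidden_suffixes):
        return True
    return False


def design_phased_inserts(constraints: DesignConstraints | None = None) -> PhasedInsertSet:
    """Generate a balanced phased insert set by rejection sampling.

    Within the balance window each cycle gets a random permutation of a
    multiset holding k/4 copies of each base, assigned across the k
    inserts; tail cycles (beyond the window) assign mutually distinct
    bases to whichever inserts are still running.  Candidates violating
    homopolymer or boundary constraints are rejected and redrawn, with a
    bounded number of restarts.  Deterministic for a given seed.
    """
    c = constraints or DesignConstraints()
    rng = np.random.default_rng(c.seed)
    k = len(c.lengths)
    window = c.balance_window
    column = np.repeat(list(DNA_BASES), k // 4)

    for _ in range(c.max_attempts):
        seqs = [""] * k
        ok = True
        for cycle in range(max(c.lengths)):
            active = [i for i, L in enumerate(c.lengths) if cycle < L]
            # redraw this cycle's assignment on violation before giving up
            # on the whole candidate
            for _retry in range(64):
                if cycle < window:
                    bases = rng.permutation(column)
                else:
                    # diversity, not balance: distinct bases across tails
                    bases = rng.permutation(list(DNA_BASES))[: len(active)]
                trial = {i: seqs[i] + b for i, b in zip(active, bases)}
                if all(
                    not _violates(s, c, final=len(s) == c.lengths[i])
                    for i, s in trial.items()
                ):
                    for i, s in trial.items():
                        seqs[i] = s
                    break
            else:
                ok = False
            if not ok:
                break
        if not ok:
            continue
        try:
            return PhasedInsertSet(inserts=tuple(seqs))
        except Exception:  # prefix violation; redraw
            continue
    raise DesignError(
        f"no insert set satisfying {c} found in {c.max_attempts} attempts"
    )


@dataclass(frozen=True)
class BalanceReport:
    balanced: bool
    counts: pd.DataFrame  # per-cycle weighted base fractions
    first_violation: int | None


def validate_balance(
    inserts: PhasedInsertSet, window: int | None = None, tol: float = 1e-9
) -> BalanceReport:
    """Check column balance of an insert set over the first ``window`` cycles.

    Balanced means each base carries exactly 1/4 of the mixing weight at
    every windowed cycle (for four equal-proportion inserts: each column
    is a permutation of ACGT).
    """
    window = min(inserts.lengths) if window is None else window
    if window > min(inserts.lengths):
        raise DesignError("window exceeds the shortest insert length")
    frac = np.zeros((window, 4))
    for seq, p in zip(inserts.inserts, inserts.proportions):
        for cycle in range(window):
            frac[cycle, DNA_BASES.index(seq[cycle])] += p
    bad = np.where(np.abs(frac - 0.25).max(axis=1) > tol)[0]
    counts = pd.DataFrame(frac, columns=list(DNA_BASES))
    counts.index.name = "cycle"
    return BalanceReport(
        balanced=bad.size == 0,
        counts=counts,
        first_violation=int(bad[0]) if bad.size else None,
    )
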