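"""Assembly handling: scaffold length filtering and assembly statistics.

Short scaffolds are pruned before screening because fragments of viral
homology on tiny scaffolds are more likely to reflect assembler error
or contamination than genuine endogenization.  The assembly statistics
computed here (lengths, scaffold/contig counts and N50s) are the
genome-quality factors later correlated with per-genome element
counts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

logger = logging.getLogger(__name__)

_IUPAC_NT_RE = re.compile(r"^[ACGTUNRYSWKMBDHV]*$")

#: a run of at least this many N's splits a scaffold into contigs
DEFAULT_GAP_RUN = 10


@dataclass
class Scaffold:
    """A named nucleotide sequence from an assembly."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not _IUPAC_NT_RE.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTUNRYSWKMBDHV"))
            raise ValueError(f"scaffold {self.id}: non-IUPAC symbols {bad}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AssemblyStats:
    """The five quality factors used in the genome-quality correlation."""

    total_length: int
    n_scaffolds: int
    scaffold_n50: int
    n_contigs: int
    contig_n50: int


def filter_scaffolds(assembly: Sequence[Scaffold], min_len: int) -> list[Scaffold]:
    """Drop scaffolds shorter than ``min_len``.

    "Under min_len" is strict: a scaffold of exactly ``min_len`` bp is
    kept.  Input order is preserved.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [s for s in assembly if len(s) >= min_len]
    if not kept:
        logger.warning("scaffold filter at %d bp removed every scaffold", min_len)
    else:
        logger.info(
            "scaffold filter: kept %d/%d scaffolds (>= %d bp)",
            len(kept), len(assembly), min_len,
        )
    return kept


def n50(lengths: Sequence[int]) -> int:
    """N50: the length at which the descending cumulative sum first
    reaches half the total."""
    if not lengths:
        return 0
    total = sum(lengths)
    acc = 0
    for ln in sorted(lengths, reverse=True):
        acc += ln
        if 2 * acc >= total:
            return ln
    return 0  # pragma: no cover


def split_contigs(seq: str, gap_run: int = DEFAULT_GAP_RUN) -> list[str]:
    """Split a scaffold into contigs at runs of >= ``gap_run`` N's."""
    return [c for c in re.split("N{%d,}" % gap_run, seq) if c]


def assembly_stats(assembly: Sequence[Scaffold], gap_run: int = DEFAULT_GAP_RUN) -> AssemblyStats:
    """Compute scaffold and contig statistics for an assembly.

    Contigs are defined by splitting each scaffold at runs of at least
    ``gap_run`` consecutive N's (the common assembler gap convention).
    """
    if not assembly:
        raise ValueError("assembly_stats requires a non-empty assembly")
    slens = [len(s) for s in assembly]
    clens = [len(c) for s in assembly for c in split_contigs(s.seq, gap_run)]
    return AssemblyStats(
        total_length=sum(slens),
        n_scaffolds=len(slens),
        scaffold_n50=n50(slens),
        n_contigs=len(clens),
        contig_n50=n50(clens),
    )
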