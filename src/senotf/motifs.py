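"""Degenerate IUPAC motifs and exact (no-mismatch) promoter scanning.

Transcription factor binding sites are short, degenerate DNA words.  Here a
motif is an IUPAC string (e.g. ``TTTSSCGC`` for the E2F site), attached to the
gene encoding the transcription factor that binds it.  The number of concrete
A/C/G/T words matching a motif (its *variant count*) is the product of the
per-position code degeneracies; motifs with fewer than ``max_variants``
(default 1,000) variants are *eligible* for scanning — highly degenerate
patterns match almost everywhere and carry no positional information.

Scanning is exact: a promoter position matches iff every sequence base lies in
the corresponding code's base set.  An ``N`` in the *sequence* (a masked base)
matches nothing.  By default both strands are searched (a binding site is a
double-stranded feature) by additionally matching the reverse complement of
the pattern on the forward sequence; identical intervals arising from
palindromic patterns are reported once.  Coordinates are 0-based, half-open.
"""

from __future__ import annotations

import functools
import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, NamedTuple

import pandas as pd

#: IUPAC nucleotide codes mapped to the set of concrete bases they denote.
IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: Complement of each IUPAC code (complement of the base set).
IUPAC_COMPLEMENT: Mapping[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

DEFAULT_MAX_VARIANTS = 1000


class MotifError(ValueError):
    """Invalid IUPAC pattern or disallowed motif operation."""


def variant_count(pattern: str) -> int:
    """Number of concrete A/C/G/T strings matching ``pattern``.

    The product over positions of the degeneracy of each IUPAC code
    (A/C/G/T → 1, two-base codes → 2, three-base codes → 3, N → 4).

    Raises
    ------
    MotifError
        If the pattern is empty or contains a non-IUPAC character (the error
        names the offending position and character).
    """
    if not pattern:
        raise MotifError("empty motif pattern")
    n = 1
    for i, char in enumerate(pattern):
        bases = IUPAC_CODES.get(char)
        if bases is None:
            raise MotifError(
                f"invalid IUPAC code {char!r} at position {i} in pattern {pattern!r}"
            )
        n *= len(bases)
    return n


def reverse_complement(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (degeneracy-preserving)."""
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(pattern))
    except KeyError as exc:  # pragma: no cover - guarded by variant_count upstream
        raise MotifError(f"invalid IUPAC code {exc.args[0]!r} in {pattern!r}") from exc


@dataclass(frozen=True)
class IUPACMotif:
    """A degenerate binding motif attached to its transcription factor gene."""

    tf_gene_id: str
    pattern: str

    def __post_init__(self) -> None:
        variant_count(self.pattern)  # validates
        object.__setattr__(self, "pattern", self.pattern.upper())

    @property
    def variant_count(self) -> int:
        return variant_count(self.pattern)

    def is_eligible(self, max_variants: int = DEFAULT_MAX_VARIANTS) -> bool:
        """Strictly fewer variants than ``max_variants``."""
        return self.variant_count < max_variants

    @property
    def key(self) -> str:
        """Column key used in occurrence matrices and reports."""
        return f"{self.tf_gene_id}:{self.pattern}"

    def __len__(self) -> int:
        return len(self.pattern)


def expand_variants(
    motif: IUPACMotif | str, max_variants: int = DEFAULT_MAX_VARIANTS
) -> set[str]:
    """All concrete sequences matching the motif; cardinality = variant count.

    Refuses ineligible motifs to guard against combinatorial blow-up.
    """
    pattern = motif.pattern if isinstance(motif, IUPACMotif) else pattern_upper(motif)
    n = variant_count(pattern)
    if n >= max_variants:
        raise MotifError(
            f"motif {pattern!r} has {n} variants (>= {max_variants}); refusing to expand"
        )
    return {"".join(p) for p in itertools.product(*(IUPAC_CODES[c] for c in pattern))}


def pattern_upper(pattern: str) -> str:
    return pattern.upper()


class Match(NamedTuple):
    """A motif occurrence: 0-based half-open interval and strand."""

    start: int
    end: int
    strand: str


@functools.lru_cache(maxsize=4096)
def _compiled(pattern: str) -> re.Pattern[str]:
    # Lookahead so overlapping occurrences are all reported; sequence 'N'
    # never appears in any class, so masked bases match nothing.
    body = "".join(f"[{IUPAC_CODES[c]}]" for c in pattern)
    return re.compile(f"(?=({body}))")


def scan(
    sequence: str,
    motif: IUPACMotif | str,
    strand_mode: str = "both",
    overlap: str = "allowed",
) -> list[Match]:
    """Exact-match occurrences of ``motif`` in ``sequence``.

    Parameters
    ----------
    sequence
        Uppercase nucleotide string over {A,C,G,T,N}.
    strand_mode
        ``"forward"`` or ``"both"``.  In both-strand mode the reverse
        complement of the pattern is additionally matched on the forward
        sequence; duplicate intervals (palindromes) are reported once, with
        strand ``"+"``.
    overlap
        ``"allowed"`` reports every occurrence; ``"disallowed"`` keeps a
        greedy left-to-right non-overlapping subset.

    A motif longer than the sequence yields zero matches (not an error).
    """
    pattern = motif.pattern if isinstance(motif, IUPACMotif) else motif.upper()
    variant_count(pattern)  # validate
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if overlap not in ("allowed", "disallowed"):
        raise ValueError(f"unknown overlap policy {overlap!r}")
    m = len(pattern)
    hits: dict[int, str] = {}
    for s in _compiled(pattern).finditer(sequence):
        hits[s.start()] = "+"
    if strand_mode == "both":
        rc = reverse_complement(pattern)
        for s in _compiled(rc).finditer(sequence):
            hits.setdefault(s.start(), "-")  # palindrome dedup: '+' wins
    matches = [Match(start, start + m, strand) for start, strand in sorted(hits.items())]
    if overlap == "disallowed":
        kept: list[Match] = []
        last_end = -1
        for hit in matches:
            if hit.start >= last_end:
                kept.append(hit)
                last_end = hit.end
        matches = kept
    return matches


class PromoterCollection:
    """Named upstream sequences keyed by gene identifier.

    Sequences are uppercase over {A,C,G,T,N}; ids are unique and sequences
    nonempty.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._sequences: dict[str, str] = {}
        for gene_id, seq in sequences.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for promoter {gene_id!r}")
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"promoter {gene_id!r} contains non-nucleotide {bad}")
            self._sequences[str(gene_id)] = seq

    @property
    def ids(self) -> list[str]:
        return list(self._sequences)

    def __getitem__(self, gene_id: str) -> str:
        return self._sequences[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._sequences

    def __len__(self) -> int:
        return len(self._sequences)

    def __iter__(self) -> Iterator[str]:
        return iter(self._sequences)

    def items(self) -> Iterable[tuple[str, str]]:
        return self._sequences.items()

    def replace(self, gene_id: str, sequence: str) -> None:
        if gene_id not in self._sequences:
            raise KeyError(gene_id)
        if len(sequence) != len(self._sequences[gene_id]):
            raise ValueError("replacement changes sequence length")
        self._sequences[gene_id] = sequence.upper()


@dataclass(frozen=True)
class ScanSettings:
    """Scanner configuration, recorded alongside every occurrence matrix."""

    strand_mode: str = "both"
    overlap: str = "allowed"
    max_variants: int = DEFAULT_MAX_VARIANTS


def count_occurrences(
    promoters: PromoterCollection,
    motifs: Iterable[IUPACMotif],
    settings: ScanSettings = ScanSettings(),
) -> pd.DataFrame:
    """Per-promoter, per-motif exact match counts.

    Returns a genes × motifs integer DataFrame (index = gene ids, columns =
    motif keys).  All motifs must be eligible under ``settings.max_variants``.
    An empty motif list yields an empty matrix with the promoter index.
    """
    motifs = list(motifs)
    for motif in motifs:
        if not motif.is_eligible(settings.max_variants):
            raise MotifError(
                f"motif {motif.key} has {motif.variant_count} variants "
                f"(>= {settings.max_variants}); filter before scanning"
            )
    counts = {
        motif.key: [
            len(scan(seq, motif, settings.strand_mode, settings.overlap))
            for _, seq in promoters.items()
        ]
        for motif in motifs
    }
    return pd.DataFrame(counts, index=pd.Index(promoters.ids, name="gene_id"), dtype=int)


def match_table(
    promoters: PromoterCollection,
    motifs: Iterable[IUPACMotif],
    settings: ScanSettings = ScanSettings(),
) -> pd.DataFrame:
    """BED-like table of individual matches: gene_id, start, end, strand, motif."""
    rows = []
    for motif in motifs:
        for gene_id, seq in promoters.items():
            for hit in scan(seq, motif, settings.strand_mode, settings.overlap):
                rows.append((gene_id, hit.start, hit.end, hit.strand, motif.key))
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand", "motif"])
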