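"""IUPAC degenerate-base algebra, codon expansion and amino-acid profiles.

A degenerate codon is a position-wise mixture of bases synthesized as a
single oligonucleotide: each of its three positions carries one of the 15
IUPAC ambiguity symbols (A, C, G, T, R, Y, S, W, K, M, B, D, H, V, N), so a
mixture expands to between 1 and 64 concrete codons.  Translating the
expansion under the standard genetic code gives the mixture's amino-acid
multiplicity profile — how many of its codons encode each amino acid (and
stop, written '*') — which is the quantity every downstream design and QC
step consumes.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, FrozenSet, Mapping, Set, Tuple

from Bio.Data import CodonTable
from Bio.Data.IUPACData import ambiguous_dna_complement, ambiguous_dna_values

#: The 15 IUPAC nucleotide ambiguity symbols, alphabetically.  This is the
#: canonical symbol order used wherever mixtures are enumerated or sorted.
IUPAC_SYMBOLS: str = "ABCDGHKMNRSTVWY"

# Bio's table also carries the legacy 'X' alias for N; restrict to the 15.
_BASE_SETS: Dict[str, FrozenSet[str]] = {
    sym: frozenset(ambiguous_dna_values[sym]) for sym in IUPAC_SYMBOLS
}
_COMPLEMENT: Dict[str, str] = {
    sym: ambiguous_dna_complement[sym] for sym in IUPAC_SYMBOLS
}

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
STOP: str = "*"


class InvalidAlphabetError(ValueError):
    """A character is not a valid IUPAC nucleotide symbol."""


@dataclass(frozen=True)
class DegenerateBase:
    """One IUPAC ambiguity symbol and the base subset it denotes."""

    symbol: str
    base_set: FrozenSet[str]

    def __post_init__(self) -> None:
        if self.symbol not in _BASE_SETS:
            raise InvalidAlphabetError(
                f"invalid IUPAC nucleotide symbol: {self.symbol!r}"
            )
        if self.base_set != _BASE_SETS[self.symbol]:
            raise ValueError(
                f"base set {set(self.base_set)} does not match symbol "
                f"{self.symbol!r} (expected {set(_BASE_SETS[self.symbol])})"
            )

    def __len__(self) -> int:
        return len(self.base_set)


@dataclass(frozen=True)
class DegenerateCodon:
    """Three degenerate bases; expands to ``codon_count`` concrete codons."""

    positions: Tuple[DegenerateBase, DegenerateBase, DegenerateBase]

    def __post_init__(self) -> None:
        if len(self.positions) != 3:
            raise ValueError("a codon has exactly three positions")

    @classmethod
    def from_string(cls, code: str) -> "DegenerateCodon":
        if len(code) != 3:
            raise ValueError(f"degenerate codon must be 3 symbols, got {code!r}")
        return cls(tuple(parse_iupac(c) for c in code))  # type: ignore[arg-type]

    @property
    def code(self) -> str:
        """Upper-case three-symbol IUPAC string."""
        return "".join(p.symbol for p in self.positions)

    @property
    def codon_count(self) -> int:
        n = 1
        for p in self.positions:
            n *= len(p)
        return n


@dataclass(frozen=True)
class CodonProfile:
    """Amino-acid multiplicities of one degenerate codon mixture.

    ``multiplicities[a]`` is the number of concrete codons in the expansion
    that translate to amino acid ``a`` ('*' for stop); the values sum to
    ``codon_count``.
    """

    multiplicities: Mapping[str, int]
    codon_count: int

    def __post_init__(self) -> None:
        total = sum(self.multiplicities.values())
        if total != self.codon_count:
            raise ValueError(
                f"multiplicities sum to {total}, expected {self.codon_count}"
            )
        if any(m < 1 for m in self.multiplicities.values()):
            raise ValueError("all multiplicities must be >= 1")

    @property
    def stop_count(self) -> int:
        return self.multiplicities.get(STOP, 0)

    @property
    def amino_acids(self) -> Set[str]:
        return set(self.multiplicities)


@dataclass(frozen=True)
class GeneticCode:
    """Total map from the 64 concrete codons to amino acids and stop."""

    table: Mapping[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError("genetic code must map all 64 codons")
        stops = [c for c, a in self.table.items() if a == STOP]
        if len(stops) != 3:
            raise ValueError("standard-style code must have 3 stop codons")

    def __getitem__(self, codon: str) -> str:
        return self.table[codon]


def _standard_code() -> GeneticCode:
    ncbi = CodonTable.unambiguous_dna_by_id[1]
    table = dict(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        table[stop] = STOP
    return GeneticCode(table=table)


#: The standard genetic code (NCBI translation table 1).
STANDARD_CODE: GeneticCode = _standard_code()


def _normalize(seq: str) -> str:
    """Upper-case and map U (dU chemistry) to T."""
    return seq.upper().replace("U", "T")


def parse_iupac(symbol: str) -> DegenerateBase:
    """Return the :class:`DegenerateBase` for one IUPAC symbol.

    Case-insensitive; ``U`` is accepted as a synonym for ``T``.
    """
    if not isinstance(symbol, str) or len(symbol) != 1:
        raise InvalidAlphabetError(f"expected a single character, got {symbol!r}")
    sym = _normalize(symbol)
    if sym not in _BASE_SETS:
        raise InvalidAlphabetError(f"invalid IUPAC nucleotide symbol: {symbol!r}")
    return DegenerateBase(symbol=sym, base_set=_BASE_SETS[sym])


def base_set(symbol: str) -> FrozenSet[str]:
    """Shorthand: the concrete-base subset of one IUPAC symbol."""
    return parse_iupac(symbol).base_set


def expand_degenerate_codon(codon: "DegenerateCodon | str") -> Set[str]:
    """All concrete codons in the mixture (Cartesian product of base sets)."""
    if isinstance(codon, str):
        codon = DegenerateCodon.from_string(codon)
    return {
        "".join(bases)
        for bases in itertools.product(*(sorted(p.base_set) for p in codon.positions))
    }


def translate(codon: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate one concrete codon; stop codons return '*'."""
    c = _normalize(codon)
    if len(c) != 3 or any(b not in "ACGT" for b in c):
        raise InvalidAlphabetError(
            f"translate requires a concrete ACGT 3-mer, got {codon!r}"
        )
    return code[c]


@lru_cache(maxsize=4096)
def _profile_standard(code: str) -> CodonProfile:
    counts = Counter(translate(c) for c in expand_degenerate_codon(code))
    return CodonProfile(multiplicities=dict(counts), codon_count=sum(counts.values()))


def profile(
    codon: "DegenerateCodon | str", code: GeneticCode = STANDARD_CODE
) -> CodonProfile:
    """Amino-acid multiplicity profile of a degenerate codon mixture.

    The multiplicity of amino acid ``a`` equals the number of expanded
    concrete codons translating to ``a``; stops are tallied under '*'.
    """
    if isinstance(codon, DegenerateCodon):
        codon = codon.code
    codon = _normalize(codon)
    DegenerateCodon.from_string(codon)  # validate
    if code is STANDARD_CODE:
        return _profile_standard(codon)
    counts = Counter(translate(c, code) for c in expand_degenerate_codon(codon))
    return CodonProfile(multiplicities=dict(counts), codon_count=sum(counts.values()))


def reverse_complement(seq: str) -> str:
    """Reverse-complement a (possibly degenerate) DNA string.

    Each IUPAC symbol maps to the symbol of its complemented base set
    (A<->T, C<->G, R<->Y, K<->M, B<->V, D<->H; S, W, N are self-
    complementary).  Output is upper case.
    """
    s = _normalize(seq)
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(s))
    except KeyError as exc:
        raise InvalidAlphabetError(
            f"invalid IUPAC nucleotide symbol: {exc.args[0]!r}"
        ) from None
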