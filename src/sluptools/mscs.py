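"""Mixed Synthesis Codon Selector (MSCS).

A conventional DNA synthesizer can put any of 15 equimolar base mixtures at
each of the three positions of a codon, so there are 15**3 = 3375 possible
degenerate codon mixtures.  Given a weighted list of amino acids the user
wants encoded, every mixture is evaluated — which requested amino acids it
encodes and how many times, which are missing, which unrequested amino acids
ride along, and how many stop codons it contains — scored, and ranked.

Scoring
-------
For a request with weights ``w_a`` (in [-1, 1]) and a mixture whose profile
gives multiplicity ``m_a`` to amino acid ``a``::

    score = sum(w_a for requested a with m_a >= 1)
            - penalty_missing * sum(w_a for requested a with m_a == 0 and w_a > 0)
            - penalty_extra   * extra_codon_mass / codon_count
            - penalty_stop    * stop_count

where ``extra_codon_mass`` is the summed multiplicity of unrequested amino
acids.  Negative-weight amino acids lower the score when encoded and incur
no missing penalty.  The extra term is the fraction of the mixture's codons
wasted on unrequested amino acids, so it is scale-free in library size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from sluptools.genetic_code import (
    AMINO_ACIDS,
    IUPAC_SYMBOLS,
    STOP,
    CodonProfile,
    DegenerateCodon,
    profile,
)

#: Default penalty for a requested, positively weighted amino acid that a
#: mixture fails to encode.
DEFAULT_PENALTY_MISSING = 1.0
#: Default penalty weight on the fraction of codons spent on unrequested
#: amino acids (extras dilute a library but do not break it).
DEFAULT_PENALTY_EXTRA = 0.5
#: Default penalty per stop codon in the mixture (a stop truncates the
#: protein, the most harmful outcome).
DEFAULT_PENALTY_STOP = 2.0


@dataclass(frozen=True)
class Request:
    """A weighted amino-acid wish list plus penalty parameters."""

    wanted: Tuple[Tuple[str, float], ...]
    penalty_missing: float = DEFAULT_PENALTY_MISSING
    penalty_extra: float = DEFAULT_PENALTY_EXTRA
    penalty_stop: float = DEFAULT_PENALTY_STOP

    def __post_init__(self) -> None:
        if not self.wanted:
            raise ValueError("request must name at least one amino acid")
        seen = set()
        for aa, w in self.wanted:
            if aa not in AMINO_ACIDS:
                raise ValueError(f"unknown amino acid {aa!r}")
            if aa in seen:
                raise ValueError(f"duplicate amino acid {aa!r} in request")
            seen.add(aa)
            if not -1.0 <= w <= 1.0:
                raise ValueError(f"weight for {aa} must be in [-1, 1], got {w}")
        for name in ("penalty_missing", "penalty_extra", "penalty_stop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_lists(
        cls,
        amino_acids: Sequence[str],
        weights: Sequence[float] | None = None,
        **penalties: float,
    ) -> "Request":
        aas = [a.upper() for a in amino_acids]
        if weights is None:
            weights = [1.0] * len(aas)
        if len(weights) != len(aas):
            raise ValueError("one weight per amino acid is required")
        return cls(wanted=tuple(zip(aas, (float(w) for w in weights))), **penalties)

    @property
    def amino_acids(self) -> Tuple[str, ...]:
        return tuple(a for a, _ in self.wanted)

    @property
    def weights(self) -> Dict[str, float]:
        return dict(self.wanted)


@dataclass(frozen=True)
class MixtureEvaluation:
    """One degenerate codon mixture judged against a request."""

    code: str
    profile: CodonProfile = field(repr=False)
    encoded: Dict[str, int]
    missing: Tuple[str, ...]
    extra: Dict[str, int]
    stop_count: int
    codon_count: int
    n_encoded: int
    n_requested: int
    score: float

    @property
    def extra_codon_mass(self) -> int:
        return sum(self.extra.values())


def enumerate_all_mixtures() -> List[DegenerateCodon]:
    """All 3375 degenerate codon mixtures, in lexicographic symbol order.

    Symbols are ordered alphabetically (A B C D G H K M N R S T V W Y); the
    list is the Cartesian cube of that order, so it is deterministic.
    """
    return [
        DegenerateCodon.from_string("".join(symbols))
        for symbols in itertools.product(IUPAC_SYMBOLS, repeat=3)
    ]


def score_mixture(prof: CodonProfile, request: Request) -> float:
    """Apply the default scoring formula to one profile (see module docs)."""
    weights = request.weights
    m = prof.multiplicities
    encoded_term = sum(w for a, w in weights.items() if m.get(a, 0) >= 1)
    missing_term = sum(
        w for a, w in weights.items() if m.get(a, 0) == 0 and w > 0
    )
    extra_mass = sum(
        mult for a, mult in m.items() if a not in weights and a != STOP
    )
    return (
        encoded_term
        - request.penalty_missing * missing_term
        - request.penalty_extra * extra_mass / prof.codon_count
        - request.penalty_stop * prof.stop_count
    )


def evaluate_mixture(code: "str | DegenerateCodon", request: Request) -> MixtureEvaluation:
    """Evaluate one degenerate codon mixture against a request."""
    if isinstance(code, DegenerateCodon):
        code = code.code
    prof = profile(code)
    weights = request.weights
    m = prof.multiplicities
    encoded = {a: m[a] for a in request.amino_acids if m.get(a, 0) >= 1}
    missing = tuple(a for a in request.amino_acids if m.get(a, 0) == 0)
    extra = {a: mult for a, mult in m.items() if a not in weights and a != STOP}
    return MixtureEvaluation(
        code=code.upper(),
        profile=prof,
        encoded=encoded,
        missing=missing,
        extra=extra,
        stop_count=prof.stop_count,
        codon_count=prof.codon_count,
        n_encoded=len(encoded),
        n_requested=len(request.amino_acids),
        score=score_mixture(prof, request),
    )


def rank_mixtures(request: Request) -> List[MixtureEvaluation]:
    """Evaluate and sort all 3375 mixtures, best first.

    Primary key: score descending.  Ties: more requested amino acids
    encoded, then fewer codons (compactness), then less codon mass on
    unrequested amino acids, then lexicographic code.
    """
    evals = [evaluate_mixture(c, request) for c in enumerate_all_mixtures()]
    evals.sort(
        key=lambda e: (
            -e.score,
            -e.n_encoded,
            e.codon_count,
            e.extra_codon_mass,
            e.code,
        )
    )
    return evals


def _aa_count_list(counts: Dict[str, int], order: Sequence[str]) -> str:
    """Render 'A2 T2 F1 ...': multiplicity descending, ties in ``order``."""
    rank = {a: i for i, a in enumerate(order)}
    items = sorted(counts.items(), key=lambda kv: (-kv[1], rank[kv[0]]))
    return " ".join(f"{a}{n}" for a, n in items)


def format_report(ev: MixtureEvaluation, request: Request) -> str:
    """One report line for a mixture evaluation.

    Format: ``k/n Encoded: <AA+count...> Missing: <AA... or 0> Extra:
    <AA+count... or 0> Codons: <count> Code: <code lower-case>`` where k is
    the number of requested amino acids encoded and n the number requested.
    Encoded amino acids are listed by multiplicity descending, ties in
    request order; extras by multiplicity descending, ties alphabetical.
    An empty missing list renders as ``Missing:0`` (no space), an empty
    extra list as ``Extra: 0``, mirroring the original report layout.
    """
    encoded = _aa_count_list(ev.encoded, request.amino_acids) if ev.encoded else "0"
    missing = " ".join(ev.missing)
    extra = _aa_count_list(ev.extra, sorted(ev.extra))
    missing_part = f"Missing: {missing}" if ev.missing else "Missing:0"
    extra_part = f"Extra: {extra}" if ev.extra else "Extra: 0"
    return (
        f"{ev.n_encoded}/{ev.n_requested} Encoded: {encoded} {missing_part} "
        f"{extra_part} Codons: {ev.codon_count} Code: {ev.code.lower()}"
    )
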