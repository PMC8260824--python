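"""Sequencing-based library quality control.

Given reads aligned to the parent amplicon (plain-text SAM) and the library
specification, this module tallies per-reference-position A/C/G/T counts and
fractions (a pileup), summarizes the mutated regions — which bases the
mutagenic primers encode, which the template encodes, and which are
unexpected — and computes end-trimmed error statistics: at a non-mutated
position every non-template base is an error, so the mean unexpected-base
fraction over such positions is the library's per-base error rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from scipy import stats

from sluptools.library_design import LibrarySpec

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i

# CIGAR operation codes (SAM spec)
_CONSUMES_BOTH = {0, 7, 8}  # M, =, X
_CONSUMES_QUERY = {1, 4}  # I, S
_CONSUMES_REF = {2, 3}  # D, N


@dataclass(frozen=True)
class PileupColumn:
    """Base counts and fractions at one reference position.

    Depth counts aligned A/C/G/T read bases only: deletions, insertions,
    reference skips and ambiguous read bases do not contribute.
    """

    position: int
    counts: Dict[str, int]
    deletions: int = 0

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> Dict[str, float]:
        d = self.depth
        if d == 0:
            return {b: 0.0 for b in BASES}
        return {b: self.counts[b] / d for b in BASES}


def pileup_counts(
    sam_path: str,
    reference_name: Optional[str] = None,
    reference_length: Optional[int] = None,
    min_base_quality: int = 0,
    min_mapping_quality: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Count aligned read bases per reference position from a SAM file.

    Walks each read's CIGAR: M/=/X blocks contribute read bases to their
    reference columns, I/S consume query only, D/N consume reference only
    (deletions are tallied separately).  Unmapped, secondary and
    supplementary records are skipped; no quality filter is applied unless
    requested.  Returns ``(counts, deletions)`` where ``counts`` is an
    (L, 4) array over A/C/G/T and ``deletions`` a length-L array.
    """
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        names = list(sam.references)
        if reference_name is None:
            if len(names) != 1:
                raise ValueError(
                    f"SAM header names {len(names)} references; pass reference_name"
                )
            reference_name = names[0]
        elif names and reference_name not in names:
            raise ValueError(
                f"reference {reference_name!r} not in SAM header ({names})"
            )
        if reference_length is None:
            reference_length = sam.get_reference_length(reference_name)
        counts = np.zeros((reference_length, 4), dtype=np.int64)
        deletions = np.zeros(reference_length, dtype=np.int64)
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != reference_name:
                raise ValueError(
                    f"read {read.query_name} aligned to {read.reference_name!r}, "
                    f"expected {reference_name!r}"
                )
            if read.mapping_quality < min_mapping_quality:
                continue
            cigar = read.cigartuples
            seq = read.query_sequence
            if not cigar or seq is None:
                logger.warning("skipping read %s with missing CIGAR/SEQ", read.query_name)
                continue
            quals = read.query_qualities if min_base_quality > 0 else None
            codes = _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            rpos = read.reference_start
            qpos = 0
            for op, length in cigar:
                if op in _CONSUMES_BOTH:
                    block = codes[qpos : qpos + length]
                    refs = np.arange(rpos, rpos + length)
                    ok = (block != 255) & (refs >= 0) & (refs < reference_length)
                    if quals is not None:
                        q = np.asarray(quals[qpos : qpos + length])
                        ok &= q >= min_base_quality
                    np.add.at(counts, (refs[ok], block[ok].astype(np.intp)), 1)
                    rpos += length
                    qpos += length
                elif op in _CONSUMES_QUERY:
                    qpos += length
                elif op in _CONSUMES_REF:
                    if op == 2:
                        deletions[max(rpos, 0) : min(rpos + length, reference_length)] += 1
                    rpos += length
                # H (5) and P (6) consume neither
    return counts, deletions


def pileup_from_sam(
    sam_path: str,
    reference: Optional[str] = None,
    reference_name: Optional[str] = None,
    min_base_quality: int = 0,
    min_mapping_quality: int = 0,
) -> List[PileupColumn]:
    """Per-position pileup columns from aligned reads.

    ``reference`` (the template sequence) fixes the column count; without it
    the header's reference length is used.
    """
    counts, deletions = pileup_counts(
        sam_path,
        reference_name=reference_name,
        reference_length=len(reference) if reference else None,
        min_base_quality=min_base_quality,
        min_mapping_quality=min_mapping_quality,
    )
    return [
        PileupColumn(
            position=i,
            counts={b: int(counts[i, j]) for j, b in enumerate(BASES)},
            deletions=int(deletions[i]),
        )
        for i in range(counts.shape[0])
    ]


def pileup_table(columns: Sequence[PileupColumn]) -> str:
    """TSV: 1-based position, fraction of each base, total reads counted."""
    rows = ["position\tfrac_A\tfrac_C\tfrac_G\tfrac_T\treads"]
    for col in columns:
        f = col.fractions
        rows.append(
            f"{col.position + 1}\t"
            + "\t".join(f"{f[b]:.6f}" for b in BASES)
            + f"\t{col.depth}"
        )
    return "\n".join(rows) + "\n"


@dataclass(frozen=True)
class RegionSummary:
    """Observed base composition at one mutated position.

    ``expected_bases`` is the degenerate symbol's base set (what the
    mutagenic primer encodes); any observed base outside it is unexpected.
    """

    position: int
    template_base: str
    symbol: str
    expected_bases: FrozenSet[str]
    counts: Dict[str, int]
    no_coverage: bool = False

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> Dict[str, float]:
        d = self.depth
        return {b: (self.counts[b] / d if d else 0.0) for b in BASES}

    @property
    def label(self) -> str:
        """1-based report label, e.g. ``113 C > M``."""
        return f"{self.position + 1} {self.template_base} > {self.symbol}"

    def encoded_by_primer(self, base: str) -> bool:
        return base in self.expected_bases

    def encoded_by_template(self, base: str) -> bool:
        return base == self.template_base

    def render(self) -> str:
        """Human-readable composition, bases by descending fraction.

        Bases the primer does not encode are printed lower-case; the
        template-encoded base is bracketed.
        """
        f = self.fractions
        parts = []
        for b in sorted(BASES, key=lambda b: -f[b]):
            name = b if self.encoded_by_primer(b) else b.lower()
            if self.encoded_by_template(b):
                name = f"[{name}]"
            parts.append(f"{name} {100 * f[b]:.1f}%")
        return ", ".join(parts)


def summarize_regions(
    columns: Sequence[PileupColumn], spec: LibrarySpec
) -> List[RegionSummary]:
    """One summary row per mutated position of the spec."""
    by_pos = {c.position: c for c in columns}
    rows: List[RegionSummary] = []
    for pos, symbol in sorted(spec.mutated_positions().items()):
        col = by_pos.get(pos)
        counts = col.counts if col is not None else {b: 0 for b in BASES}
        from sluptools.genetic_code import base_set

        rows.append(
            RegionSummary(
                position=pos,
                template_base=spec.template[pos],
                symbol=symbol,
                expected_bases=base_set(symbol),
                counts=dict(counts),
                no_coverage=(col is None or col.depth == 0),
            )
        )
    return rows


def region_table(rows: Sequence[RegionSummary]) -> str:
    """TSV region summary with explicit encoded-by flags per base."""
    header = (
        "position\ttemplate_base\tsymbol\tbase\tfraction\tcount"
        "\tencoded_by_primer\tencoded_by_template\tno_coverage"
    )
    out = [header]
    for r in rows:
        f = r.fractions
        for b in sorted(BASES, key=lambda b: -f[b]):
            out.append(
                "\t".join(
                    [
                        str(r.position + 1),
                        r.template_base,
                        r.symbol,
                        b,
                        f"{f[b]:.6f}",
                        str(r.counts[b]),
                        str(r.encoded_by_primer(b)).lower(),
                        str(r.encoded_by_template(b)).lower(),
                        str(r.no_coverage).lower(),
                    ]
                )
            )
    return "\n".join(out) + "\n"


@dataclass(frozen=True)
class ErrorStats:
    """Unexpected-base statistics over trimmed, non-mutated positions."""

    mean_unexpected_fraction: float
    sd_unexpected_fraction: float
    mean_depth: float
    n_positions: int
    trim_5p: int
    trim_3p: int


def error_rate(
    columns: Sequence[PileupColumn],
    spec: LibrarySpec,
    trim_5p: int = 25,
    trim_3p: int = 0,
    near_exclusion: int = 0,
    population_sd: bool = True,
) -> ErrorStats:
    """Per-base error rate outside the mutated positions.

    At a non-mutated position the unexpected-base fraction is
    ``1 - fraction(template base)``.  Positions within ``trim_5p`` of the 5'
    end and ``trim_3p`` of the 3' end are dropped (sequencing artifacts
    concentrate at the ends), as are mutated positions, positions within
    ``near_exclusion`` nt of a mutated base, and zero-depth positions.
    SD is the population standard deviation over positions by default.
    """
    L = len(spec.template)
    mutated = set(spec.mutated_positions())
    excluded = set(mutated)
    if near_exclusion:
        for p in mutated:
            excluded.update(range(p - near_exclusion, p + near_exclusion + 1))
    fracs: List[float] = []
    depths: List[int] = []
    for col in columns:
        p = col.position
        if p < trim_5p or p >= L - trim_3p or p in excluded:
            continue
        if col.depth == 0:
            continue
        fracs.append(1.0 - col.fractions[spec.template[p]])
        depths.append(col.depth)
    if not fracs:
        raise ValueError("trimming and exclusion left no positions to assess")
    arr = np.asarray(fracs)
    ddof = 0 if population_sd else 1
    sd = float(arr.std(ddof=ddof)) if len(arr) > ddof else 0.0
    return ErrorStats(
        mean_unexpected_fraction=float(arr.mean()),
        sd_unexpected_fraction=sd,
        mean_depth=float(np.mean(depths)),
        n_positions=len(fracs),
        trim_5p=trim_5p,
        trim_3p=trim_3p,
    )


@dataclass(frozen=True)
class DeviationRow:
    """Observed vs equimolar-expected composition at one mutated position."""

    position: int
    symbol: str
    expected_fraction: float
    observed_fractions: Dict[str, float]
    max_abs_deviation: float
    chi_square: float
    dof: int
    p_value: float


def compare_observed_expected(
    summary: Sequence[RegionSummary], spec: LibrarySpec
) -> List[DeviationRow]:
    """Goodness of fit of observed base fractions to the equimolar design.

    For each mutated position with coverage, compares the observed counts
    over the site's expected base set with the uniform 1/|base_set|
    expectation: maximum absolute deviation of the fractions and a
    chi-square statistic with |base_set| - 1 degrees of freedom
    (descriptive; expected counts use the full column depth).
    """
    rows: List[DeviationRow] = []
    for r in summary:
        if r.depth == 0:
            continue
        bases = sorted(r.expected_bases)
        k = len(bases)
        exp_frac = 1.0 / k
        exp_count = r.depth / k
        obs = {b: r.counts[b] / r.depth for b in bases}
        chi2 = sum((r.counts[b] - exp_count) ** 2 / exp_count for b in bases)
        dof = k - 1
        p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else 1.0
        rows.append(
            DeviationRow(
                position=r.position,
                symbol=r.symbol,
                expected_fraction=exp_frac,
                observed_fractions=obs,
                max_abs_deviation=max(abs(obs[b] - exp_frac) for b in bases),
                chi_square=float(chi2),
                dof=dof,
                p_value=p,
            )
        )
    return rows
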