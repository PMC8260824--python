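"""Multi-site library specification, diversity accounting and donor primers.

A library is specified on the coding (top) strand of a template as an
ordered list of non-overlapping mutation sites, each replacing a stretch of
template bases with a degenerate sequence.  From that single object the
module computes the library's codon-level and protein-level diversity, the
expected per-position base composition (assuming equimolar base mixtures),
and the 5'-phosphorylated donor primers that introduce the variation on the
single-stranded template, including overlap checking and partitioning of
overlapping primers into separate sub-libraries.

Coordinates are 0-based, half-open on the coding strand throughout the API;
human-readable reports use 1-based positions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml
from Bio import SeqIO

from sluptools.genetic_code import (
    InvalidAlphabetError,
    base_set,
    parse_iupac,
    profile,
)

#: Flank lengths recommended for donor primers (nt on each side of the
#: mutated core).
RECOMMENDED_FLANK_RANGE = (15, 20)
#: Donor primer total lengths validated in practice; outside this range a
#: warning is attached (shortest working primer 29 nt, longest 68 nt).
VALIDATED_PRIMER_LENGTH_RANGE = (29, 68)
#: Minimum combined-flank annealing temperature for donor primers (deg C),
#: evaluated excluding the mutated core.
DEFAULT_TM_THRESHOLD = 55.0


class FrameError(ValueError):
    """A site is not a whole in-frame codon substitution."""


def _validate_degenerate(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    for ch in s:
        parse_iupac(ch)
    return s


def _validate_concrete(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = [ch for ch in s if ch not in "ACGT"]
    if bad:
        raise InvalidAlphabetError(f"{what} must be concrete A/C/G/T, found {bad[0]!r}")
    return s


@dataclass(frozen=True)
class MutationSite:
    """One altered stretch on the coding strand.

    ``reference`` is the template sequence being replaced (empty for a pure
    insertion); ``replacement`` is the degenerate sequence written in its
    place (empty for a deletion).  ``start`` is 0-based; the site occupies
    the half-open interval [start, start + len(reference)).
    """

    start: int
    reference: str
    replacement: str
    label: str = ""
    in_frame_codon: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("site start must be >= 0")
        object.__setattr__(
            self, "reference", _validate_concrete(self.reference, "site reference")
        )
        object.__setattr__(
            self,
            "replacement",
            _validate_degenerate(self.replacement, "site replacement"),
        )
        if not self.reference and not self.replacement:
            raise ValueError("site must have a reference and/or a replacement")

    @property
    def end(self) -> int:
        return self.start + len(self.reference)

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)

    @property
    def n_expansions(self) -> int:
        """Number of concrete sequences the replacement expands to."""
        n = 1
        for ch in self.replacement:
            n *= len(base_set(ch))
        return n

    def is_codon_substitution(self, frame_offset: int) -> bool:
        return (
            len(self.reference) == 3
            and len(self.replacement) == 3
            and (self.start - frame_offset) % 3 == 0
        )


@dataclass(frozen=True)
class LibrarySpec:
    """Coding-strand template plus ordered, non-overlapping mutation sites."""

    template: str
    sites: Tuple[MutationSite, ...] = ()
    frame_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "template", _validate_concrete(self.template, "template")
        )
        sites = tuple(sorted(self.sites, key=lambda s: s.start))
        object.__setattr__(self, "sites", sites)
        if not 0 <= self.frame_offset < max(len(self.template), 1):
            raise ValueError("frame_offset must lie within the template")
        prev_end = -1
        for site in sites:
            if site.end > len(self.template):
                raise ValueError(f"site {site.label or site.start} exceeds template")
            if self.template[site.start : site.end] != site.reference:
                raise ValueError(
                    f"site at {site.start}: reference {site.reference!r} does not "
                    f"match template "
                    f"{self.template[site.start:site.end]!r}"
                )
            if site.start < prev_end:
                raise ValueError("mutation sites overlap")
            prev_end = max(prev_end, site.end)

    # -- serialization ----------------------------------------------------

    @classmethod
    def from_dict(cls, d: Dict, template: Optional[str] = None) -> "LibrarySpec":
        if template is None:
            tf = d.get("template_file")
            if tf is not None:
                template = read_template_fasta(tf)
            else:
                template = d["template"]
        sites = tuple(
            MutationSite(
                start=int(s["start"]),
                reference=s.get("reference", ""),
                replacement=s.get("replacement", ""),
                label=s.get("label", ""),
            )
            for s in d.get("sites", [])
        )
        return cls(
            template=template, sites=sites, frame_offset=int(d.get("frame_offset", 0))
        )

    @classmethod
    def from_file(cls, path: "str | Path", template: Optional[str] = None) -> "LibrarySpec":
        """Load a spec from YAML or JSON (extension-sniffed, YAML default)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            d = json.loads(text)
        else:
            d = yaml.safe_load(text)
        if template is None and "template_file" in d:
            tf = Path(d["template_file"])
            if not tf.is_absolute():
                tf = path.parent / tf
            template = read_template_fasta(tf)
        return cls.from_dict(d, template=template)

    def to_dict(self, include_template: bool = True) -> Dict:
        d: Dict = {
            "frame_offset": self.frame_offset,
            "sites": [
                {
                    "start": s.start,
                    "reference": s.reference,
                    "replacement": s.replacement,
                    "label": s.label,
                }
                for s in self.sites
            ],
        }
        if include_template:
            d["template"] = self.template
        return d

    def mutated_positions(self) -> Dict[int, str]:
        """Map template position -> degenerate symbol, for same-length sites.

        Insertion/deletion sites contribute only the overlapping aligned
        prefix (positions past the shorter of reference/replacement are not
        position-wise comparable and are omitted).
        """
        out: Dict[int, str] = {}
        for site in self.sites:
            for i in range(min(len(site.reference), len(site.replacement))):
                out[site.start + i] = site.replacement[i]
        return out


def read_template_fasta(path: "str | Path") -> str:
    """Read a single-record FASTA template (coding strand)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record in {path}, got {len(records)}")
    return _validate_concrete(str(records[0].seq), "template")


# -- diversity accounting --------------------------------------------------


def codon_diversity(spec: LibrarySpec) -> int:
    """Number of distinct DNA sequences in the library (exact integer).

    Product over sites of the number of concrete expansions of each
    replacement; 1 for a spec with no sites.
    """
    n = 1
    for site in spec.sites:
        n *= site.n_expansions
    return n


def protein_diversity(spec: LibrarySpec) -> int:
    """Number of distinct encoded protein sequences (exact integer).

    Product over sites of the number of distinct amino acids (stop included
    when encoded) in each site's codon profile.  Every site must substitute
    exactly one whole in-frame codon.
    """
    n = 1
    for site in spec.sites:
        if not site.is_codon_substitution(spec.frame_offset):
            raise FrameError(
                f"site {site.label or site.start} is not a whole in-frame codon "
                "substitution; protein-level diversity is undefined for it"
            )
        n *= len(profile(site.replacement).multiplicities)
    return n


def variant_count(
    protein_length: int, alternatives_per_site: int, n_sites_changed: int
) -> int:
    """Number of distinct n-site protein variants: C(L, n) * k**n.

    With 19 alternative amino acids per site, a 100-residue protein has
    C(100,1) * 19 = 1900 single-site variants.
    """
    if protein_length <= 0 or alternatives_per_site <= 0 or n_sites_changed < 0:
        raise ValueError("arguments must be positive (n_sites_changed >= 0)")
    if n_sites_changed > protein_length:
        raise ValueError("cannot change more sites than the protein has")
    return math.comb(protein_length, n_sites_changed) * (
        alternatives_per_site**n_sites_changed
    )


def expected_base_fractions(spec: LibrarySpec) -> Dict[int, Dict[str, float]]:
    """Expected A/C/G/T fraction at every template position.

    Non-mutated positions carry the template base at fraction 1; a mutated
    position spreads 1/|base_set| over each base of its degenerate symbol
    (equimolar synthesis assumption).
    """
    mutated = spec.mutated_positions()
    out: Dict[int, Dict[str, float]] = {}
    for pos, tbase in enumerate(spec.template):
        fracs = {b: 0.0 for b in "ACGT"}
        sym = mutated.get(pos)
        if sym is None:
            fracs[tbase] = 1.0
        else:
            bases = base_set(sym)
            for b in bases:
                fracs[b] = 1.0 / len(bases)
        out[pos] = fracs
    return out


# -- donor primers ---------------------------------------------------------


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 4*(G+C) + 2*(A+T) deg C."""
    s = _validate_concrete(seq, "Tm sequence")
    gc = sum(1 for b in s if b in "GC")
    return 4.0 * gc + 2.0 * (len(s) - gc)


@dataclass(frozen=True)
class DonorPrimer:
    """Coding-sense mutagenic oligo: template-exact flanks around a core.

    Donor primers anneal to the retained bottom-strand ssDNA template, so
    their sequence equals the coding strand over their footprint (with the
    degenerate core in place of the reference bases).  They carry a 5'
    phosphate, required for the ligation step.
    """

    sequence: str
    interval: Tuple[int, int]
    left_flank_len: int
    right_flank_len: int
    flank_tm: float
    phosphorylated_5p: bool = True
    label: str = ""
    warnings: Tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerSet:
    """An end primer plus the donor primers of one synthesis reaction."""

    donors: Tuple[DonorPrimer, ...]
    end_primer: Optional[str] = None


def design_donor_primer(
    spec: LibrarySpec,
    site: MutationSite,
    min_flank: int = RECOMMENDED_FLANK_RANGE[0],
    max_flank: int = RECOMMENDED_FLANK_RANGE[1],
    tm_threshold: float = DEFAULT_TM_THRESHOLD,
) -> DonorPrimer:
    """Design the coding-sense donor primer for one mutation site.

    Flanks start at ``min_flank`` nt on each side and grow one base at a
    time (shorter side first; left first on ties) until the Wallace Tm of
    the combined flanks — the mutated core is excluded from the Tm — reaches
    ``tm_threshold`` or both flanks hit ``max_flank``.  If the threshold is
    unreachable the primer is still returned, with a warning.  Warnings are
    also attached for flank lengths outside the recommended 15-20 nt and
    total lengths outside the validated 29-68 nt range.
    """
    if min_flank < 1 or max_flank < min_flank:
        raise ValueError("need 1 <= min_flank <= max_flank")
    template = spec.template
    if site.start < min_flank or len(template) - site.end < min_flank:
        raise ValueError(
            f"site at {site.start} is too close to the template edge for "
            f"{min_flank} nt flanks"
        )
    left = right = min_flank
    max_left = min(max_flank, site.start)
    max_right = min(max_flank, len(template) - site.end)

    def flanks(l: int, r: int) -> Tuple[str, str]:
        return template[site.start - l : site.start], template[site.end : site.end + r]

    while wallace_tm("".join(flanks(left, right))) < tm_threshold and (
        left < max_left or right < max_right
    ):
        if (left <= right and left < max_left) or right >= max_right:
            left += 1
        else:
            right += 1

    lf, rf = flanks(left, right)
    tm = wallace_tm(lf + rf)
    sequence = lf + site.replacement + rf
    warnings: List[str] = []
    if tm < tm_threshold:
        warnings.append(
            f"combined-flank Tm {tm:.0f} C is below the {tm_threshold:.0f} C threshold"
        )
    lo, hi = RECOMMENDED_FLANK_RANGE
    for name, n in (("left", left), ("right", right)):
        if not lo <= n <= hi:
            warnings.append(
                f"{name} flank of {n} nt is outside the recommended {lo}-{hi} nt"
            )
    plo, phi = VALIDATED_PRIMER_LENGTH_RANGE
    if not plo <= len(sequence) <= phi:
        warnings.append(
            f"primer length {len(sequence)} nt is outside the validated "
            f"{plo}-{phi} nt range"
        )
    return DonorPrimer(
        sequence=sequence,
        interval=(site.start - left, site.end + right),
        left_flank_len=left,
        right_flank_len=right,
        flank_tm=tm,
        phosphorylated_5p=True,
        label=site.label,
        warnings=tuple(warnings),
    )


def design_primer_set(
    spec: LibrarySpec,
    end_primer_len: int = 20,
    **kwargs,
) -> PrimerSet:
    """Donor primers for every site plus the 5'-end primer of the template."""
    donors = tuple(design_donor_primer(spec, site, **kwargs) for site in spec.sites)
    end_primer = spec.template[:end_primer_len] if end_primer_len else None
    return PrimerSet(donors=donors, end_primer=end_primer)


def check_primer_set(
    primers: "PrimerSet | Sequence[DonorPrimer]",
) -> Tuple[List[Tuple[str, str]], List[List[DonorPrimer]]]:
    """Find overlapping donor pairs and partition donors into sub-libraries.

    Donor primers cannot overlap within one synthesis reaction (touching
    endpoints are allowed — intervals are half-open).  Returns the list of
    conflicting pairs (by label, or interval string when unlabeled) and a
    partition of the donors into the minimum number of pairwise-compatible
    sub-libraries, obtained by greedy interval-graph coloring on intervals
    sorted by start (optimal because interval graphs are perfect).
    """
    donors = list(primers.donors if isinstance(primers, PrimerSet) else primers)

    def name(d: DonorPrimer) -> str:
        return d.label or f"[{d.interval[0]},{d.interval[1]})"

    conflicts: List[Tuple[str, str]] = []
    order = sorted(range(len(donors)), key=lambda i: donors[i].interval)
    for ai in range(len(order)):
        a = donors[order[ai]]
        for bi in range(ai + 1, len(order)):
            b = donors[order[bi]]
            if b.interval[0] >= a.interval[1]:
                break
            conflicts.append((name(a), name(b)))

    # greedy coloring: first sub-library whose last interval ends by our start
    groups: List[List[DonorPrimer]] = []
    ends: List[int] = []
    for i in order:
        d = donors[i]
        for g, e in enumerate(ends):
            if d.interval[0] >= e:
                groups[g].append(d)
                ends[g] = d.interval[1]
                break
        else:
            groups.append([d])
            ends.append(d.interval[1])
    if not groups:
        groups = [[]]
    return conflicts, groups


def primer_fasta(primers: PrimerSet) -> str:
    """FASTA text for a primer set (degenerate IUPAC sequences)."""
    lines: List[str] = []
    if primers.end_primer:
        lines += [">end_primer", primers.end_primer]
    for i, d in enumerate(primers.donors, start=1):
        name = d.label or f"donor_{i}"
        lines += [f">{name} interval={d.interval[0]}-{d.interval[1]} 5prime_phos", d.sequence]
    return "\n".join(lines) + "\n"


def primer_table(primers: PrimerSet) -> str:
    """TSV report for donor primers (1-based inclusive coordinates)."""
    header = (
        "name\tstart\tend\tlength\tleft_flank\tright_flank\tflank_tm_C"
        "\tphosphorylated_5p\twarnings"
    )
    rows = [header]
    for i, d in enumerate(primers.donors, start=1):
        rows.append(
            "\t".join(
                [
                    d.label or f"donor_{i}",
                    str(d.interval[0] + 1),
                    str(d.interval[1]),
                    str(len(d)),
                    str(d.left_flank_len),
                    str(d.right_flank_len),
                    f"{d.flank_tm:.1f}",
                    "yes" if d.phosphorylated_5p else "no",
                    "; ".join(d.warnings),
                ]
            )
        )
    return "\n".join(rows) + "\n"
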