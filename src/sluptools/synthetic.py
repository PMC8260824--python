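"""Synthetic library sequencing reads with known ground truth.

Emulates, at desk scale, sequencing of a degenerate-codon library: each read
derives from a library molecule obtained by drawing a base at every mutated
position (uniformly over the site's base set by default, matching equimolar
synthesis), is placed uniformly on the template, and acquires substitution
errors independently per base at a configurable rate, uniform over the three
alternative bases.  Reads are emitted as correctly placed plain-text SAM
records so the QC stage can be exercised end-to-end, and the generator
returns the exact ground truth (variant bases drawn, error positions) for
parameter-recovery tests.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pysam

from sluptools.genetic_code import base_set
from sluptools.library_design import LibrarySpec, MutationSite

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}

#: Mixtures of the five-site recombinase library used as a bundled fixture
#: spec (in-frame codon substitutions on a generated template).
CRE_LIKE_MIXTURES = ("RRK", "VNA", "VNA", "DSC", "VDS")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated sequencing run.

    ``error_rate`` is the per-base substitution probability; errors are
    uniform over the three non-read bases and never produce ambiguity
    codes.  ``mixture_weights`` optionally overrides the uniform base draw
    at given template positions (map position -> {base: weight}).
    ``complex_cigar_fraction`` makes that fraction of reads carry soft
    clips and an internal deletion or insertion, for CIGAR-walker tests.
    """

    spec: LibrarySpec
    n_reads: int
    read_length: int
    error_rate: float = 0.0
    seed: int = 0
    mixture_weights: Optional[Mapping[int, Mapping[str, float]]] = None
    complex_cigar_fraction: float = 0.0
    reference_name: str = "template"
    quality_char: str = "I"

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 1 <= self.read_length <= len(self.spec.template):
            raise ValueError("read_length must be in [1, template length]")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not 0.0 <= self.complex_cigar_fraction <= 1.0:
            raise ValueError("complex_cigar_fraction must be in [0, 1]")
        for site in self.spec.sites:
            if len(site.reference) != len(site.replacement):
                raise ValueError(
                    "the simulator supports same-length substitution sites only"
                )


@dataclass
class SimulationTruth:
    """Exact ground truth of a simulated run, read-parallel lists."""

    starts: List[int]
    variant_bases: List[Dict[int, str]]
    error_positions: List[List[int]]
    cigars: List[str] = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return sum(len(e) for e in self.error_positions)

    def to_json(self) -> str:
        return json.dumps(
            {
                "starts": self.starts,
                "variant_bases": [
                    {str(k): v for k, v in d.items()} for d in self.variant_bases
                ],
                "error_positions": self.error_positions,
                "cigars": self.cigars,
            }
        )


def generate_template(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """Random concrete template with the requested expected GC content."""
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=p))


def cre_like_spec(
    template_length: int = 1050, seed: int = 0, first_codon: int = 60, spacing: int = 48
) -> LibrarySpec:
    """Bundled fixture: five in-frame codon sites with the recombinase
    library's mixtures (RRK, VNA, VNA, DSC, VDS) on a generated template."""
    template = generate_template(template_length, seed=seed)
    sites = []
    pos = first_codon
    for i, mixture in enumerate(CRE_LIKE_MIXTURES):
        sites.append(
            MutationSite(
                start=pos,
                reference=template[pos : pos + 3],
                replacement=mixture,
                label=f"site{i + 1}",
            )
        )
        pos += 3 + spacing
    return LibrarySpec(template=template, sites=tuple(sites), frame_offset=0)


def sample_variant_bases(
    spec: LibrarySpec,
    n: int,
    rng: np.random.Generator,
    mixture_weights: Optional[Mapping[int, Mapping[str, float]]] = None,
) -> Tuple[List[int], np.ndarray]:
    """Draw library-molecule bases at every mutated position.

    Returns the ordered mutated positions and an (n, n_positions) array of
    base codes (0..3 over ACGT); draws are uniform over each position's base
    set unless ``mixture_weights`` overrides it.
    """
    positions = sorted(spec.mutated_positions())
    symbols = spec.mutated_positions()
    out = np.empty((n, len(positions)), dtype=np.uint8)
    for j, pos in enumerate(positions):
        bases = sorted(base_set(symbols[pos]))
        codes = np.array([_BASE_TO_CODE[b] for b in bases], dtype=np.uint8)
        if mixture_weights and pos in mixture_weights:
            w = np.array([mixture_weights[pos].get(b, 0.0) for b in bases], float)
            if w.sum() <= 0:
                raise ValueError(f"mixture weights at {pos} must have positive mass")
            p = w / w.sum()
        else:
            p = None
        out[:, j] = rng.choice(codes, size=n, p=p)
    return positions, out


def _codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    table = np.full(256, 255, dtype=np.uint8)
    for b, i in _BASE_TO_CODE.items():
        table[ord(b)] = i
    return table[arr]


def _seq(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def simulate_library_reads(
    config: SimulationConfig,
    sam_path: "str | Path",
    fasta_path: "Optional[str | Path]" = None,
    truth_path: "Optional[str | Path]" = None,
) -> SimulationTruth:
    """Simulate aligned single-end reads of a library; write SAM (+FASTA).

    Each read samples a library molecule (one base draw per mutated
    position), a uniform start such that the read fits the reference, and
    per-base substitution errors at ``config.error_rate``.  Records are
    written in read order with a full-match CIGAR unless
    ``complex_cigar_fraction`` injects soft-clipped/indel-containing
    alignments.  Output is byte-identical for identical configs.
    """
    spec = config.spec
    rng = np.random.default_rng(config.seed)
    L = len(spec.template)
    rl = config.read_length
    n = config.n_reads
    template_codes = _codes(spec.template)

    positions, variants = sample_variant_bases(
        spec, n, rng, config.mixture_weights
    )
    pos_arr = np.array(positions, dtype=np.int64)
    starts = rng.integers(0, L - rl + 1, size=n)
    complex_mask = (
        rng.random(n) < config.complex_cigar_fraction
        if config.complex_cigar_fraction > 0
        else np.zeros(n, dtype=bool)
    )

    # molecule windows for all reads
    reads = template_codes[starts[:, None] + np.arange(rl)[None, :]].copy()
    for j, p in enumerate(pos_arr):
        offset = p - starts
        covered = (offset >= 0) & (offset < rl)
        reads[np.nonzero(covered)[0], offset[covered]] = variants[covered, j]

    # substitution errors, uniform over the three alternatives
    if config.error_rate > 0:
        err_mask = rng.random((n, rl)) < config.error_rate
        shifts = rng.integers(1, 4, size=(n, rl), dtype=np.uint8)
        reads = np.where(err_mask, (reads + shifts) % 4, reads)
    else:
        err_mask = np.zeros((n, rl), dtype=bool)

    truth = SimulationTruth(starts=[], variant_bases=[], error_positions=[], cigars=[])
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": config.reference_name, "LN": L}],
    }
    sam_path = Path(sam_path)
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for i in range(n):
            start = int(starts[i])
            if complex_mask[i]:
                seq, cigar, start = _complexify(
                    reads[i], start, L, rng
                )
            else:
                seq = _seq(reads[i])
                cigar = f"{rl}M"
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = f"read{i}"
            rec.flag = 0
            rec.reference_id = 0
            rec.reference_start = start
            rec.mapping_quality = 60
            rec.cigarstring = cigar
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array(
                config.quality_char * len(seq)
            )
            out.write(rec)
            truth.starts.append(start)
            truth.variant_bases.append(
                {int(p): BASES[variants[i, j]] for j, p in enumerate(pos_arr)}
            )
            truth.error_positions.append(
                [int(starts[i] + k) for k in np.nonzero(err_mask[i])[0]]
            )
            truth.cigars.append(cigar)

    if fasta_path is not None:
        write_reference_fasta(spec.template, config.reference_name, fasta_path)
    if truth_path is not None:
        Path(truth_path).write_text(truth.to_json())
    return truth


def _complexify(
    read_codes: np.ndarray, start: int, ref_len: int, rng: np.random.Generator
) -> Tuple[str, str, int]:
    """Rewrite one full-match read as a soft-clipped/indel alignment.

    The query keeps its length: leading/trailing stretches become soft
    clips, and either an internal deletion skips reference bases or an
    internal stretch of the query becomes an insertion.  These reads are
    meant for CIGAR-walker equivalence tests; their base content is not
    tracked against the per-position truth.
    """
    rl = len(read_codes)
    lead = int(rng.integers(1, 6))
    tail = int(rng.integers(0, 4))
    core = read_codes[lead : rl - tail if tail else rl]
    new_start = start + lead
    op = int(rng.integers(0, 3))  # 0: none, 1: deletion, 2: insertion
    parts: List[str] = []
    seq_parts: List[str] = []
    if op == 1 and len(core) > 4 and new_start + len(core) + 3 < ref_len:
        cut = int(rng.integers(2, len(core) - 2))
        dlen = int(rng.integers(1, 4))
        # query unchanged; bases after the cut shift right on the reference
        parts = [f"{cut}M", f"{dlen}D", f"{len(core) - cut}M"]
        seq_parts = [_seq(core)]
    elif op == 2 and len(core) > 4:
        cut = int(rng.integers(2, len(core) - 2))
        ilen = int(rng.integers(1, 4))
        ins = _seq(rng.integers(0, 4, size=ilen, dtype=np.uint8))
        parts = [f"{cut}M", f"{ilen}I", f"{len(core) - cut}M"]
        seq_parts = [_seq(core[:cut]), ins, _seq(core[cut:])]
    else:
        parts = [f"{len(core)}M"]
        seq_parts = [_seq(core)]
    cigar = (f"{lead}S" if lead else "") + "".join(parts) + (f"{tail}S" if tail else "")
    seq = _seq(read_codes[:lead]) + "".join(seq_parts) + (
        _seq(read_codes[rl - tail :]) if tail else ""
    )
    return seq, cigar, new_start


def write_reference_fasta(
    template: str, name: str, path: "str | Path", width: int = 70
) -> None:
    lines = [f">{name}"]
    for i in range(0, len(template), width):
        lines.append(template[i : i + width])
    Path(path).write_text("\n".join(lines) + "\n")
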