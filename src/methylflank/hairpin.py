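"""Hairpin bisulfite read processing.

A hairpin read carries both strands of one substrate duplex, so the
original sequence and the methylation state of both target cytosines can
be reconstituted by comparing the two bisulfite-converted strands
position by position.  With the antisense segment re-oriented so that its
index i is the bottom-strand base at duplex position i, the legal
(sense, antisense) base pairs and their meaning are::

    (A,T) -> top A                      (T,A) -> top T
    (C,G) -> top C, methylated          (T,G) -> top C, converted (unmethylated)
    (G,C) -> top G, bottom C methylated (G,T) -> top G, bottom C converted

Any other ordered pair is a pair-mismatch: the position is masked to N and
counted.  The 6-row table is total and unambiguous; the remaining 10
ordered pairs over {A,C,G,T} are all mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._seq import complement
from .config import SubstrateLayout

#: (sense, oriented antisense) -> (top base, top-C state, bottom-C state)
PAIR_TABLE: dict[tuple[str, str], tuple[str, str | None, str | None]] = {
    ("A", "T"): ("A", None, None),
    ("T", "A"): ("T", None, None),
    ("G", "C"): ("G", None, "methylated"),
    ("G", "T"): ("G", None, "unmethylated"),
    ("C", "G"): ("C", "methylated", None),
    ("T", "G"): ("C", "unmethylated", None),
}


@dataclass(frozen=True)
class HairpinRead:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities differ in length")


@dataclass(frozen=True)
class Segmentation:
    """Accepted full-length read split into its duplex segments."""

    sense: str
    antisense: str  # oriented: index i = bottom-strand base at duplex position i


@dataclass(frozen=True)
class Rejection:
    reason: str  # "no-linker" | "short-antisense" | "arm-mismatch"


@dataclass
class ReconstructedMolecule:
    read_id: str
    original_top_sequence: str
    state_top: str      # methylated | unmethylated | undetermined
    state_bottom: str   # methylated | unmethylated | undetermined | absent
    n_pair_mismatches: int
    qc_pass: bool
    sense: str = ""     # retained for conversion QC over fixed-arm cytosines


@dataclass(frozen=True)
class ConversionQC:
    n_control_cytosines: int
    n_converted: int

    @property
    def conversion_rate(self) -> float:
        if self.n_control_cytosines == 0:
            raise ZeroDivisionError("no control cytosine observations")
        return self.n_converted / self.n_control_cytosines


def trim_quality(read: HairpinRead, qmin: int) -> HairpinRead:
    """Remove the maximal 3' suffix in which every base has quality < qmin."""
    if qmin < 0:
        raise ValueError("qmin must be >= 0")
    end = len(read.qualities)
    while end > 0 and read.qualities[end - 1] < qmin:
        end -= 1
    if end == len(read.qualities):
        return read
    return HairpinRead(read.read_id, read.sequence[:end], read.qualities[:end])


def _bisulfite_hamming(expected: str, observed: str) -> int:
    """Hamming distance where an expected C also matches T (conversion)."""
    d = 0
    for e, o in zip(expected, observed):
        if e == o:
            continue
        if e == "C" and o == "T":
            continue
        d += 1
    return d


def select_full_length(
    read: HairpinRead,
    layout: SubstrateLayout,
    max_mismatch: int = 1,
) -> Segmentation | Rejection:
    """Accept a read only if both full-length strand segments are present.

    The linker must sit at its designed offset (fixed amplicon layout, no
    indels) within ``max_mismatch`` substitutions, both segments must have
    the full duplex length, and all four arm anchors must match with
    conversion-tolerant Hamming distance <= ``max_mismatch`` each.
    """
    L, ll = layout.duplex_len, len(layout.linker)
    seq = read.sequence
    if len(seq) < L + ll or _bisulfite_hamming(layout.linker, seq[L : L + ll]) > max_mismatch:
        return Rejection("no-linker")
    antisense_raw = seq[L + ll : L + ll + L]
    if len(antisense_raw) < L:
        return Rejection("short-antisense")
    sense = seq[:L]
    oriented = antisense_raw[::-1]
    a5, a3 = len(layout.arm5), len(layout.arm3)
    checks = (
        (layout.arm5, sense[:a5]),
        (layout.arm3, sense[L - a3 :]),
        # bottom strand at duplex position i is the complement of the top
        # design base, itself subject to C->T conversion
        (complement(layout.arm5), oriented[:a5]),
        (complement(layout.arm3), oriented[L - a3 :]),
    )
    for expected, observed in checks:
        if _bisulfite_hamming(expected, observed) > max_mismatch:
            return Rejection("arm-mismatch")
    return Segmentation(sense=sense, antisense=oriented)


def reconstruct_molecule(
    sense: str,
    antisense: str,
    layout: SubstrateLayout,
    read_id: str = "",
    mismatch_limit: int = 1,
) -> ReconstructedMolecule:
    """Recover the original duplex and both target states from one read pair.

    ``antisense`` must already be oriented (index i = bottom base at duplex
    position i), as returned by :func:`select_full_length`.
    """
    if len(sense) != len(antisense):
        raise ValueError("sense and antisense segments differ in length")
    if len(sense) != layout.duplex_len:
        raise ValueError("segments do not have the designed duplex length")
    c = layout.central_offset
    original = []
    n_mm = 0
    state_top = "undetermined"
    state_bottom = "absent" if layout.central_motif != "CG" else "undetermined"
    for i, (s, a) in enumerate(zip(sense, antisense)):
        row = PAIR_TABLE.get((s, a))
        if row is None:
            original.append("N")
            n_mm += 1
            continue
        base, top_state, bottom_state = row
        original.append(base)
        if i == c and top_state is not None:
            state_top = top_state
        if i == c + 1 and bottom_state is not None and layout.central_motif == "CG":
            state_bottom = bottom_state
    qc = (n_mm <= mismatch_limit
          and state_top != "undetermined"
          and state_bottom != "undetermined")
    return ReconstructedMolecule(
        read_id=read_id,
        original_top_sequence="".join(original),
        state_top=state_top,
        state_bottom=state_bottom,
        n_pair_mismatches=n_mm,
        qc_pass=qc,
        sense=sense,
    )


def estimate_conversion(
    molecules: Iterable[ReconstructedMolecule],
    control_positions: Sequence[int],
) -> ConversionQC:
    """Bisulfite conversion rate over fixed-arm control cytosines.

    Control positions must be top-strand cytosines that are guaranteed
    unmethylated.  Only QC-passing molecules contribute; observations other
    than C (unconverted) or T (converted) — sequencing errors — are ignored.
    """
    total = converted = 0
    for mol in molecules:
        if not mol.qc_pass or not mol.sense:
            continue
        for p in control_positions:
            obs = mol.sense[p]
            if obs == "T":
                total += 1
                converted += 1
            elif obs == "C":
                total += 1
    if total == 0:
        raise ZeroDivisionError("no control cytosine observations")
    return ConversionQC(n_control_cytosines=total, n_converted=converted)


def process_reads(
    reads: Iterable[HairpinRead],
    layout: SubstrateLayout,
    trim_qmin: int = 20,
    anchor_max_mismatch: int = 1,
    pair_mismatch_limit: int = 1,
) -> tuple[list[ReconstructedMolecule], dict[str, int]]:
    """Full per-read pipeline: trim, select, reconstruct.

    Returns the reconstructed molecules (accepted reads only) and a count
    dictionary that reconciles: reads_in = accepted + sum(rejections).
    """
    counts = {"reads_in": 0, "accepted": 0, "no-linker": 0,
              "short-antisense": 0, "arm-mismatch": 0, "qc_fail": 0}
    molecules = []
    for read in reads:
        counts["reads_in"] += 1
        trimmed = trim_quality(read, trim_qmin)
        seg = select_full_length(trimmed, layout, anchor_max_mismatch)
        if isinstance(seg, Rejection):
            counts[seg.reason] += 1
            continue
        counts["accepted"] += 1
        mol = reconstruct_molecule(seg.sense, seg.antisense, layout,
                                   read_id=read.read_id,
                                   mismatch_limit=pair_mismatch_limit)
        if not mol.qc_pass:
            counts["qc_fail"] += 1
        molecules.append(mol)
    return molecules, counts
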