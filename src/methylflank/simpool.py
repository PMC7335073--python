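"""Synthetic deep-enzymology substrate pools.

Emulates the wet-lab workflow end to end: synthesis of a duplex pool in
which the target cytosine-dinucleotide is flanked by random nucleotides on
each side, enzymatic methylation under a known (ground-truth) preference
model, hairpin ligation, bisulfite conversion and sequencing.  Every
downstream stage of the package can therefore be tested against known
truth without external data.

Methylation is modelled as a single Bernoulli event per strand-site: for a
CpG target the top- and bottom-strand cytosines are drawn independently,
each conditioned on its own strand-read flanking context.  Non-CpG targets
(CpA/CpT/CpC) have no symmetric cytosine, so only the top strand carries an
event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from ._seq import BASES, revcomp
from .config import SubstrateLayout


@dataclass(frozen=True)
class SubstrateMolecule:
    """One double-stranded substrate with random flanks around the target."""

    molecule_id: str
    top_sequence: str
    flank_len: int
    central_offset: int
    central_motif: str

    def __post_init__(self) -> None:
        c = self.central_offset
        if self.top_sequence[c : c + 2] != self.central_motif:
            raise ValueError("central bases do not match central_motif")

    def flank_context(self) -> str:
        """Top-strand flanking context (left flank + right flank, 2*flank_len)."""
        c, f = self.central_offset, self.flank_len
        return self.top_sequence[c - f : c] + self.top_sequence[c + 2 : c + 2 + f]

    def bottom_flank_context(self) -> str:
        """Flanking context read 5'->3' on the bottom strand (CpG targets only)."""
        c, f = self.central_offset, self.flank_len
        window = revcomp(self.top_sequence[c - f : c + 2 + f])
        return window[:f] + window[f + 2 :]


@dataclass(frozen=True)
class StrandMethylationOutcome:
    """Result of one enzymatic methylation event on one strand-site."""

    molecule_id: str
    strand: str  # "top" | "bottom"
    target_methylated: bool
    strand_context: str


@dataclass
class PreferenceModel:
    """Ground-truth flanking-sequence preference used by the simulator.

    Two flavours:

    * ``lookup`` — an explicit map from a flank context of half-width
      ``half_width`` (string of length ``2*half_width``) to a methylation
      probability; ``default`` fills uncovered contexts (None = strict).
    * ``positional`` — ``base_rate`` multiplied by per-position per-base
      weights, clamped to [0, 1].  Positions are -flank..-1, +1..+flank
      relative to the target dinucleotide.
    """

    kind: str = "positional"
    lookup: Mapping[str, float] = field(default_factory=dict)
    half_width: int = 0
    default: float | None = None
    base_rate: float = 0.5
    weights: Mapping[int, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("lookup", "positional"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        for ctx, p in self.lookup.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {ctx!r} outside [0, 1]")
        if self.default is not None and not 0.0 <= self.default <= 1.0:
            raise ValueError("default probability outside [0, 1]")

    def probability(self, context: str) -> float:
        """Methylation probability for a full-width strand context.

        ``context`` is the concatenated left+right flank read 5'->3' on the
        strand carrying the scored cytosine.  Lookup models defined at a
        narrower half-width use the central window of the context.
        """
        flank = len(context) // 2
        if self.kind == "lookup":
            k = self.half_width or flank
            if k > flank:
                raise ValueError("model half-width exceeds available flank")
            key = context[flank - k : flank] + context[flank : flank + k]
            if key in self.lookup:
                return self.lookup[key]
            if self.default is None:
                raise KeyError(f"context {key!r} missing from lookup model")
            return self.default
        p = self.base_rate
        for i in range(flank):
            left_pos, right_pos = -(flank - i), i + 1
            p *= self.weights.get(left_pos, {}).get(context[i], 1.0)
            p *= self.weights.get(right_pos, {}).get(context[flank + i], 1.0)
        return min(1.0, max(0.0, p))

    @classmethod
    def constant(cls, p: float) -> "PreferenceModel":
        return cls(kind="positional", base_rate=p, weights={})

    @classmethod
    def random_lookup(
        cls, half_width: int, rng: np.random.Generator,
        low: float = 0.05, high: float = 0.95,
    ) -> "PreferenceModel":
        """Uniformly random per-context probabilities over all 4^(2k) contexts."""
        from itertools import product

        contexts = ["".join(c) for c in product(BASES, repeat=2 * half_width)]
        probs = rng.uniform(low, high, size=len(contexts))
        return cls(kind="lookup", lookup=dict(zip(contexts, probs)),
                   half_width=half_width)


def generate_pool(
    n_molecules: int,
    flank_len: int,
    central_motif: str,
    seed: int,
    layout: SubstrateLayout | None = None,
) -> list[SubstrateMolecule]:
    """Draw a pool of substrates with i.i.d. uniform random flanks.

    Deterministic for a fixed seed.  The fixed arms come from ``layout``
    (defaults if omitted); ``flank_len`` and ``central_motif`` override the
    layout's values.
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    base = layout or SubstrateLayout()
    layout = SubstrateLayout(arm5=base.arm5, arm3=base.arm3, linker=base.linker,
                             flank_len=flank_len, central_motif=central_motif)
    rng = np.random.default_rng(seed)
    flanks = rng.integers(0, 4, size=(n_molecules, 2 * flank_len))
    lut = np.array(BASES)
    pool = []
    for i in range(n_molecules):
        fl = "".join(lut[flanks[i]])
        top = (layout.arm5 + fl[:flank_len] + central_motif
               + fl[flank_len:] + layout.arm3)
        pool.append(SubstrateMolecule(
            molecule_id=f"mol{i:07d}", top_sequence=top,
            flank_len=flank_len, central_offset=layout.central_offset,
            central_motif=central_motif))
    return pool


def simulate_methylation(
    pool: Sequence[SubstrateMolecule],
    model: PreferenceModel,
    seed: int,
) -> list[StrandMethylationOutcome]:
    """One Bernoulli methylation event per eligible strand-site.

    Top and bottom strands of a CpG target are drawn independently, each
    conditioned on its own 5'->3' strand context.
    """
    rng = np.random.default_rng(seed)
    outcomes = []
    for mol in pool:
        ctx_top = mol.flank_context()
        outcomes.append(StrandMethylationOutcome(
            mol.molecule_id, "top",
            bool(rng.random() < model.probability(ctx_top)), ctx_top))
        if mol.central_motif == "CG":
            ctx_bot = mol.bottom_flank_context()
            outcomes.append(StrandMethylationOutcome(
                mol.molecule_id, "bottom",
                bool(rng.random() < model.probability(ctx_bot)), ctx_bot))
    return outcomes


def _bisulfite_image(
    strand: str, methylated_positions: set[int],
    conversion_rate: float, inappropriate_conversion: float,
    rng: np.random.Generator,
) -> str:
    """Apply C->T bisulfite chemistry to one strand read 5'->3'."""
    out = []
    for i, b in enumerate(strand):
        if b == "C":
            p = inappropriate_conversion if i in methylated_positions else conversion_rate
            out.append("T" if rng.random() < p else "C")
        else:
            out.append(b)
    return "".join(out)


def emit_hairpin_fastq(
    pool: Sequence[SubstrateMolecule],
    outcomes: Iterable[StrandMethylationOutcome],
    conversion_rate: float,
    inappropriate_conversion: float,
    seq_error: float,
    seed: int,
    out: TextIO | str | Path,
    layout: SubstrateLayout | None = None,
    quality_high: int = 37,
    quality_low: int = 10,
    lowq_tail_frac: float = 0.0,
    lowq_tail_max: int = 8,
) -> int:
    """Write one hairpin bisulfite read per molecule; returns the read count.

    Read layout: sense segment (bisulfite image of the top strand), the
    cytosine-free linker, then the antisense segment (bisulfite image of the
    bottom strand read 5'->3' through the hairpin, i.e. duplex right-to-left).
    Substitution errors at ``seq_error`` are applied after conversion.
    Byte-identical output for identical inputs and seed.
    """
    for name, v in (("conversion_rate", conversion_rate),
                    ("inappropriate_conversion", inappropriate_conversion),
                    ("seq_error", seq_error)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    layout = layout or SubstrateLayout(
        flank_len=pool[0].flank_len if pool else 10,
        central_motif=pool[0].central_motif if pool else "CG")
    meth: dict[str, dict[str, bool]] = {}
    for o in outcomes:
        meth.setdefault(o.molecule_id, {})[o.strand] = o.target_methylated

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    handle: TextIO
    close = False
    if isinstance(out, (str, Path)):
        handle = open(out, "w")
        close = True
    else:
        handle = out
    n = 0
    try:
        for mol in pool:
            c = mol.central_offset
            L = len(mol.top_sequence)
            states = meth.get(mol.molecule_id, {})
            top_meth = {c} if states.get("top", False) else set()
            bottom = revcomp(mol.top_sequence)
            # bottom-strand target C sits opposite the top G at c+1
            bot_meth = {L - 1 - (c + 1)} if states.get("bottom", False) else set()
            sense = _bisulfite_image(mol.top_sequence, top_meth,
                                     conversion_rate, inappropriate_conversion, rng)
            antisense = _bisulfite_image(bottom, bot_meth,
                                         conversion_rate, inappropriate_conversion, rng)
            seq = list(sense + layout.linker + antisense)
            if seq_error > 0:
                for i in range(len(seq)):
                    if rng.random() < seq_error:
                        alts = [b for b in "ACGT" if b != seq[i]]
                        seq[i] = alts[rng.integers(0, 3)]
            quals = np.full(len(seq), quality_high, dtype=int)
            if lowq_tail_frac > 0 and rng.random() < lowq_tail_frac:
                tail = int(rng.integers(1, lowq_tail_max + 1))
                quals[-tail:] = quality_low
            qstr = "".join(chr(q + 33) for q in quals)
            handle.write(f"@{mol.molecule_id}\n{''.join(seq)}\n+\n{qstr}\n")
            n += 1
    finally:
        if close:
            handle.close()
    return n


def write_truth_table(
    pool: Sequence[SubstrateMolecule],
    outcomes: Iterable[StrandMethylationOutcome],
    out: TextIO | str | Path,
    seed: int | None = None,
) -> None:
    """Tab-separated ground truth: molecule_id, top_sequence, per-strand states."""
    meth: dict[str, dict[str, bool]] = {}
    for o in outcomes:
        meth.setdefault(o.molecule_id, {})[o.strand] = o.target_methylated
    handle: TextIO
    close = False
    if isinstance(out, (str, Path)):
        handle = open(out, "w")
        close = True
    else:
        handle = out
    try:
        if seed is not None:
            handle.write(f"# seed={seed}\n")
        handle.write("molecule_id\ttop_sequence\tmeth_top\tmeth_bottom\n")
        for mol in pool:
            s = meth.get(mol.molecule_id, {})
            mt = int(s.get("top", False))
            mb = int(s["bottom"]) if "bottom" in s else "NA"
            handle.write(f"{mol.molecule_id}\t{mol.top_sequence}\t{mt}\t{mb}\n")
    finally:
        if close:
            handle.close()
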