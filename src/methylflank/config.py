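"""Substrate layout and pipeline configuration.

The amplicon substrate is a fixed-layout duplex::

    5' arm (fixed) | left flank (random) | C+N target | right flank (random) | 3' arm (fixed)

A hairpin loop joins the 3' end of the top strand to the 5' end of the
bottom strand, so a single sequencing read runs top strand 5'->3', then the
loop (linker), then the bottom strand 5'->3' (duplex right-to-left)::

    read:  [ sense = bisulfite image of top ][ linker ][ antisense = bisulfite image of bottom ]
    duplex position of antisense base j:  L - 1 - j   (L = duplex length)

The linker is cytosine-free so bisulfite conversion cannot change it, which
makes it a reliable anchor for segmenting reads.  Fixed-arm cytosines are
never enzyme targets, so they serve as built-in conversion controls.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

VALID_MOTIFS = ("CG", "CA", "CT", "CC")

# Default fixed sequences.  Both arms avoid CpG dinucleotides so no arm
# cytosine is a plausible de novo methylation target, and each contains
# several cytosines to power the conversion-rate estimate.
DEFAULT_ARM5 = "ACTCCATTAGTCAATGTCAG"
DEFAULT_ARM3 = "TGACTAATGGACCATCATTG"
DEFAULT_LINKER = "GATTAGAT"  # C-free: invariant under bisulfite conversion


@dataclass(frozen=True)
class SubstrateLayout:
    """Geometry of the randomized-flank substrate and its hairpin read."""

    arm5: str = DEFAULT_ARM5
    arm3: str = DEFAULT_ARM3
    linker: str = DEFAULT_LINKER
    flank_len: int = 10
    central_motif: str = "CG"

    def __post_init__(self) -> None:
        if not self.central_motif.startswith("C") or self.central_motif not in VALID_MOTIFS:
            raise ValueError(
                f"central_motif must be one of {VALID_MOTIFS}, got {self.central_motif!r}"
            )
        if self.flank_len < 0:
            raise ValueError("flank_len must be >= 0")
        for name in ("arm5", "arm3", "linker"):
            s = getattr(self, name)
            if set(s) - set("ACGT"):
                raise ValueError(f"{name} contains non-ACGT characters: {s!r}")
        if "C" in self.linker:
            raise ValueError("linker must be cytosine-free (conversion-invariant anchor)")

    @property
    def central_offset(self) -> int:
        """0-based index of the target cytosine on the top strand."""
        return len(self.arm5) + self.flank_len

    @property
    def duplex_len(self) -> int:
        return len(self.arm5) + 2 * self.flank_len + 2 + len(self.arm3)

    @property
    def read_len(self) -> int:
        """Length of an error-free, untrimmed hairpin read."""
        return 2 * self.duplex_len + len(self.linker)

    def control_cytosine_positions(self) -> tuple[int, ...]:
        """Top-strand positions of fixed-arm cytosines (guaranteed unmethylated).

        Flank cytosines are excluded: they can be genuine enzyme substrates.
        """
        pos = [i for i, b in enumerate(self.arm5) if b == "C"]
        off3 = len(self.arm5) + 2 * self.flank_len + 2
        pos += [off3 + i for i, b in enumerate(self.arm3) if b == "C"]
        return tuple(pos)


@dataclass
class PipelineConfig:
    """All tunables of the simulate -> reconstruct -> profile pipeline.

    Thresholds are validated on construction; unknown keys in a config file
    are rejected rather than silently ignored.
    """

    layout: SubstrateLayout = field(default_factory=SubstrateLayout)

    # simulation rates
    conversion_rate: float = 0.998       # P(unmethylated C -> T)
    inappropriate_conversion: float = 0.002  # P(methylated C -> T)
    seq_error: float = 0.001             # per-base substitution rate
    quality_high: int = 37
    quality_low: int = 10
    lowq_tail_frac: float = 0.0          # fraction of reads given a Q-low 3' tail
    lowq_tail_max: int = 8

    # read processing
    trim_qmin: int = 20
    anchor_max_mismatch: int = 1
    pair_mismatch_limit: int = 1

    # profiling
    min_coverage: int = 10               # per-context events for ranking/correlation

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_rate", "inappropriate_conversion", "seq_error", "lowq_tail_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("trim_qmin", "anchor_max_mismatch", "pair_mismatch_limit",
                     "min_coverage", "quality_high", "quality_low", "lowq_tail_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["layout"] = dataclasses.asdict(self.layout)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        layout_data = data.pop("layout", {})
        unknown = set(layout_data) - {f.name for f in dataclasses.fields(SubstrateLayout)}
        if unknown:
            raise ValueError(f"unknown layout keys: {sorted(unknown)}")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(layout=SubstrateLayout(**layout_data), **data)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)
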