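"""Domain types and coordinate conventions.

All coordinates are 0-based, half-open, on a circular chromosome unless a
genome is explicitly linear. A chromosome has two replichores (arms) defined
by the replication origin (``ori``) and terminus (``ter``): the forward arm
runs from ori forward (in increasing coordinate, wrapping) to ter, the
reverse arm from ter forward to ori. On the forward arm the Watson (+1)
strand is the leading strand; on the reverse arm the Crick (-1) strand is
leading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Genome:
    """A nucleotide sequence over {A,C,G,T,N}, uppercase, usually circular."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """A gene with 0-based half-open coordinates and strand in {+1, -1}.

    ``wraps`` marks features crossing the circular coordinate origin, in
    which case ``end`` may be <= ``start`` (interpreted modulo length).
    """

    gene_id: str
    start: int
    end: int
    strand: int
    kind: str = "CDS"
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")
        if not self.wraps and self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end <= start on non-wrapping feature")

    def midpoint(self, genome_length: int | None = None) -> float:
        if self.wraps:
            if genome_length is None:
                raise ValueError("wrapping feature needs genome_length")
            span = (self.end - self.start) % genome_length
            return (self.start + span / 2) % genome_length
        return (self.start + self.end) / 2

    def length(self, genome_length: int | None = None) -> int:
        if self.wraps:
            if genome_length is None:
                raise ValueError("wrapping feature needs genome_length")
            return (self.end - self.start) % genome_length
        return self.end - self.start


@dataclass
class StrandBias:
    """Sup-form strand bias: max(N_W, N_C) / (N_W + N_C), in [0.5, 1].

    Used where the replichore polarity of the measured DNA is unknown
    (e.g. random donor fragments). Undefined at zero total occurrences.
    """

    n_watson: int
    n_crick: int

    @property
    def defined(self) -> bool:
        return self.n_watson + self.n_crick > 0

    @property
    def value(self) -> float:
        total = self.n_watson + self.n_crick
        if total == 0:
            raise ValueError("strand bias undefined at zero occurrences")
        return max(self.n_watson, self.n_crick) / total


@dataclass
class PermissiveFraction:
    """Fraction of occurrences in the permissive (leading-strand) orientation.

    In [0, 1]; requires a replichore map, unlike the sup-form StrandBias.
    """

    n_permissive: int
    n_nonpermissive: int

    @property
    def defined(self) -> bool:
        return self.n_permissive + self.n_nonpermissive > 0

    @property
    def value(self) -> float:
        total = self.n_permissive + self.n_nonpermissive
        if total == 0:
            raise ValueError("permissive fraction undefined at zero occurrences")
        return self.n_permissive / total


@dataclass
class ReplichoreMap:
    """Origin/terminus positions and the induced arm/leading-strand geometry."""

    ori: int
    ter: int
    length: int
    delta: float | None = None
    delta_profile: list | None = None
    low_confidence: bool = False
    ambiguous_polarity: bool = False

    def __post_init__(self) -> None:
        if self.ori == self.ter:
            raise ValueError("ori and ter must differ")
        self.ori %= self.length
        self.ter %= self.length

    def arm_of(self, pos) -> np.ndarray | int:
        """1 for the forward arm (ori -> ter), 2 for the reverse arm."""
        pos = np.asarray(pos) % self.length
        from_ori = (pos - self.ori) % self.length
        arm_len_fwd = (self.ter - self.ori) % self.length
        out = np.where(from_ori < arm_len_fwd, 1, 2)
        return out if out.ndim else int(out)

    def is_leading(self, pos, strand) -> np.ndarray | bool:
        """True iff an occurrence at ``pos`` on ``strand`` lies on the leading strand."""
        arm = np.asarray(self.arm_of(pos))
        strand = np.asarray(strand)
        out = np.where(arm == 1, strand == 1, strand == -1)
        return out if out.ndim else bool(out)

    def distance_from_terminus(self, pos, clamp: bool = True) -> np.ndarray | float:
        """Distance to ter along the arm containing ``pos``, as % genome length.

        0 at the terminus; 50 at the origin for equal arms. On the longer arm
        of an unequal-arm genome values exceed 50; ``clamp`` caps them at 50.
        """
        pos = np.asarray(pos, dtype=float) % self.length
        arm = np.asarray(self.arm_of(pos.astype(np.int64)))
        fwd = (self.ter - pos) % self.length  # along forward arm
        rev = (pos - self.ter) % self.length  # along reverse arm
        dist = np.where(arm == 1, fwd, rev) * 100.0 / self.length
        if clamp:
            dist = np.minimum(dist, 50.0)
        return dist if dist.ndim else float(dist)

    def arm_intervals(self) -> dict[int, list[tuple[int, int]]]:
        """Each arm as a list of linear [start, end) intervals (split at wrap)."""
        out: dict[int, list[tuple[int, int]]] = {}
        for arm, (a, b) in ((1, (self.ori, self.ter)), (2, (self.ter, self.ori))):
            if a < b:
                out[arm] = [(a, b)]
            else:
                out[arm] = [(a, self.length), (0, b)]
        return out


def region_intervals(center: int, half_width: int, length: int) -> list[tuple[int, int]]:
    """Circular window ``center ± half_width`` as linear [start, end) intervals."""
    if 2 * half_width >= length:
        return [(0, length)]
    a = (center - half_width) % length
    b = (center + half_width) % length
    if a < b:
        return [(a, b)]
    return [(a, length), (0, b)]


def intersect_intervals(
    xs: list[tuple[int, int]], ys: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    for a1, b1 in xs:
        for a2, b2 in ys:
            lo, hi = max(a1, a2), min(b1, b2)
            if lo < hi:
                out.append((lo, hi))
    return out


@dataclass
class TruthTable:
    """Planted ground truth emitted alongside a synthetic genome."""

    ori: int
    ter: int
    planted_aims: dict = field(default_factory=dict)
    planted_inversions: list = field(default_factory=list)
    planted_insertions: list = field(default_factory=list)
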