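"""Data model for tiled resequencing arrays.

A resequencing array interrogates every base of a set of target regions
with a *quartet* of 25-mer probes per strand: four probes identical except
at the central position, which carries each of A, C, G and T.  Eight
features (4 bases x 2 strands) therefore report on each interrogated
position.  The reverse-strand probe for substituted base ``b`` is the
reverse complement of the forward-strand probe carrying ``b``, so features
on both strands are keyed by the same nucleotide on the forward reference
strand.

This module builds such designs from a reference sequence plus region
intervals, and exposes per-probe sequence analytics (G/C content and
homopolymer "stack" flags) that drive hybridization behaviour downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

BASES = "ACGT"
_BASE_TO_IDX = {b: i for i, b in enumerate(BASES)}
# complement under the A=0,C=1,G=2,T=3 encoding is index reversal
A, C, G, T = 0, 1, 2, 3


class DesignError(ValueError):
    """Invalid tiling request (coordinates or parameters)."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, idx in _BASE_TO_IDX.items():
        out[arr == ord(base)] = idx
    if (out == 255).any():
        bad = seq[int(np.argmax(out == 255))]
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return out


def decode_sequence(idx: np.ndarray) -> str:
    return "".join(BASES[i] for i in idx)


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq.upper()))


#: IUPAC ambiguity codes for unordered heterozygous base pairs.
HET_CODES = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
}
CODE_TO_PAIR = {v: k for k, v in HET_CODES.items()}


@dataclass(frozen=True)
class Quartet:
    """The four feature intensities for one position on one strand.

    ``values`` is indexed by substituted-base index (A=0, C=1, G=2, T=3),
    keyed on the forward strand for both strands.
    """

    values: np.ndarray

    @classmethod
    def from_dict(cls, intensities: dict[str, float]) -> "Quartet":
        vals = np.array([float(intensities[b]) for b in BASES])
        return cls(values=vals)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (4,):
            raise ValueError("a quartet holds exactly 4 intensities")
        if (self.values < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class ProbeStats:
    """Sequence composition of a single probe."""

    probe_length: int
    g_count: int
    c_count: int
    gc_fraction: float
    has_g_stack: bool
    has_c_stack: bool


def _max_run(idx: np.ndarray, base: int) -> int:
    best = run = 0
    for v in idx:
        run = run + 1 if v == base else 0
        best = max(best, run)
    return best


def probe_stats(probe: str, stack_k: int = 4) -> ProbeStats:
    """Composition statistics for one probe sequence.

    ``has_g_stack`` / ``has_c_stack`` flag a run of at least ``stack_k``
    consecutive G (resp. C) bases anywhere in the probe; runs of >= 4 Gs
    are the classic signature of degraded hybridization signal.
    """
    idx = encode_sequence(probe)
    g = int(np.count_nonzero(idx == G))
    c = int(np.count_nonzero(idx == C))
    return ProbeStats(
        probe_length=len(probe),
        g_count=g,
        c_count=c,
        gc_fraction=(g + c) / len(probe),
        has_g_stack=_max_run(idx, G) >= stack_k,
        has_c_stack=_max_run(idx, C) >= stack_k,
    )


@dataclass(frozen=True)
class FeatureStats:
    """Per-feature composition tensors, shape ``(n_positions, 2, 4)``.

    Axis 1 is strand (0=fwd, 1=rev), axis 2 the substituted base keyed on
    the forward strand.  ``g_stack`` flags a run of >= ``stack_k`` Gs in
    the physical probe sequence of that feature.
    """

    g_count: np.ndarray
    c_count: np.ndarray
    g_stack: np.ndarray
    stack_k: int


@dataclass
class ArrayDesign:
    """Tiled interrogated positions with their 8-probe feature sets.

    Coordinates are 0-based; ``positions`` is sorted and contiguous within
    each tiled fragment.  Probes are regenerated on demand from the
    reference, which keeps the design light and guarantees probe/reference
    consistency by construction.
    """

    chrom: str
    reference: str
    positions: np.ndarray           # genomic position per interrogated base
    exon_of: np.ndarray             # exon identifier per position (object/str)
    fragment_id: np.ndarray         # tiled-fragment index per position
    probe_length: int = 25

    _ref_idx: np.ndarray = field(init=False, repr=False)
    _stats_cache: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.probe_length % 2 == 0 or self.probe_length < 9:
            raise DesignError(f"probe_length must be odd and >= 9, got {self.probe_length}")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.exon_of = np.asarray(self.exon_of, dtype=object)
        self.fragment_id = np.asarray(self.fragment_id, dtype=np.int64)
        if not (len(self.positions) == len(self.exon_of) == len(self.fragment_id)):
            raise DesignError("positions, exon_of and fragment_id must align")
        self._ref_idx = encode_sequence(self.reference)
        k = self.flank
        if len(self.positions) and (
            self.positions.min() < k or self.positions.max() + k >= len(self.reference)
        ):
            raise DesignError("interrogated position too close to the reference edge")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def flank(self) -> int:
        return (self.probe_length - 1) // 2

    @property
    def ref_idx(self) -> np.ndarray:
        """Reference base index (0..3) per interrogated position."""
        return self._ref_idx[self.positions]

    @property
    def ref_base(self) -> np.ndarray:
        return np.array([BASES[i] for i in self.ref_idx], dtype=object)

    # ---- probe sequences -------------------------------------------------

    def probe(self, position: int, strand: str, sub_base: str) -> str:
        """Probe sequence for one feature.

        ``strand`` is ``"fwd"`` or ``"rev"``; ``sub_base`` is always the
        interrogated nucleotide on the forward strand (the reverse-strand
        probe physically carries its complement at the centre).
        """
        if strand not in ("fwd", "rev"):
            raise ValueError(f"strand must be 'fwd' or 'rev', got {strand!r}")
        k = self.flank
        window = self.reference[position - k : position + k + 1].upper()
        fwd = window[:k] + sub_base.upper() + window[k + 1 :]
        return fwd if strand == "fwd" else revcomp(fwd)

    def iter_features(self) -> Iterable[tuple[int, str, str, str, str]]:
        """Yield (position, strand, sub_base, probe_seq, exon_id) rows."""
        for i, pos in enumerate(self.positions):
            for strand in ("fwd", "rev"):
                for base in BASES:
                    yield int(pos), strand, base, self.probe(int(pos), strand, base), str(self.exon_of[i])

    # ---- vectorized composition ------------------------------------------

    def feature_stats(self, stack_k: int = 4) -> FeatureStats:
        """G/C counts and G-stack flags for all 8 features per position.

        The reverse-strand probe is the reverse complement of the forward
        one, so its G-count equals the forward probe's C-count and its
        G-stack flag equals the forward probe's C-stack flag.
        """
        if stack_k in self._stats_cache:
            return self._stats_cache[stack_k]
        n, L, k = self.n_positions, self.probe_length, self.flank
        windows = sliding_window_view(self._ref_idx, L)[self.positions - k]

        off_g = (windows == G).sum(axis=1) - (windows[:, k] == G)
        off_c = (windows == C).sum(axis=1) - (windows[:, k] == C)
        g_count = np.empty((n, 2, 4), dtype=np.int16)
        c_count = np.empty((n, 2, 4), dtype=np.int16)
        g_stack = np.empty((n, 2, 4), dtype=bool)
        for b in range(4):
            gf = off_g + (b == G)
            cf = off_c + (b == C)
            g_count[:, 0, b] = gf
            c_count[:, 0, b] = cf
            g_count[:, 1, b] = cf          # revcomp swaps G and C counts
            c_count[:, 1, b] = gf
            sub = windows.copy()
            sub[:, k] = b
            g_stack[:, 0, b] = _has_run(sub == G, stack_k)
            g_stack[:, 1, b] = _has_run(sub == C, stack_k)
        stats = FeatureStats(g_count=g_count, c_count=c_count, g_stack=g_stack, stack_k=stack_k)
        self._stats_cache[stack_k] = stats
        return stats


def _has_run(mask: np.ndarray, k: int) -> np.ndarray:
    """Row-wise: does a run of >= k consecutive True exist?"""
    if mask.shape[1] < k:
        return np.zeros(mask.shape[0], dtype=bool)
    run = mask[:, : mask.shape[1] - k + 1].copy()
    for off in range(1, k):
        run &= mask[:, off : mask.shape[1] - k + 1 + off]
    return run.any(axis=1)


def tile_probes(
    reference: str,
    regions: Sequence[tuple],
    probe_length: int = 25,
    chrom: str = "ref",
) -> ArrayDesign:
    """Tile probe quartets over every base of the given regions.

    ``regions`` are 0-based half-open ``(start, end)`` or
    ``(start, end, name)`` intervals on ``reference``; each becomes one
    tiled fragment and, when named, one exon.  Every base of every region
    must have ``(probe_length - 1) / 2`` flanking reference bases
    available on both sides.
    """
    if probe_length % 2 == 0:
        raise DesignError(f"probe_length must be odd, got {probe_length}")
    if not regions:
        raise DesignError("empty region list")
    k = (probe_length - 1) // 2
    positions, exons, frags = [], [], []
    for fid, region in enumerate(regions):
        start, end = int(region[0]), int(region[1])
        name = str(region[2]) if len(region) > 2 else f"exon_{fid:03d}"
        if start >= end:
            raise DesignError(f"empty or inverted region {region}")
        if start - k < 0 or end + k > len(reference):
            raise DesignError(
                f"region {region} lacks {k} flanking bases within the reference"
            )
        positions.extend(range(start, end))
        exons.extend([name] * (end - start))
        frags.extend([fid] * (end - start))
    return ArrayDesign(
        chrom=chrom,
        reference=reference,
        positions=np.array(positions, dtype=np.int64),
        exon_of=np.array(exons, dtype=object),
        fragment_id=np.array(frags, dtype=np.int64),
        probe_length=probe_length,
    )
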