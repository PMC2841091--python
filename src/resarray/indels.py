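"""Candidate-indel detection from tiling-array signatures.

Resequencing arrays cannot genotype an unanticipated indel, but an indel
leaves two indirect footprints that can be flagged for confirmatory
sequencing:

* a *no-call stretch*: the probes spanning the event match no allele, so
  the caller emits a run of no-calls (sometimes with spurious variant
  calls mixed in);
* a *regional intensity drop*: peak feature intensities are depressed
  across the surrounding window.

Either signature yields an :class:`IndelCandidate`.  Small (1-bp) events
in G/C-rich context often produce neither signature; that is a known
limitation of the platform, not of this scanner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .caller import N_CALL, is_variant_call
from .design import ArrayDesign
from .simulate import SampleIntensities

__all__ = ["IndelCandidate", "detect_nocall_stretches", "detect_intensity_drop", "merge_candidates"]


@dataclass(frozen=True)
class IndelCandidate:
    """Candidate indel region (genomic, 0-based half-open)."""

    start: int
    end: int
    evidence: str                 # nocall_stretch | intensity_drop | both
    n_nocalls: int = 0
    n_variants: int = 0
    drop_ratio: float = float("nan")   # window median peak / array median peak

    def overlaps(self, other: "IndelCandidate") -> bool:
        return self.start < other.end and other.start < self.end


def detect_nocall_stretches(
    calls: pd.DataFrame, design: ArrayDesign, min_len: int = 8
) -> list[IndelCandidate]:
    """Report maximal runs of consecutive N-or-variant positions.

    A run must be contiguous (no wild-type interruptions), stay within
    one tiled fragment, and contain at least ``min_len`` no-calls.
    """
    bad = (calls["call"] == N_CALL).to_numpy() | is_variant_call(calls)
    nmask = (calls["call"] == N_CALL).to_numpy()
    pos = design.positions
    frag = design.fragment_id
    out: list[IndelCandidate] = []
    i, n = 0, len(bad)
    while i < n:
        if not bad[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and bad[j + 1] and frag[j + 1] == frag[i] and pos[j + 1] == pos[j] + 1:
            j += 1
        n_no = int(nmask[i : j + 1].sum())
        if n_no >= min_len:
            out.append(
                IndelCandidate(
                    start=int(pos[i]),
                    end=int(pos[j]) + 1,
                    evidence="nocall_stretch",
                    n_nocalls=n_no,
                    n_variants=int(j + 1 - i - n_no),
                )
            )
        i = j + 1
    return out


def detect_intensity_drop(
    sample: SampleIntensities,
    design: ArrayDesign,
    window: int = 15,
    drop_frac: float = 0.5,
) -> list[IndelCandidate]:
    """Report regions whose local peak intensity collapses.

    Slides an odd ``window`` over each fragment; positions where the
    rolling median of per-position peak intensity (max over all 8
    features) falls below ``drop_frac`` times the array-wide median peak
    are merged into candidate intervals.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    peaks = sample.peak_per_position()
    array_median = float(np.median(peaks))
    thresh = drop_frac * array_median
    h = window // 2
    out: list[IndelCandidate] = []
    for fid in np.unique(design.fragment_id):
        sel = design.fragment_id == fid
        p = peaks[sel]
        pos = design.positions[sel]
        med = (
            pd.Series(p).rolling(window, center=True, min_periods=h + 1).median().to_numpy()
        )
        low = med < thresh
        i, n = 0, len(low)
        while i < n:
            if not low[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and low[j + 1]:
                j += 1
            win_med = float(np.median(p[max(0, i - h) : j + 1 + h]))
            out.append(
                IndelCandidate(
                    start=int(pos[i]),
                    end=int(pos[j]) + 1,
                    evidence="intensity_drop",
                    drop_ratio=win_med / array_median if array_median > 0 else float("nan"),
                )
            )
            i = j + 1
    return sorted(out, key=lambda c: c.start)


def merge_candidates(
    a: list[IndelCandidate], b: list[IndelCandidate]
) -> list[IndelCandidate]:
    """Merge overlapping candidates from the two detectors.

    Overlapping intervals are unioned; a merged candidate supported by
    both signatures gets evidence ``both``.  The result is disjoint and
    sorted by start.
    """
    todo = sorted(a + b, key=lambda c: (c.start, c.end))
    out: list[IndelCandidate] = []
    for cand in todo:
        if out and out[-1].overlaps(cand):
            prev = out[-1]
            evidence = prev.evidence if prev.evidence == cand.evidence else "both"
            drop = cand.drop_ratio if np.isnan(prev.drop_ratio) else prev.drop_ratio
            out[-1] = IndelCandidate(
                start=prev.start,
                end=max(prev.end, cand.end),
                evidence=evidence,
                n_nocalls=prev.n_nocalls + cand.n_nocalls,
                n_variants=prev.n_variants + cand.n_variants,
                drop_ratio=drop,
            )
        else:
            out.append(cand)
    return out
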