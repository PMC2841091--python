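"""Primary quartet-based base caller.

A deliberately transparent ratio-based caller that turns the 8 feature
intensities per interrogated position into a homozygous call, a
heterozygous (IUPAC) call, or a no-call (N):

* both strands must rank the same base first with a peak/second ratio of
  at least ``r_call`` for a homozygous call;
* failing that, both strands must rank the same unordered base pair in
  the top two with a second/third ratio of at least ``r_het`` for a
  heterozygous call (by default the pair must contain the reference
  base, appropriate to a recessive-disease screen);
* the call's quality is the weaker strand's log2 ratio, and calls below
  ``q_min`` are demoted to N.

This is a simple stand-in for commercial array base callers built on the
adaptive-background genotyping scheme; it is intentionally conservative
so that ambiguity lands in no-calls rather than in miscalls, which is the
regime the no-call rescue step is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ArrayDesign, BASES, HET_CODES, Quartet
from .simulate import SampleIntensities

__all__ = ["CallParams", "BaseCall", "call_position", "call_array", "strand_evidence"]

N_CALL = "N"
CALL_COLUMNS = ["array_id", "pos", "ref", "call", "quality", "source", "flags"]


@dataclass(frozen=True)
class CallParams:
    r_call: float = 1.5          # min peak/second ratio per strand, hom call
    r_het: float = 1.3           # min second/third ratio per strand, het call
    q_min: float = 3.0           # min quality (log2 ratio scale) to emit a call
    het_must_contain_ref: bool = True
    floor_frac: float = 1e-6     # intensity floor as a fraction of the array median

    def __post_init__(self) -> None:
        if self.r_call <= 1 or self.r_het <= 1:
            raise ValueError("ratio thresholds must exceed 1")
        if self.q_min < 0:
            raise ValueError("q_min must be non-negative")


@dataclass
class BaseCall:
    """One position's call with quality and provenance.

    ``call`` is a base letter, an IUPAC het code, or ``"N"``.  For a
    no-call, ``quality`` records the best score any calling route
    achieved, so downstream quality filters see how close the position
    came to being called.
    """

    pos: int
    ref: str | None
    call: str
    quality: float
    source: str = "primary"
    flags: set[str] = field(default_factory=set)

    @property
    def is_nocall(self) -> bool:
        return self.call == N_CALL

    @property
    def is_variant(self) -> bool:
        return self.call != N_CALL and self.call != self.ref


def _rank(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stable descending order and sorted values (ties -> lower base index)."""
    order = np.argsort(-vals, kind="stable")
    return order, vals[order]


def call_position(
    fwd: Quartet,
    rev: Quartet,
    params: CallParams,
    ref_base: str | None = None,
    pos: int = -1,
) -> BaseCall:
    """Call a single position from its two strand quartets.

    Pure-Python reference implementation of the decision rule; the
    batch path :func:`call_array` is checked against it.
    """
    vals = np.stack([fwd.values, rev.values]).astype(float)
    med = float(np.median(vals))
    if med <= 0:
        return BaseCall(pos=pos, ref=ref_base, call=N_CALL, quality=0.0)
    vals = np.maximum(vals, params.floor_frac * med)

    orders, sortvals = zip(*(_rank(vals[s]) for s in (0, 1)))
    r1 = [sortvals[s][0] / sortvals[s][1] for s in (0, 1)]
    r2 = [sortvals[s][1] / sortvals[s][2] for s in (0, 1)]
    peaks = [int(orders[s][0]) for s in (0, 1)]
    pairs = [frozenset(int(b) for b in orders[s][:2]) for s in (0, 1)]
    ref_idx = BASES.index(ref_base) if ref_base is not None else None

    q_hom = min(np.log2(r1)) if peaks[0] == peaks[1] else None
    het_allowed = pairs[0] == pairs[1] and (
        not params.het_must_contain_ref or ref_idx is None or ref_idx in pairs[0]
    )
    q_het = min(np.log2(r2)) if het_allowed else None

    if peaks[0] == peaks[1] and all(r >= params.r_call for r in r1):
        call, quality = BASES[peaks[0]], q_hom
    elif het_allowed and all(r >= params.r_het for r in r2):
        call = HET_CODES[frozenset(BASES[b] for b in pairs[0])]
        quality = q_het
    else:
        call, quality = N_CALL, None
    if quality is not None and quality < params.q_min:
        call = N_CALL
    if quality is None:
        quality = max((q for q in (q_hom, q_het) if q is not None), default=0.0)
    return BaseCall(pos=pos, ref=ref_base, call=call, quality=float(quality))


def strand_evidence(
    sample: SampleIntensities, params: CallParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-strand ranking evidence for every position.

    Returns ``(peak, r1, r2)`` with shapes (n, 2), (n, 2), (n, 2):
    peak-base index, peak/second ratio and second/third ratio per strand,
    after applying the intensity floor.  This is the shared statistic the
    caller and the no-call rescue both consume.
    """
    v = np.asarray(sample.values, dtype=float)
    med = float(np.median(v))
    floor = params.floor_frac * med if med > 0 else np.finfo(float).tiny
    v = np.maximum(v, floor)
    order = np.argsort(-v, axis=2, kind="stable")
    sv = np.take_along_axis(v, order, axis=2)
    r1 = sv[:, :, 0] / sv[:, :, 1]
    r2 = sv[:, :, 1] / sv[:, :, 2]
    return order[:, :, 0], r1, r2


def call_array(
    sample: SampleIntensities, design: ArrayDesign, params: CallParams | None = None
) -> pd.DataFrame:
    """Call every position of one array; rows align with the design.

    Returns the standard call table with columns
    ``array_id, pos, ref, call, quality, source, flags``.
    """
    params = params or CallParams()
    v = np.asarray(sample.values, dtype=float)
    n = design.n_positions
    if v.shape != (n, 2, 4):
        raise ValueError("sample intensities do not align with the design")
    med = float(np.median(v))
    floor = params.floor_frac * med if med > 0 else np.finfo(float).tiny
    v = np.maximum(v, floor)

    order = np.argsort(-v, axis=2, kind="stable")
    sv = np.take_along_axis(v, order, axis=2)
    r1 = sv[:, :, 0] / sv[:, :, 1]
    r2 = sv[:, :, 1] / sv[:, :, 2]
    peak = order[:, :, 0]
    pair = np.sort(order[:, :, :2], axis=2)

    q_hom = np.log2(r1).min(axis=1)
    q_het = np.log2(r2).min(axis=1)
    peak_agree = peak[:, 0] == peak[:, 1]
    pair_agree = (pair[:, 0, :] == pair[:, 1, :]).all(axis=1)
    ref = design.ref_idx
    if params.het_must_contain_ref:
        pair_agree &= (pair[:, 0, 0] == ref) | (pair[:, 0, 1] == ref)

    hom_sel = peak_agree & (r1 >= params.r_call).all(axis=1)
    het_sel = ~hom_sel & pair_agree & (r2 >= params.r_het).all(axis=1)

    base_arr = np.array(list(BASES))
    het_lut = np.full((4, 4), N_CALL, dtype=object)
    for fs, code in HET_CODES.items():
        b1, b2 = sorted(BASES.index(b) for b in fs)
        het_lut[b1, b2] = het_lut[b2, b1] = code

    call = np.full(n, N_CALL, dtype=object)
    quality = np.where(peak_agree, q_hom, -np.inf)
    quality = np.maximum(quality, np.where(pair_agree, q_het, -np.inf))
    quality = np.where(np.isfinite(quality), quality, 0.0)
    call[hom_sel] = base_arr[peak[hom_sel, 0]]
    quality[hom_sel] = q_hom[hom_sel]
    call[het_sel] = het_lut[pair[het_sel, 0, 0], pair[het_sel, 0, 1]]
    quality[het_sel] = q_het[het_sel]
    call[quality < params.q_min] = N_CALL
    # all-zero quartets carry no evidence at all
    dead = (np.asarray(sample.values) <= 0).all(axis=(1, 2))
    call[dead] = N_CALL
    quality[dead] = 0.0

    return pd.DataFrame(
        {
            "array_id": sample.array_id,
            "pos": design.positions,
            "ref": base_arr[ref],
            "call": call,
            "quality": quality,
            "source": "primary",
            "flags": "",
        },
        columns=CALL_COLUMNS,
    )


def is_variant_call(calls: pd.DataFrame) -> np.ndarray:
    """Boolean mask of variant calls (non-N, differing from the reference)."""
    return (calls["call"] != N_CALL).to_numpy() & (calls["call"] != calls["ref"]).to_numpy()


def is_nocall(calls: pd.DataFrame) -> np.ndarray:
    return (calls["call"] == N_CALL).to_numpy()
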