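"""False-positive screens for variant calls.

Two post-hoc filters, applied to the call table after (optional) no-call
resolution:

* **density** — a variant call surrounded by many other variant calls or
  no-calls is likely a hybridization artifact (or an indel shadow), not
  an isolated substitution;
* **lowq** — a variant call whose quality score is below threshold.

Filtered variant calls are demoted to N — which routes them to
confirmatory sequencing — and keep a flag recording why; they are never
silently dropped.  Wild-type calls and no-calls pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .caller import N_CALL, is_variant_call
from .design import ArrayDesign
from .sprofiler import _add_flag

__all__ = ["FilterParams", "density_filter", "quality_filter", "apply_filters"]


@dataclass(frozen=True)
class FilterParams:
    window: int = 25          # centred window (bases) for the density screen
    max_neighbors: int = 2    # max variant+N neighbours (excluding self) allowed
    q_filter: float = 3.0     # min quality for a variant call to survive

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if self.max_neighbors < 0:
            raise ValueError("max_neighbors must be >= 0")


def _demote(calls: pd.DataFrame, mask: np.ndarray, flag: str) -> pd.DataFrame:
    out = calls.copy()
    call_col = out["call"].to_numpy(dtype=object)
    flag_col = out["flags"].to_numpy(dtype=object)
    for i in np.flatnonzero(mask):
        call_col[i] = N_CALL
        flag_col[i] = _add_flag(flag_col[i], flag)
    out["call"], out["flags"] = call_col, flag_col
    return out


def density_filter(
    calls: pd.DataFrame, design: ArrayDesign, params: FilterParams | None = None
) -> pd.DataFrame:
    """Flag variant calls in windows rich in variant calls and no-calls.

    Counts variant-or-N positions (excluding the call itself) in a
    centred window of ``params.window`` bases; windows are truncated at
    tiled-fragment boundaries.  Calls with more than
    ``params.max_neighbors`` such neighbours gain flag ``density`` and
    are demoted to N.
    """
    params = params or FilterParams()
    variant = is_variant_call(calls)
    bad = variant | (calls["call"] == N_CALL).to_numpy()
    h = (params.window - 1) // 2
    counts = _window_sums(bad.astype(np.int64), design.fragment_id, h) - bad
    return _demote(calls, variant & (counts > params.max_neighbors), "density")


def _window_sums(x: np.ndarray, fragment_id: np.ndarray, h: int) -> np.ndarray:
    """Centred +/-h window sums of x, truncated at fragment boundaries."""
    out = np.empty_like(x)
    for fid in np.unique(fragment_id):
        sel = fragment_id == fid
        xs = x[sel]
        cs = np.concatenate([[0], np.cumsum(xs)])
        idx = np.arange(len(xs))
        lo = np.maximum(idx - h, 0)
        hi = np.minimum(idx + h + 1, len(xs))
        out[sel] = cs[hi] - cs[lo]
    return out


def quality_filter(calls: pd.DataFrame, params: FilterParams | None = None) -> pd.DataFrame:
    """Flag variant calls with quality below ``params.q_filter`` as ``lowq``."""
    params = params or FilterParams()
    lowq = is_variant_call(calls) & (calls["quality"].to_numpy() < params.q_filter)
    return _demote(calls, lowq, "lowq")


def apply_filters(
    calls: pd.DataFrame, design: ArrayDesign, params: FilterParams | None = None
) -> pd.DataFrame:
    """Density screen, then quality screen."""
    params = params or FilterParams()
    return quality_filter(density_filter(calls, design, params), params)
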