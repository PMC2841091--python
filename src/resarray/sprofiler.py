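"""sPROFILER: strand-specific no-call rescue for resequencing arrays.

Primary array callers are conservative: when either strand's probe
quartet hybridizes poorly (typically because that strand's probe is
G-rich or carries a G-stack), the position becomes a no-call even though
the other strand shows an unambiguous wild-type signature.  sPROFILER
re-examines those no-calls using single-strand evidence:

1.  Per-strand thresholds are learned from the array itself: the
    peak/second intensity ratios of all wild-type-called bases on that
    strand, summarized by a low quantile ``q`` (default 0.05), so a
    rescued strand must look at least as clean as the bulk of genuine
    wild-type signatures.
2.  The threshold is scaled per position by the batch-wide wild-type
    proportion ``w(p)``: ``t_eff = t * (1 + alpha * (1 - w))``.  At a
    position that is frequently called variant across arrays the
    algorithm therefore demands stronger evidence before assigning
    wild-type, and vice versa.
3.  A no-call whose peak base equals the reference on at least one
    strand with ratio >= ``t_eff`` is converted to wild-type.  Wild-type
    calls *inside no-call stretches* (a hallmark of indels) are first
    re-examined under a stricter two-strand rule and demoted to N when
    they fail.  No other existing call is ever touched.

An optional mode additionally assigns a homozygous variant call when a
single alternate base dominates one strand and the other strand does not
contradict it; such calls are always flagged for confirmation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .caller import CallParams, N_CALL, strand_evidence
from .design import ArrayDesign, BASES
from .simulate import SampleIntensities

__all__ = [
    "ThresholdModel",
    "FittingError",
    "fit_thresholds",
    "fit_threshold_model",
    "wildtype_proportion",
    "resolve_no_calls",
    "reexamine_wildtype_in_stretches",
    "apply_sprofiler",
]

logger = logging.getLogger(__name__)

LOG_COLUMNS = ["array_id", "pos", "old_call", "new_call", "strand_used", "ratio", "t_eff", "w"]
MIN_WILDTYPE_RATIOS = 100


class FittingError(RuntimeError):
    """Too little wild-type signal to learn thresholds from."""


@dataclass
class ThresholdModel:
    """Per-strand rescue thresholds plus cross-array wild-type proportions.

    ``w`` is aligned to the design's position index; missing entries
    (NaN) are treated as the uninformative 0.5.
    """

    t_fwd: float
    t_rev: float
    q: float = 0.05
    alpha: float = 1.0
    w: np.ndarray | None = None

    def t_eff(self, design: ArrayDesign) -> np.ndarray:
        """Effective per-position, per-strand thresholds, shape (n, 2)."""
        if self.w is None:
            w = np.full(design.n_positions, 0.5)
        else:
            w = np.asarray(self.w, dtype=float)
            if len(w) != design.n_positions:
                raise ValueError("wild-type proportions do not align with the design")
            if np.isnan(w).any():
                logger.warning(
                    "%d positions missing a wild-type proportion; using w=0.5",
                    int(np.isnan(w).sum()),
                )
                w = np.where(np.isnan(w), 0.5, w)
        scale = 1.0 + self.alpha * (1.0 - w)
        return np.stack([self.t_fwd * scale, self.t_rev * scale], axis=1)


def fit_thresholds(
    sample: SampleIntensities,
    calls: pd.DataFrame,
    design: ArrayDesign,
    q: float = 0.05,
    params: CallParams | None = None,
) -> tuple[float, float]:
    """Learn per-strand peak/second ratio thresholds from wild-type bases.

    For each strand, collects the peak/second ratio at every position the
    primary caller labelled wild-type and whose peak base on that strand
    equals the reference, and returns the empirical ``q``-quantile
    (linear interpolation between order statistics).
    """
    if not (0 < q <= 0.5):
        raise ValueError(f"quantile q must lie in (0, 0.5], got {q}")
    peak, r1, _ = strand_evidence(sample, params or CallParams())
    ref = design.ref_idx
    wildtype = (calls["call"] == calls["ref"]).to_numpy()
    out = []
    for s in range(2):
        ratios = r1[wildtype & (peak[:, s] == ref), s]
        if len(ratios) < MIN_WILDTYPE_RATIOS:
            raise FittingError(
                f"only {len(ratios)} wild-type ratios on strand {s}; "
                f"need >= {MIN_WILDTYPE_RATIOS}"
            )
        out.append(float(np.quantile(ratios, q)))
    return out[0], out[1]


def wildtype_proportion(batch_calls: Sequence[pd.DataFrame]) -> np.ndarray:
    """Laplace-smoothed per-position wild-type proportion across a batch.

    ``w(p) = (#arrays called wild-type at p + 1) / (#arrays called at p + 2)``,
    so w is strictly inside (0, 1) and uncalled positions get 0.5.
    """
    if len(batch_calls) < 2:
        raise ValueError("wild-type proportions need at least 2 arrays")
    wt = np.zeros(len(batch_calls[0]))
    called = np.zeros(len(batch_calls[0]))
    for calls in batch_calls:
        wt += (calls["call"] == calls["ref"]).to_numpy()
        called += (calls["call"] != N_CALL).to_numpy()
    return (wt + 1.0) / (called + 2.0)


def fit_threshold_model(
    sample: SampleIntensities,
    calls: pd.DataFrame,
    batch_calls: Sequence[pd.DataFrame],
    design: ArrayDesign,
    q: float = 0.05,
    alpha: float = 1.0,
    params: CallParams | None = None,
) -> ThresholdModel:
    """Fit thresholds on one array and w on its batch (the standard recipe)."""
    t_fwd, t_rev = fit_thresholds(sample, calls, design, q=q, params=params)
    return ThresholdModel(
        t_fwd=t_fwd, t_rev=t_rev, q=q, alpha=alpha, w=wildtype_proportion(batch_calls)
    )


def resolve_no_calls(
    sample: SampleIntensities,
    calls: pd.DataFrame,
    model: ThresholdModel,
    design: ArrayDesign,
    mode: str = "wildtype_only",
    params: CallParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve primary no-calls from single-strand evidence.

    Returns the updated call table and a resolution log with one row per
    examined no-call.  Existing non-N calls are never modified.  In
    ``with_variant_assign`` mode, no-calls that fail the wild-type test
    but show a single dominant alternate base on a passing strand (with
    no contradicting strand) are assigned a homozygous variant call
    flagged ``requires_confirmation``.
    """
    if mode not in ("wildtype_only", "with_variant_assign"):
        raise ValueError(f"unknown mode {mode!r}")
    peak, r1, _ = strand_evidence(sample, params or CallParams())
    ref = design.ref_idx
    teff = model.t_eff(design)
    w = model.w if model.w is not None else np.full(design.n_positions, 0.5)
    w = np.where(np.isnan(np.asarray(w, dtype=float)), 0.5, w)

    out = calls.copy()
    nmask = (calls["call"] == N_CALL).to_numpy()
    passes = r1 >= teff                       # (n, 2)
    peak_is_ref = peak == ref[:, None]
    wt_pass = passes & peak_is_ref

    log_rows: list[tuple] = []
    call_col = out["call"].to_numpy(dtype=object)
    qual_col = out["quality"].to_numpy(dtype=float)
    src_col = out["source"].to_numpy(dtype=object)
    flag_col = out["flags"].to_numpy(dtype=object)
    base_arr = np.array(list(BASES))

    for i in np.flatnonzero(nmask):
        new_call, strand_used, ratio = N_CALL, "", np.nan
        if wt_pass[i, 0] or wt_pass[i, 1]:
            s = 0 if (wt_pass[i, 0] and (not wt_pass[i, 1] or r1[i, 0] >= r1[i, 1])) else 1
            new_call, strand_used, ratio = base_arr[ref[i]], ("fwd", "rev")[s], float(r1[i, s])
        elif mode == "with_variant_assign":
            passing = [s for s in range(2) if passes[i, s]]
            alts = {int(peak[i, s]) for s in passing}
            if passing and len(alts) == 1 and int(peak[i, passing[0]]) != ref[i]:
                b = alts.pop()
                s = max(passing, key=lambda s: r1[i, s])
                new_call, strand_used, ratio = base_arr[b], ("fwd", "rev")[s], float(r1[i, s])
                flag_col[i] = _add_flag(flag_col[i], "requires_confirmation")
        if new_call != N_CALL:
            call_col[i] = new_call
            qual_col[i] = float(np.log2(ratio))
            src_col[i] = "sprofiler"
        log_rows.append(
            (
                sample.array_id, int(design.positions[i]), N_CALL, new_call,
                strand_used, ratio, float(teff[i, 0 if strand_used != "rev" else 1]),
                float(w[i]),
            )
        )
    out["call"], out["quality"], out["source"], out["flags"] = (
        call_col, qual_col, src_col, flag_col,
    )
    log = pd.DataFrame(log_rows, columns=LOG_COLUMNS)
    return out, log


def _add_flag(flags: str, flag: str) -> str:
    existing = [f for f in str(flags).split(",") if f]
    if flag not in existing:
        existing.append(flag)
    return ",".join(existing)


def _nocall_runs(nmask: np.ndarray, fragment_id: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Index intervals [i0, i1] of no-call stretches.

    A stretch is a maximal group of no-calls within one fragment whose
    consecutive members are separated by at most one called position
    (isolated interruptions allowed), containing >= min_run no-calls.
    """
    idx = np.flatnonzero(nmask)
    runs: list[tuple[int, int]] = []
    if len(idx) == 0:
        return runs
    start = prev = idx[0]
    count = 1
    for i in idx[1:]:
        if i - prev <= 2 and fragment_id[i] == fragment_id[start]:
            prev = i
            count += 1
        else:
            if count >= min_run:
                runs.append((int(start), int(prev)))
            start = prev = i
            count = 1
    if count >= min_run:
        runs.append((int(start), int(prev)))
    return runs


def reexamine_wildtype_in_stretches(
    sample: SampleIntensities,
    calls: pd.DataFrame,
    model: ThresholdModel,
    design: ArrayDesign,
    min_run: int = 5,
    params: CallParams | None = None,
) -> pd.DataFrame:
    """Demote suspect wild-type calls inside no-call stretches.

    Wild-type calls interrupting a stretch of >= ``min_run`` no-calls are
    re-tested under a stricter rule — both strands must rank the
    reference first with ratio >= ``t_eff`` — and demoted to N when they
    fail.  Wild-type calls outside stretches are never touched.  This
    runs *before* no-call resolution so stretch boundaries are decided on
    primary calls only.
    """
    peak, r1, _ = strand_evidence(sample, params or CallParams())
    ref = design.ref_idx
    teff = model.t_eff(design)
    both_pass = ((r1 >= teff) & (peak == ref[:, None])).all(axis=1)

    out = calls.copy()
    nmask = (calls["call"] == N_CALL).to_numpy()
    wt = (calls["call"] == calls["ref"]).to_numpy()
    call_col = out["call"].to_numpy(dtype=object)
    flag_col = out["flags"].to_numpy(dtype=object)
    for i0, i1 in _nocall_runs(nmask, design.fragment_id, min_run):
        for i in range(i0 + 1, i1):
            if wt[i] and not both_pass[i]:
                call_col[i] = N_CALL
                flag_col[i] = _add_flag(flag_col[i], "stretch_reexam")
    out["call"], out["flags"] = call_col, flag_col
    return out


def apply_sprofiler(
    sample: SampleIntensities,
    calls: pd.DataFrame,
    model: ThresholdModel,
    design: ArrayDesign,
    mode: str = "wildtype_only",
    min_run: int = 5,
    params: CallParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full sPROFILER pass: stretch re-examination, then no-call resolution."""
    reexamined = reexamine_wildtype_in_stretches(
        sample, calls, model, design, min_run=min_run, params=params
    )
    return resolve_no_calls(sample, reexamined, model, design, mode=mode, params=params)
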