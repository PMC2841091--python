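"""Performance metrics versus truth and follow-up triage.

Metric conventions (chosen to make coexisting high call rates and high
accuracies meaningful, and to keep zygosity errors from polluting the
false-positive/negative rates):

* **call rate** — percent of interrogated bases assigned any call;
* **accuracy** — percent of *called* bases concordant with truth
  (no-calls are excluded from the denominator);
* **false positive** — a variant call at a truly homozygous-reference
  base; the headline FP rate uses all interrogated bases as denominator,
  the variant FP rate uses all variant calls;
* **false negative** — a true variant called wild-type;
* **het/hom miss** — a variant call at a true variant site that has the
  wrong zygosity or allele; tracked as its own category, not as FP/FN.

Exon triage counts the exons containing at least one no-call or one
(unconfirmed) variant call — the exons a clinical workflow would submit
to confirmatory dideoxy sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .caller import N_CALL, is_variant_call
from .design import ArrayDesign
from .simulate import SampleIntensities, TruthGenotype

__all__ = [
    "PerformanceReport",
    "call_rate",
    "compare_to_truth",
    "exons_to_sequence",
    "gstack_intensity_summary",
    "batch_table",
]

BREAKDOWN_CATEGORIES = ("correct", "no_call", "het_hom_miss", "called_wildtype")


def call_rate(n_nocalls: int, n_bases: int) -> float:
    """Percent of interrogated bases called, to one decimal."""
    if n_bases <= 0:
        raise ValueError("n_bases must be positive")
    if not (0 <= n_nocalls <= n_bases):
        raise ValueError("n_nocalls must lie in [0, n_bases]")
    return round(100.0 * (1.0 - n_nocalls / n_bases), 1)


@dataclass
class PerformanceReport:
    n_bases: int
    n_nocalls: int
    call_rate: float
    accuracy: float
    fp_total: int
    fp_total_pct: float
    fn_total: int
    n_variant_calls: int
    n_true_variants: int
    variant_fp_rate: float
    variant_fn_rate: float
    variant_breakdown: dict = field(default_factory=dict)
    exons_followup: int = 0
    exons_total: int = 0

    def to_series(self) -> pd.Series:
        flat = {
            k: v for k, v in self.__dict__.items() if not isinstance(v, dict)
        }
        for cls, cats in self.variant_breakdown.items():
            for cat, count in cats.items():
                flat[f"{cls}_{cat}"] = count
        return pd.Series(flat)


def compare_to_truth(
    calls: pd.DataFrame, truth: TruthGenotype, design: ArrayDesign
) -> PerformanceReport:
    """Score one array's call table against its simulated truth."""
    if len(calls) != design.n_positions:
        raise ValueError("calls do not align with the design")
    calls = calls.sort_values("pos", kind="stable").reset_index(drop=True)
    if not np.array_equal(calls["pos"].to_numpy(), design.positions):
        raise ValueError("call positions do not match the design")
    truth_str = truth.call_string(design)
    call = calls["call"].to_numpy(dtype=object)
    ref = calls["ref"].to_numpy(dtype=object)
    called = call != N_CALL
    variant_call = is_variant_call(calls)
    true_variant = truth.zygosity > 0

    n_bases = len(calls)
    n_nocalls = int((~called).sum())
    concordant = called & (call == truth_str)
    n_called = int(called.sum())
    accuracy = 100.0 * concordant.sum() / n_called if n_called else 0.0

    fp = int((variant_call & ~true_variant).sum())
    fn = int((true_variant & called & (call == ref)).sum())
    n_vcalls = int(variant_call.sum())
    n_tv = int(true_variant.sum())

    breakdown: dict[str, dict[str, int]] = {}
    for cls, cls_mask in (("common", truth.is_common), ("rare", ~truth.is_common)):
        tv = true_variant & cls_mask
        breakdown[cls] = {
            "correct": int((tv & (call == truth_str)).sum()),
            "no_call": int((tv & ~called).sum()),
            "called_wildtype": int((tv & called & (call == ref)).sum()),
            "het_hom_miss": int(
                (tv & called & (call != truth_str) & (call != ref)).sum()
            ),
        }

    exons_followup, exons_total = exons_to_sequence(calls, design)
    return PerformanceReport(
        n_bases=n_bases,
        n_nocalls=n_nocalls,
        call_rate=call_rate(n_nocalls, n_bases),
        accuracy=accuracy,
        fp_total=fp,
        fp_total_pct=100.0 * fp / n_bases,
        fn_total=fn,
        n_variant_calls=n_vcalls,
        n_true_variants=n_tv,
        variant_fp_rate=100.0 * fp / n_vcalls if n_vcalls else 0.0,
        variant_fn_rate=100.0 * fn / n_tv if n_tv else 0.0,
        variant_breakdown=breakdown,
        exons_followup=exons_followup,
        exons_total=exons_total,
    )


def exons_to_sequence(calls: pd.DataFrame, design: ArrayDesign) -> tuple[int, int]:
    """(exons needing follow-up sequencing, total exons on the array).

    An exon needs follow-up iff it contains at least one no-call or one
    variant call.
    """
    flagged = (calls["call"] == N_CALL).to_numpy() | is_variant_call(calls)
    exons = pd.Series(design.exon_of)
    followup = exons[flagged].nunique()
    return int(followup), int(exons.nunique())


class GStackSummary(NamedTuple):
    """Grouped peak-intensity tables for content/stack diagnostics."""

    by_content: pd.DataFrame    # grouped by (g_count, c_count) of the match probe
    by_stack: pd.DataFrame      # grouped by (g_count, stack_class)


def gstack_intensity_summary(
    sample: SampleIntensities, design: ArrayDesign
) -> GStackSummary:
    """Mean/SD quartet peak intensity by match-probe composition.

    Each (position, strand) quartet contributes its peak intensity,
    attributed to the composition of that strand's reference-matching
    probe.  ``stack_class`` is ``g_stack`` when the match probe carries a
    run of >= 4 Gs, else ``c_stack`` for a run of >= 4 Cs, else ``none``.
    """
    stats = design.feature_stats()
    ref = design.ref_idx
    idx = np.arange(design.n_positions)
    peaks = sample.values.max(axis=2)               # (n, 2)
    rows = []
    for s in range(2):
        g = stats.g_count[idx, s, ref]
        c = stats.c_count[idx, s, ref]
        gs = stats.g_stack[idx, s, ref]
        # a probe's C-stack is the G-stack of its reverse complement
        cs = stats.g_stack[idx, 1 - s, ref]
        stack = np.where(gs, "g_stack", np.where(cs, "c_stack", "none"))
        rows.append(
            pd.DataFrame(
                {"strand": ("fwd", "rev")[s], "g_count": g, "c_count": c,
                 "stack_class": stack, "peak": peaks[:, s]}
            )
        )
    df = pd.concat(rows, ignore_index=True)
    by_content = (
        df.groupby(["g_count", "c_count"])["peak"]
        .agg(n="size", mean_peak="mean", sd_peak="std")
        .reset_index()
    )
    by_stack = (
        df.groupby(["g_count", "stack_class"])["peak"]
        .agg(n="size", mean_peak="mean", sd_peak="std")
        .reset_index()
    )
    return GStackSummary(by_content=by_content, by_stack=by_stack)


def batch_table(reports: Sequence[PerformanceReport]) -> pd.DataFrame:
    """One row per array plus a per-array-average row, Table-style."""
    df = pd.DataFrame([r.to_series() for r in reports])
    mean = df.mean(numeric_only=True)
    mean.name = "mean"
    return pd.concat([df, mean.to_frame().T])
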