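"""Synthetic hybridization model for resequencing arrays.

Generates per-feature fluorescence intensities for a batch of simulated
arrays, with the sequence- and genotype-dependent effects that dominate
real probe behaviour:

* probe affinity decays with G-content more steeply than with C-content,
  and a run of >= 4 consecutive Gs (a "G-stack") imposes an extra
  multiplicative penalty — so a position whose forward probe carries a
  G-stack typically still hybridizes well on the reverse strand, whose
  probe carries the complementary C-stack;
* mismatch features receive a cross-hybridization fraction of the signal;
* heterozygous alleles each contribute a configurable dosage (default
  50%) of the homozygous signal;
* an indel abolishes the match of every probe whose footprint overlaps
  the event and can depress signal multiplicatively over a surrounding
  window.

Intensities are background + signal, both lognormal, so they are
positive, right-skewed and heavy-tailed enough to produce realistic
primary-caller no-calls.  Everything is driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import ArrayDesign, BASES, HET_CODES, probe_stats

__all__ = [
    "SimParams",
    "Indel",
    "TruthGenotype",
    "SampleIntensities",
    "affinity",
    "affinity_matrix",
    "simulate_batch",
    "sample_truths",
    "random_reference",
]

@dataclass(frozen=True)
class SimParams:
    """Hybridization-model parameters.

    Defaults are calibrated so that a default batch (24 arrays, ~26,000
    interrogated bases) yields a primary-caller no-call rate of roughly
    2-3%, dominated by strand-asymmetric G-stack failures — the regime in
    which single-strand no-call rescue is useful.
    """

    signal_scale: float = 4000.0       # full-match signal before affinity
    background_mean: float = 25.0      # median additive background (a.u.)
    background_sd: float = 0.30        # lognormal shape of the background
    beta_g: float = 0.10               # per-G affinity penalty (log scale)
    beta_c: float = 0.01               # per-C affinity penalty (log scale)
    beta_stack: float = 0.20           # multiplicative G-stack penalty factor
    cross_hyb: float = 0.015           # mismatch leakage fraction
    noise_cv: float = 0.22             # multiplicative lognormal noise CV
    het_fraction: float = 0.5          # per-allele dosage in heterozygotes
    indel_drop: float = 1.0            # regional multiplier around indels
    indel_halfwidth: int = 10          # half-width (bases) of the drop window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta_g <= self.beta_c:
            raise ValueError("beta_g must exceed beta_c (G-richness hurts more)")
        if not (0 <= self.cross_hyb < 1):
            raise ValueError("cross_hyb must lie in [0, 1)")
        if not (0 < self.beta_stack <= 1):
            raise ValueError("beta_stack is a multiplicative factor in (0, 1]")
        if not (0 < self.indel_drop <= 1):
            raise ValueError("indel_drop must lie in (0, 1]")


@dataclass(frozen=True)
class Indel:
    """Homozygous insertion/deletion event.

    ``start == end`` with a non-empty ``seq`` is an insertion at that
    breakpoint; ``end > start`` is a deletion of the half-open interval.
    """

    start: int
    end: int
    seq: str = ""

    @property
    def is_deletion(self) -> bool:
        return self.end > self.start


@dataclass
class TruthGenotype:
    """Ground-truth genotypes for one simulated array.

    Arrays are aligned to the design's position index: ``zygosity`` is
    0 = hom-ref, 1 = het(ref, alt), 2 = hom-alt; ``alt_idx`` holds the
    alternate-base index (255 where hom-ref); ``is_common`` marks variant
    positions whose site segregates across the batch (vs rare singletons).
    """

    zygosity: np.ndarray
    alt_idx: np.ndarray
    is_common: np.ndarray
    indels: list[Indel] = field(default_factory=list)

    def n_variants(self) -> int:
        return int(np.count_nonzero(self.zygosity > 0))

    def call_string(self, design: ArrayDesign) -> np.ndarray:
        """Truth rendered in caller vocabulary: base letter or IUPAC het code."""
        ref = design.ref_idx
        out = np.empty(design.n_positions, dtype=object)
        for i in range(design.n_positions):
            z = self.zygosity[i]
            if z == 0:
                out[i] = BASES[ref[i]]
            elif z == 2:
                out[i] = BASES[self.alt_idx[i]]
            else:
                out[i] = HET_CODES[frozenset({BASES[ref[i]], BASES[self.alt_idx[i]]})]
        return out


@dataclass
class SampleIntensities:
    """Per-feature intensities for one array: shape (n_positions, 2, 4).

    Axis 1 is strand (0=fwd, 1=rev); axis 2 the substituted base, keyed on
    the forward strand for both strands.
    """

    array_id: str
    values: np.ndarray

    def peak_per_position(self) -> np.ndarray:
        """Max over all 8 features per position."""
        return self.values.reshape(self.values.shape[0], -1).max(axis=1)


def affinity(probe: str, params: SimParams) -> float:
    """Hybridization affinity of one probe, in (0, 1].

    ``exp(-beta_g * g_count - beta_c * c_count)``, multiplied by
    ``beta_stack`` when the probe contains a G-stack (>= 4 consecutive Gs).
    """
    st = probe_stats(probe)
    a = float(np.exp(-params.beta_g * st.g_count - params.beta_c * st.c_count))
    if st.has_g_stack:
        a *= params.beta_stack
    return a


def affinity_matrix(design: ArrayDesign, params: SimParams) -> np.ndarray:
    """Affinity of every feature, shape (n_positions, 2, 4)."""
    st = design.feature_stats()
    aff = np.exp(-params.beta_g * st.g_count - params.beta_c * st.c_count)
    aff[st.g_stack] *= params.beta_stack
    return aff


def _dosage_matrix(design: ArrayDesign, truth: TruthGenotype, params: SimParams) -> np.ndarray:
    """Allele dosage per (position, base): rows for hom sum to 1, het to 2*het_fraction."""
    n = design.n_positions
    dos = np.zeros((n, 4))
    idx = np.arange(n)
    ref = design.ref_idx
    hom_ref = truth.zygosity == 0
    dos[idx[hom_ref], ref[hom_ref]] = 1.0
    het = truth.zygosity == 1
    dos[idx[het], ref[het]] = params.het_fraction
    dos[idx[het], truth.alt_idx[het]] += params.het_fraction
    hom_alt = truth.zygosity == 2
    dos[idx[hom_alt], truth.alt_idx[hom_alt]] = 1.0
    # probes overlapping an indel footprint match no allele
    k = design.flank
    for ev in truth.indels:
        if ev.is_deletion:
            hit = (design.positions + k >= ev.start) & (design.positions - k < ev.end)
        else:
            hit = (design.positions >= ev.start - k) & (design.positions <= ev.start + k - 1)
        dos[hit, :] = 0.0
    return dos


def _regional_factor(design: ArrayDesign, truth: TruthGenotype, params: SimParams) -> np.ndarray:
    reg = np.ones(design.n_positions)
    h = params.indel_halfwidth
    for ev in truth.indels:
        hit = (design.positions >= ev.start - h) & (design.positions < ev.end + h)
        reg[hit] *= params.indel_drop
    return reg


def simulate_one(
    design: ArrayDesign,
    truth: TruthGenotype,
    params: SimParams,
    rng: np.random.Generator,
    array_id: str,
) -> SampleIntensities:
    """Simulate one array's 8 features per position."""
    aff = affinity_matrix(design, params)
    dos = _dosage_matrix(design, truth, params)
    total = dos.sum(axis=1, keepdims=True)
    match = dos + params.cross_hyb * (total - dos)       # (n, 4)
    match = match[:, None, :]                            # both strands identical
    reg = _regional_factor(design, truth, params)[:, None, None]

    shape = (design.n_positions, 2, 4)
    bg = rng.lognormal(np.log(params.background_mean), params.background_sd, size=shape)
    if params.noise_cv > 0:
        s = np.sqrt(np.log1p(params.noise_cv**2))
        noise = rng.lognormal(-0.5 * s * s, s, size=shape)
    else:
        noise = 1.0
    values = bg + params.signal_scale * aff * match * reg * noise
    return SampleIntensities(array_id=array_id, values=values)


def simulate_batch(
    design: ArrayDesign,
    truths: Sequence[TruthGenotype],
    params: SimParams,
) -> list[SampleIntensities]:
    """Simulate a batch, one array per truth genotype.

    The global seed is expanded into independent per-array substreams, so
    the batch is bit-reproducible and individual arrays are independent of
    the batch size ordering.
    """
    for t in truths:
        if len(t.zygosity) != design.n_positions:
            raise ValueError("truth genotype does not align with the design")
        if (t.zygosity > 0).any() and (t.alt_idx[t.zygosity > 0] == design.ref_idx[t.zygosity > 0]).any():
            raise ValueError("alternate base equals the reference base")
    children = np.random.SeedSequence(params.seed).spawn(len(truths))
    return [
        simulate_one(design, t, params, np.random.default_rng(child), f"array_{i:03d}")
        for i, (t, child) in enumerate(zip(truths, children))
    ]


def sample_truths(
    design: ArrayDesign,
    n_arrays: int,
    seed: int,
    n_common_sites: int = 30,
    common_freq_range: tuple[float, float] = (0.05, 0.5),
    rare_rate: float = 1.5,
) -> list[TruthGenotype]:
    """Draw a batch of truth genotypes emulating a patient cohort.

    ``n_common_sites`` polymorphic sites are shared across the batch with
    per-site allele frequencies drawn uniformly from
    ``common_freq_range`` and Hardy-Weinberg genotypes; each array
    additionally carries Poisson(``rare_rate``) rare singleton variants
    (heterozygous with probability 0.8).  With the defaults this averages
    about 15 true variants per array on a ~26,000-base design.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7275]))
    n = design.n_positions
    ref = design.ref_idx
    common_pos = rng.choice(n, size=min(n_common_sites, n), replace=False)
    common_freq = rng.uniform(*common_freq_range, size=len(common_pos))
    common_alt = np.array(
        [rng.choice([b for b in range(4) if b != ref[p]]) for p in common_pos]
    )
    truths = []
    for _ in range(n_arrays):
        zyg = np.zeros(n, dtype=np.uint8)
        alt = np.full(n, 255, dtype=np.uint8)
        common = np.zeros(n, dtype=bool)
        u = rng.random(len(common_pos))
        hom = u < common_freq**2
        het = (~hom) & (u < common_freq**2 + 2 * common_freq * (1 - common_freq))
        zyg[common_pos[hom]] = 2
        zyg[common_pos[het]] = 1
        carrier = common_pos[hom | het]
        alt[carrier] = common_alt[hom | het]
        common[carrier] = True
        for _ in range(rng.poisson(rare_rate)):
            p = int(rng.integers(n))
            if zyg[p] != 0:
                continue
            zyg[p] = 1 if rng.random() < 0.8 else 2
            alt[p] = rng.choice([b for b in range(4) if b != ref[p]])
        truths.append(TruthGenotype(zygosity=zyg, alt_idx=alt, is_common=common))
    return truths


def default_design(
    seed: int,
    total_bases: int = 26292,
    n_fragments: int = 180,
    gc: float = 0.40,
    probe_length: int = 25,
    chrom: str = "synthetic_ref",
):
    """Synthetic array design emulating a disease-gene resequencing chip.

    ~26,000 interrogated bases split over ~180 short tiled fragments
    (one exon each), drawn from a random reference of the given GC
    fraction.  Fragment boundaries leave full probe flanks available.
    """
    from .design import tile_probes

    if total_bases < n_fragments:
        raise ValueError("total_bases must be >= n_fragments")
    flank = (probe_length - 1) // 2
    gap = flank + 5
    base_len = total_bases // n_fragments
    lens = [base_len] * n_fragments
    lens[-1] += total_bases - base_len * n_fragments
    regions = []
    cursor = flank + gap
    for i, ln in enumerate(lens):
        regions.append((cursor, cursor + ln, f"exon_{i:03d}"))
        cursor += ln + gap
    ref = random_reference(cursor + flank, gc=gc, seed=seed)
    return tile_probes(ref, regions, probe_length=probe_length, chrom=chrom)


def random_reference(length: int, gc: float = 0.40, seed: int = 0) -> str:
    """IID random reference sequence with the given GC fraction."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E9]))
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=p))
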