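"""Nucleotide composition, GC aggregates, compositional skews, parity coordinates.

All percentages are on the 0-100 scale.  Every statistic excludes a trailing
stop codon so that composition operates on the same codon set as RSCU and CAI.
Undefined ratios (zero denominators) are returned as NaN, never coerced to 0,
and propagate as missing values into downstream correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

from .genetic_code import CODON_TO_AA, SYNONYMOUS_FAMILIES
from .io_qc import CodingSequence, effective_sequence

NAN = float("nan")


def _pct(count: int, total: int) -> float:
    return 100.0 * count / total if total else NAN


def _ratio(a: int, b: int) -> float:
    """(a - b) / (a + b), NaN when a + b == 0."""
    return (a - b) / (a + b) if a + b else NAN


@dataclass(frozen=True)
class PositionalComposition:
    """Percent composition overall and per codon position, plus GC aggregates.

    ``pct[N]`` is overall percent of N; ``pct_pos[N][k]`` the percent of N at
    codon position k in {1,2,3}.  ``gc3s`` is percent GC at third positions of
    codons in multi-codon synonymous families only (Met/Trp excluded).
    """

    pct: dict[str, float]
    pct_pos: dict[str, dict[int, float]]
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc3s: float

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2.0


@dataclass(frozen=True)
class SkewSet:
    """Six pairwise nucleotide disproportion ratios over a whole CDS.

    AT (A-T)/(A+T), GC (G-C)/(G+C), purine (A-G)/(A+G), pyrimidine
    (T-C)/(T+C), amino (A-C)/(A+C), keto (T-G)/(T+G).  ``cumulative_at`` and
    ``cumulative_gc`` are prefix sums of per-window skews.
    """

    at_skew: float
    gc_skew: float
    purine_skew: float
    pyrimidine_skew: float
    amino_skew: float
    keto_skew: float
    cumulative_at: tuple[float, ...]
    cumulative_gc: tuple[float, ...]


@dataclass(frozen=True)
class ParityCoordinates:
    """Parity-rule-2 coordinates at third codon positions.

    ``at_bias3`` = A3/(A3+T3) (ordinate), ``gc_bias3`` = G3/(G3+C3)
    (abscissa); (0.5, 0.5) is the PR2 parity point where A=T and G=C.
    """

    at_bias3: float
    gc_bias3: float


def positional_composition(
    record: Union[str, CodingSequence]
) -> PositionalComposition:
    seq = effective_sequence(record)
    if not seq:
        raise ValueError("empty effective sequence")
    n = len(seq)
    counts = {b: seq.count(b) for b in "ATGC"}
    pos_counts = {b: {k: 0 for k in (1, 2, 3)} for b in "ATGC"}
    for i, base in enumerate(seq):
        pos_counts[base][i % 3 + 1] += 1
    n_codons = n // 3
    pct = {b: _pct(counts[b], n) for b in "ATGC"}
    pct_pos = {
        b: {k: _pct(pos_counts[b][k], n_codons) for k in (1, 2, 3)} for b in "ATGC"
    }
    gc = _pct(counts["G"] + counts["C"], n)
    gck = {
        k: _pct(pos_counts["G"][k] + pos_counts["C"][k], n_codons) for k in (1, 2, 3)
    }
    syn_third = [
        seq[i + 2]
        for i in range(0, n_codons * 3, 3)
        if len(SYNONYMOUS_FAMILIES.get(CODON_TO_AA.get(seq[i : i + 3], "?"), ())) > 1
    ]
    gc3s = (
        _pct(sum(b in "GC" for b in syn_third), len(syn_third)) if syn_third else NAN
    )
    return PositionalComposition(
        pct=pct, pct_pos=pct_pos, gc=gc, gc1=gck[1], gc2=gck[2], gc3=gck[3], gc3s=gc3s
    )


def skew_set(record: Union[str, CodingSequence], window: int = 30) -> SkewSet:
    """Scalar skews over the whole CDS plus cumulative windowed profiles.

    Windows are non-overlapping; a window whose denominator is zero
    contributes 0 to the running sum (the profile must stay defined).
    """
    seq = effective_sequence(record)
    if not seq:
        raise ValueError("empty effective sequence")
    a, t, g, c = (seq.count(b) for b in "ATGC")

    cum_at: list[float] = []
    cum_gc: list[float] = []
    run_at = run_gc = 0.0
    for i in range(0, len(seq), window):
        chunk = seq[i : i + window]
        wa, wt, wg, wc = (chunk.count(b) for b in "ATGC")
        s_at = _ratio(wa, wt)
        s_gc = _ratio(wg, wc)
        run_at += 0.0 if math.isnan(s_at) else s_at
        run_gc += 0.0 if math.isnan(s_gc) else s_gc
        cum_at.append(run_at)
        cum_gc.append(run_gc)

    return SkewSet(
        at_skew=_ratio(a, t),
        gc_skew=_ratio(g, c),
        purine_skew=_ratio(a, g),
        pyrimidine_skew=_ratio(t, c),
        amino_skew=_ratio(a, c),
        keto_skew=_ratio(t, g),
        cumulative_at=tuple(cum_at),
        cumulative_gc=tuple(cum_gc),
    )


def parity_coordinates(record: Union[str, CodingSequence]) -> ParityCoordinates:
    seq = effective_sequence(record)
    third = seq[2::3]
    if not third:
        raise ValueError("empty effective sequence")
    a3, t3, g3, c3 = (third.count(b) for b in "ATGC")
    at = a3 / (a3 + t3) if a3 + t3 else NAN
    gc = g3 / (g3 + c3) if g3 + c3 else NAN
    return ParityCoordinates(at_bias3=at, gc_bias3=gc)
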