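"""Per-gene codon-usage statistics.

Implements the directional and adaptive measures of codon usage bias (CUB):

* RSCU — relative synonymous codon usage, observed/expected within each
  synonymous family; family values sum to the family's degeneracy.
* scaled chi-square (SCS) — the summed within-family chi-square against
  equal usage, normalized by codon count; higher means more biased.
* CAI — codon adaptation index, the geometric mean of reference relative
  adaptiveness weights; 1 means every codon is the reference-optimal one.
* P2 — translational selection statistic (WWC+SSU)/(WWY+SSY) over mRNA
  codon patterns (W = A/U, S = C/G, Y = C/U); values above 0.5 are read as
  bias favoring translational selection.
* dinucleotide odds ratios — observed over expected dinucleotide frequency,
  with under/over-representation thresholds 0.78 and 1.23.

All statistics are computed on the amino-acid-coding codons only (trailing
stop excluded); undefined quantities are NaN, never silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Union

from .genetic_code import (
    ALL_CODONS,
    BASES,
    CODON_TO_AA,
    INFORMATIVE_CODONS,
    MULTI_CODON_AAS,
    SYNONYMOUS_FAMILIES,
)
from .io_qc import CodingSequence, effective_sequence
from .reference import ReferenceCodonUsage

NAN = float("nan")

UNDER, RANDOM, OVER = "UNDER", "RANDOM", "OVER"

#: classification thresholds (strict inequalities; boundary values are RANDOM)
RSCU_OVER = 1.6
RSCU_UNDER = 0.6
ODDS_OVER = 1.23
ODDS_UNDER = 0.78

DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)


@dataclass(frozen=True)
class CodonCountTable:
    counts: dict[str, int]
    n_codons: int

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(codon, 0)


@dataclass(frozen=True)
class P2Terms:
    """Codon-pattern counts behind the translational-selection P2 statistic."""

    wwc: int
    ssu: int
    wwy: int
    ssy: int

    @property
    def p2(self) -> float:
        denom = self.wwy + self.ssy
        return (self.wwc + self.ssu) / denom if denom else NAN

    @property
    def high(self) -> bool:
        return self.p2 > 0.5


@dataclass(frozen=True)
class DinucleotideProfile:
    odds: dict[str, float]
    classification: dict[str, str]


def count_codons(record: Union[str, CodingSequence]) -> CodonCountTable:
    """Count frame-0 non-overlapping codons, trailing stop excluded."""
    seq = effective_sequence(record)
    counts: dict[str, int] = {}
    n = 0
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        counts[codon] = counts.get(codon, 0) + 1
        n += 1
    return CodonCountTable(counts=counts, n_codons=n)


def rscu(counts: CodonCountTable) -> dict[str, float]:
    """RSCU for the 59 informative codons; unobserved families give NaN.

    rscu(c) = counts(c) / (family total / degeneracy); within each observed
    family the values sum to the degeneracy.
    """
    out: dict[str, float] = {}
    for aa in MULTI_CODON_AAS:
        family = SYNONYMOUS_FAMILIES[aa]
        total = sum(counts[c] for c in family)
        if total == 0:
            for c in family:
                out[c] = NAN
        else:
            expected = total / len(family)
            for c in family:
                out[c] = counts[c] / expected
    return out


def classify_rscu(value: float) -> str:
    """OVER above 1.6, UNDER below 0.6, RANDOM in between (and on boundaries)."""
    if math.isnan(value):
        return ""
    if value > RSCU_OVER:
        return OVER
    if value < RSCU_UNDER:
        return UNDER
    return RANDOM


def classify_odds_ratio(value: float) -> str:
    """OVER above 1.23, UNDER below 0.78, RANDOM between (boundaries RANDOM)."""
    if math.isnan(value):
        return ""
    if value > ODDS_OVER:
        return OVER
    if value < ODDS_UNDER:
        return UNDER
    return RANDOM


def scaled_chi_square(
    counts: CodonCountTable,
    denominator: Literal["multi", "peptide"] = "multi",
) -> float:
    """Scaled chi-square: summed family chi-squares over the codon count.

    For each multi-codon family with total n_F and degeneracy d the
    chi-square against equal usage is sum_c (obs - n_F/d)^2 / (n_F/d); the
    sum over families is divided by N.  ``denominator="multi"`` (default)
    takes N as the codons in multi-codon families; ``"peptide"`` takes all
    counted codons.
    """
    chi_total = 0.0
    n_multi = 0
    for aa in MULTI_CODON_AAS:
        family = SYNONYMOUS_FAMILIES[aa]
        n_f = sum(counts[c] for c in family)
        if n_f == 0:
            continue
        n_multi += n_f
        expected = n_f / len(family)
        chi_total += sum((counts[c] - expected) ** 2 / expected for c in family)
    n = n_multi if denominator == "multi" else counts.n_codons
    return chi_total / n if n else NAN


def cai(counts: CodonCountTable, reference: ReferenceCodonUsage) -> float:
    """Codon adaptation index: geometric mean of reference w over informative codons."""
    log_sum = 0.0
    n = 0
    for codon in INFORMATIVE_CODONS:
        k = counts[codon]
        if k:
            log_sum += k * math.log(reference.w[codon])
            n += k
    return math.exp(log_sum / n) if n else NAN


_W = frozenset("AT")  # weak (A or U on mRNA)
_S = frozenset("CG")  # strong
_Y = frozenset("CT")  # pyrimidine (C or U on mRNA)


def translational_selection_p2(counts: CodonCountTable) -> P2Terms:
    """Classify codons into the WWC/SSU/WWY/SSY patterns and form P2.

    Patterns are read on the mRNA alphabet (DNA T plays U); WWC and SSU are
    subsets of WWY and SSY respectively, so per-gene P2 is at most 1.
    """
    wwc = ssu = wwy = ssy = 0
    for codon, k in counts.counts.items():
        if codon not in CODON_TO_AA:
            continue
        p1, p2_, p3 = codon
        if p1 in _W and p2_ in _W:
            if p3 in _Y:
                wwy += k
                if p3 == "C":
                    wwc += k
        elif p1 in _S and p2_ in _S:
            if p3 in _Y:
                ssy += k
                if p3 == "T":  # U on mRNA
                    ssu += k
    return P2Terms(wwc=wwc, ssu=ssu, wwy=wwy, ssy=ssy)


def dinucleotide_odds_ratios(
    record: Union[str, CodingSequence]
) -> DinucleotideProfile:
    """Odds ratio rho(xy) = f(xy)/(f(x) f(y)) over all overlapping dinucleotides.

    Dinucleotide counting spans codon boundaries (whole-sequence windows at
    positions 1..L-1); mononucleotide frequencies come from the same
    sequence.  rho is NaN when f(x) f(y) = 0.
    """
    seq = effective_sequence(record)
    if len(seq) < 2:
        raise ValueError("sequence too short for dinucleotide analysis")
    mono = {b: seq.count(b) / len(seq) for b in BASES}
    n_di = len(seq) - 1
    di_counts: dict[str, int] = {d: 0 for d in DINUCLEOTIDES}
    for i in range(n_di):
        pair = seq[i : i + 2]
        if pair in di_counts:
            di_counts[pair] += 1
    odds: dict[str, float] = {}
    classification: dict[str, str] = {}
    for d in DINUCLEOTIDES:
        expected = mono[d[0]] * mono[d[1]]
        rho = (di_counts[d] / n_di) / expected if expected > 0 else NAN
        odds[d] = rho
        classification[d] = classify_odds_ratio(rho)
    return DinucleotideProfile(odds=odds, classification=classification)
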