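"""Protein indices correlated against codon usage bias.

Nine per-protein quantities: GRAVY (mean Kyte-Doolittle hydropathy), AROMA
(fraction of F/Y/W), isoelectric point, instability index (Guruprasad DIWV
dipeptide weights), aliphatic index (Ikai), and the hydrophobic / acidic /
basic / neutral residue-class fractions.  GRAVY, AROMA, the instability
index and pI are computed with Bio.SeqUtils.ProtParam, which carries the
published tables; the aliphatic index and class fractions are computed here.

The residue partition behind the class fractions is not standardized across
tools, so it is configurable: defaults are acidic = {D,E}, basic = {K,R,H},
neutral = the rest, hydrophobic = {A,V,L,I,M,F,W,C}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet

from Bio.SeqUtils.ProtParam import ProteinAnalysis

STANDARD_AAS = frozenset("ACDEFGHIKLMNPQRSTVWY")
AROMATIC = frozenset("FYW")

DEFAULT_ACIDIC: FrozenSet[str] = frozenset("DE")
DEFAULT_BASIC: FrozenSet[str] = frozenset("KRH")
DEFAULT_HYDROPHOBIC: FrozenSet[str] = frozenset("AVLIMFWC")

#: instability-index threshold above which a protein is conventionally
#: classified as unstable
INSTABILITY_THRESHOLD = 40.0


@dataclass(frozen=True)
class ProteinIndexSet:
    gravy: float
    aroma: float
    pi: float
    instability: float
    aliphatic: float
    hydrophobic_frac: float
    acidic_frac: float
    basic_frac: float
    neutral_frac: float
    length_aa: int

    @property
    def unstable(self) -> bool:
        return self.instability > INSTABILITY_THRESHOLD


def _check(protein: str) -> str:
    if not protein:
        raise ValueError("empty protein")
    bad = set(protein) - STANDARD_AAS
    if bad:
        raise ValueError(f"non-standard residue(s): {', '.join(sorted(bad))}")
    return protein


def gravy(protein: str) -> float:
    """Grand average of hydropathy (Kyte-Doolittle), typically in [-2, 2]."""
    return ProteinAnalysis(_check(protein)).gravy()


def aroma(protein: str) -> float:
    """Fraction of aromatic residues F, Y, W."""
    p = _check(protein)
    return sum(r in AROMATIC for r in p) / len(p)


def isoelectric_point(protein: str) -> float:
    """pH of zero net charge under the Henderson-Hasselbalch charge model."""
    return ProteinAnalysis(_check(protein)).isoelectric_point()


def net_charge(protein: str, ph: float) -> float:
    """Net charge at a given pH (same charge model as isoelectric_point)."""
    analysis = ProteinAnalysis(_check(protein))
    return analysis.charge_at_pH(ph)


def instability_index(protein: str) -> float:
    """Guruprasad instability index, (10/L) * sum of dipeptide weights.

    Undefined (ValueError) for single-residue proteins: there are no
    dipeptides.  Order-dependent by construction.
    """
    p = _check(protein)
    if len(p) < 2:
        raise ValueError("instability index needs length >= 2")
    return ProteinAnalysis(p).instability_index()


def aliphatic_index(protein: str) -> float:
    """Ikai aliphatic index: 100*(X_A + 2.9*X_V + 3.9*(X_I + X_L))."""
    p = _check(protein)
    n = len(p)
    x = {aa: p.count(aa) / n for aa in "AVIL"}
    return 100.0 * (x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"]))


def residue_class_fractions(
    protein: str,
    acidic: FrozenSet[str] = DEFAULT_ACIDIC,
    basic: FrozenSet[str] = DEFAULT_BASIC,
    hydrophobic: FrozenSet[str] = DEFAULT_HYDROPHOBIC,
) -> tuple[float, float, float, float]:
    """(hydrophobic, acidic, basic, neutral) residue fractions.

    Acidic/basic/neutral partition the protein and sum to 1; hydrophobic is
    an independent overlapping class.
    """
    p = _check(protein)
    n = len(p)
    n_acid = sum(r in acidic for r in p)
    n_base = sum(r in basic for r in p)
    n_hydro = sum(r in hydrophobic for r in p)
    return (
        n_hydro / n,
        n_acid / n,
        n_base / n,
        (n - n_acid - n_base) / n,
    )


def protein_indices(protein: str) -> ProteinIndexSet:
    """All nine indices for one protein."""
    p = _check(protein)
    hydro, acid, base, neut = residue_class_fractions(p)
    return ProteinIndexSet(
        gravy=gravy(p),
        aroma=aroma(p),
        pi=isoelectric_point(p),
        instability=instability_index(p) if len(p) >= 2 else float("nan"),
        aliphatic=aliphatic_index(p),
        hydrophobic_frac=hydro,
        acidic_frac=acid,
        basic_frac=base,
        neutral_frac=neut,
        length_aa=len(p),
    )
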