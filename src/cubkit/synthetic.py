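"""Synthetic coding sequences with controlled codon-usage structure.

The generator emulates the compositional features the cohort analyses
assume: genes of 150-15000 nt in frame (start codon, clean open reading
frame, trailing stop), a controllable third-position GC level (GC3), an
optional controllable GC12 level, per-family synonymous codon bias, and
multiplicative depletion of chosen dinucleotides (e.g. CpG, TpA) by
rejection sampling at codon joins.

Cohorts realize a linear GC12-on-GC3 relationship with Gaussian noise — the
generative model behind the neutrality plot — by drawing per-gene GC3
targets uniformly from a range and tilting the amino-acid distribution so
the expected first+second-position GC matches slope*GC3 + intercept + noise.

Every operation is fully determined by its spec's seed; there is no global
randomness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .genetic_code import MULTI_CODON_AAS, STOP_CODONS, SYNONYMOUS_FAMILIES
from .io_qc import CodingSequence, write_fasta

logger = logging.getLogger(__name__)

_MAX_REJECT = 100

#: per-family codon subsets by third-position class (every multi-codon
#: family has at least one codon in each class)
_GC_ENDING = {
    aa: tuple(c for c in SYNONYMOUS_FAMILIES[aa] if c[2] in "GC")
    for aa in MULTI_CODON_AAS
}
_AT_ENDING = {
    aa: tuple(c for c in SYNONYMOUS_FAMILIES[aa] if c[2] in "AT")
    for aa in MULTI_CODON_AAS
}

#: expected GC fraction of codon positions 1+2 for each amino acid (family
#: mean; identical for the GC-ending and AT-ending subsets by the T<->C,
#: A<->G third-position symmetry of the code)
_PREFIX_GC = {
    aa: float(
        np.mean(
            [sum(b in "GC" for b in c[:2]) / 2.0 for c in SYNONYMOUS_FAMILIES[aa]]
        )
    )
    for aa in MULTI_CODON_AAS
}


@dataclass(frozen=True)
class SyntheticGeneSpec:
    """Recipe for one synthetic gene.

    ``length_codons`` counts all codons including the ATG start and the
    trailing stop; ``target_gc3`` is the expected third-position GC fraction
    of internal codons; ``family_bias`` maps an amino acid to an explicit
    probability vector over its synonymous codons (overriding the GC3
    coin); ``dinucleotide_depletion`` maps a dinucleotide to a retention
    probability in (0, 1]; ``target_gc12`` (optional) tilts the amino-acid
    distribution toward that expected first+second-position GC fraction.
    """

    length_codons: int = 200
    target_gc3: float = 0.5
    target_gc12: Optional[float] = None
    family_bias: dict[str, dict[str, float]] = field(default_factory=dict)
    dinucleotide_depletion: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_codons < 50:
            raise ValueError("length_codons must be >= 50 (150 nt) to pass QC")
        if not 0.0 < self.target_gc3 < 1.0:
            raise ValueError("target_gc3 must be in (0, 1)")
        for aa, probs in self.family_bias.items():
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"family_bias[{aa}] sums to {total}, not 1")
            if set(probs) - set(SYNONYMOUS_FAMILIES.get(aa, ())):
                raise ValueError(f"family_bias[{aa}] names non-family codons")
        for dinuc, factor in self.dinucleotide_depletion.items():
            if not 0.0 < factor <= 1.0:
                raise ValueError(f"depletion factor for {dinuc} must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Recipe for a cohort realizing a linear GC12 ~ GC3 relationship.

    ``neutrality_noise_sd`` is in percent units (the SD of the Gaussian
    scatter of GC12 targets around the line); ``gc3_range`` fractions.
    """

    n_genes: int = 47
    gc3_range: tuple[float, float] = (0.30, 0.87)
    neutrality_slope: float = 0.25
    neutrality_intercept: float = 30.0
    neutrality_noise_sd: float = 2.0
    length_codons_range: tuple[int, int] = (100, 600)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("n_genes must be >= 3")
        lo, hi = self.gc3_range
        if not lo < hi:
            raise ValueError("gc3_range must satisfy low < high")


def _tilt_weights(targets: np.ndarray, goal: float) -> np.ndarray:
    """Exponential-tilt weights w_a ~ exp(lam * e_a) with sum(w e) = goal."""
    lo, hi = targets.min(), targets.max()
    goal = float(np.clip(goal, lo + 1e-3, hi - 1e-3))

    def mean_at(lam: float) -> float:
        w = np.exp(lam * (targets - targets.mean()))
        return float((w * targets).sum() / w.sum())

    a, b = -80.0, 80.0
    for _ in range(100):
        mid = 0.5 * (a + b)
        if mean_at(mid) < goal:
            a = mid
        else:
            b = mid
    lam = 0.5 * (a + b)
    w = np.exp(lam * (targets - targets.mean()))
    return w / w.sum()


def generate_gene(spec: SyntheticGeneSpec) -> CodingSequence:
    """Generate one in-frame gene; deterministic in the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    aas = list(MULTI_CODON_AAS)
    prefix_gc = np.array([_PREFIX_GC[a] for a in aas])
    if spec.target_gc12 is None:
        aa_probs = np.full(len(aas), 1.0 / len(aas))
    else:
        aa_probs = _tilt_weights(prefix_gc, spec.target_gc12)

    bias_choices = {
        aa: (list(probs.keys()), np.array(list(probs.values())))
        for aa, probs in spec.family_bias.items()
    }

    codons = ["ATG"]
    for _ in range(spec.length_codons - 2):
        prev_tail = codons[-1][-1]
        codon = None
        for _attempt in range(_MAX_REJECT):
            aa = aas[rng.choice(len(aas), p=aa_probs)]
            if aa in bias_choices:
                fam, probs = bias_choices[aa]
                candidate = fam[rng.choice(len(fam), p=probs)]
            else:
                subset = (
                    _GC_ENDING[aa]
                    if rng.random() < spec.target_gc3
                    else _AT_ENDING[aa]
                )
                candidate = subset[rng.integers(len(subset))]
            if spec.dinucleotide_depletion:
                window = prev_tail + candidate
                introduced = [window[i : i + 2] for i in range(3)]
                keep = True
                for dinuc in introduced:
                    factor = spec.dinucleotide_depletion.get(dinuc)
                    if factor is not None and rng.random() >= factor:
                        keep = False
                        break
                if not keep:
                    continue
            codon = candidate
            break
        if codon is None:
            codon = candidate  # bounded retries exhausted; accept last draw
        codons.append(codon)
    codons.append(str(rng.choice(sorted(STOP_CODONS))))
    return CodingSequence(id=f"syn_{spec.seed}", seq="".join(codons))


def generate_cohort(spec: SyntheticCohortSpec) -> list[CodingSequence]:
    """Generate a cohort with a planted GC12 = slope*GC3 + intercept line."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.gc3_range
    genes: list[CodingSequence] = []
    for i in range(spec.n_genes):
        gc3 = float(rng.uniform(lo, hi))
        gc12_pct = (
            spec.neutrality_slope * gc3 * 100.0
            + spec.neutrality_intercept
            + rng.normal(0.0, spec.neutrality_noise_sd)
        )
        if not 0.0 <= gc12_pct <= 100.0:
            logger.warning("gc12 target %.1f%% outside [0, 100], clipping", gc12_pct)
            gc12_pct = float(np.clip(gc12_pct, 0.0, 100.0))
        length = int(rng.integers(spec.length_codons_range[0], spec.length_codons_range[1] + 1))
        gene_spec = SyntheticGeneSpec(
            length_codons=length,
            target_gc3=gc3,
            target_gc12=gc12_pct / 100.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        gene = generate_gene(gene_spec)
        genes.append(CodingSequence(id=f"gene_{i+1:03d}", seq=gene.seq))
    return genes


def write_cohort(
    genes: list[CodingSequence],
    spec: SyntheticCohortSpec,
    fasta_path: Union[str, Path],
    manifest_path: Union[str, Path, None] = None,
) -> None:
    """Write a cohort FASTA plus a JSON manifest recording the spec."""
    write_fasta(genes, fasta_path)
    if manifest_path is not None:
        manifest = {
            "n_genes": spec.n_genes,
            "gc3_range": list(spec.gc3_range),
            "neutrality_slope": spec.neutrality_slope,
            "neutrality_intercept": spec.neutrality_intercept,
            "neutrality_noise_sd": spec.neutrality_noise_sd,
            "length_codons_range": list(spec.length_codons_range),
            "seed": spec.seed,
        }
        Path(manifest_path).write_text(json.dumps(manifest, indent=2) + "\n")
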