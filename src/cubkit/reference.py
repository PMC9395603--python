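"""Reference codon usage and CAI relative-adaptiveness weights.

A reference set (e.g. the Homo sapiens table shipped with the package) gives
codon frequencies over a large CDS collection.  Within each multi-codon
synonymous family the relative adaptiveness of a codon is

    w(c) = f(c) / max_{c' in family} f(c')

so every family has at least one codon with w = 1.  RSCU and w computed from
frequencies-per-thousand equal those computed from raw counts, since both are
within-family ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

from .genetic_code import (
    ALL_CODONS,
    CODON_TO_AA,
    INFORMATIVE_CODONS,
    SYNONYMOUS_FAMILIES,
)

#: names accepted by :func:`load_reference_table` in place of a path
BUILTIN_TABLES = {"human": "human_codon_usage.tsv"}


@dataclass(frozen=True)
class ReferenceCodonUsage:
    """Reference codon frequencies with derived RSCU and w-weights.

    ``ref_rscu`` and ``w`` cover the 59 informative codons (multi-codon
    families).  Reference codons never observed get a small positive floor
    weight, 0.5 / (family maximum frequency), so that ln w stays finite.
    """

    name: str
    freq: dict[str, float]
    ref_rscu: dict[str, float]
    w: dict[str, float]

    @classmethod
    def from_frequencies(
        cls, freq: dict[str, float], name: str = "custom"
    ) -> "ReferenceCodonUsage":
        missing = sorted(set(ALL_CODONS) - set(freq))
        if missing:
            raise ValueError(f"reference table missing codons: {', '.join(missing)}")
        ref_rscu: dict[str, float] = {}
        w: dict[str, float] = {}
        for aa, family in SYNONYMOUS_FAMILIES.items():
            if len(family) < 2:
                continue
            total = sum(freq[c] for c in family)
            fmax = max(freq[c] for c in family)
            if total <= 0 or fmax <= 0:
                raise ValueError(f"reference family {aa} has zero total usage")
            floor = 0.5 / fmax
            for c in family:
                ref_rscu[c] = freq[c] / (total / len(family))
                w[c] = freq[c] / fmax if freq[c] > 0 else floor
        return cls(name=name, freq=dict(freq), ref_rscu=ref_rscu, w=w)


def load_reference_table(
    source: Union[str, Path] = "human"
) -> ReferenceCodonUsage:
    """Load a reference table from a builtin name or a whitespace-delimited file.

    File format: comment lines start with '#'; an optional header row; data
    rows are ``codon  aa  freq_per_1000  [count]``.  All 64 codons required.
    """
    name = str(source)
    if name in BUILTIN_TABLES:
        text = (
            resources.files("cubkit") / "data" / BUILTIN_TABLES[name]
        ).read_text()
    else:
        text = Path(source).read_text()
        name = Path(source).stem
    freq: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0].lower() == "codon":  # header row
            continue
        codon = parts[0].upper().replace("U", "T")
        freq[codon] = float(parts[2])
    return ReferenceCodonUsage.from_frequencies(freq, name=name)


def write_reference_table(ref: ReferenceCodonUsage, path: Union[str, Path]) -> None:
    """Write a reference table in the load_reference_table format (round-trips)."""
    with Path(path).open("w") as out:
        out.write("codon\taa\tfreq_per_1000\n")
        for codon in ALL_CODONS:
            aa = CODON_TO_AA.get(codon, "*")
            out.write(f"{codon}\t{aa}\t{ref.freq[codon]!r}\n")
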