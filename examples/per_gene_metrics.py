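"""Per-gene codon-usage metrics on one synthetic coding sequence.

Builds a 300-codon gene with GC-rich third positions (target GC3 = 0.75),
then prints the statistics the cohort analyses are built from.
"""

from cubkit import (
    SyntheticGeneSpec,
    cai,
    count_codons,
    dinucleotide_odds_ratios,
    generate_gene,
    load_reference_table,
    positional_composition,
    rscu,
    scaled_chi_square,
    translational_selection_p2,
)

gene = generate_gene(SyntheticGeneSpec(length_codons=300, target_gc3=0.75, seed=42))
counts = count_codons(gene)
comp = positional_composition(gene)
ref = load_reference_table("human")
p2 = translational_selection_p2(counts)
odds = dinucleotide_odds_ratios(gene)
rscu_values = rscu(counts)

print(f"gene length      : {gene.length_nt} nt, {counts.n_codons} coding codons")
print(f"GC3 / GC12       : {comp.gc3:.1f}% / {comp.gc12:.1f}%  (GC3 tracks the 75% target)")
print(f"scaled chi-square: {scaled_chi_square(counts):.3f}  (0 = even synonymous usage)")
print(f"CAI (human ref)  : {cai(counts, ref):.3f}  (1 = all reference-optimal codons)")
print(f"P2               : {p2.p2:.3f}  (>0.5 read as translational-selection bias)")
print(f"RSCU CTG / TTA   : {rscu_values['CTG']:.2f} / {rscu_values['TTA']:.2f}")
print(f"CpG odds ratio   : {odds.odds['CG']:.2f}  ({odds.classification['CG'] or 'n/a'})")
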