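"""Enumerate SpCas9 candidate guides in a gene sequence.

Builds a small artificial gene with a known number of target sites, then
extracts every 23-nt candidate (20-nt spacer + NGG PAM) on both strands.
"""
from crisprdesk import SequenceRecord, candidates_to_bed, extract_candidates
from crisprdesk.fixtures import generate_gene_with_exact_guides

gene = generate_gene_with_exact_guides(5, seed=11)
record = SequenceRecord(identifier="demo_gene", sequence=gene)
candidates = extract_candidates(record)

print(f"gene length: {len(gene)} nt")
print(f"candidates found: {len(candidates)} (the generator promised exactly 5)")
print("\nBED (record, start, end, 23-nt target, placeholder score, strand):")
print(candidates_to_bed(candidates), end="")
# Each line is one genomic footprint a Cas9 nuclease could cut, with the
# 20-nt spacer you would synthesize as the first 20 nt of column 4.
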