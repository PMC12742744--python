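"""On-target consensus filtering of candidate guides.

Each spacer is judged by three independent sequence rules (PAM-proximal G,
GC/poly-T composition, self-hairpin structure) and accepted on a 2-of-3
majority.
"""
from crisprdesk import CandidateGuide, evaluate

spacers = {
    "balanced, ends in G": "ACGTACTTAGCATCAATCGG",
    "all A (no G20, GC=0)": "A" * 20,
    "poly-T interrupted": "GCGCGCATTTACACACACAG",
    "self-complementary": "ACGTACGTACGTACGTACGT",
}

print(f"{'description':24} {'g20':>5} {'comp':>5} {'struct':>6} {'votes':>5}  accepted")
for label, spacer in spacers.items():
    verdict = evaluate(CandidateGuide.from_spacer(spacer))
    print(
        f"{label:24} {str(verdict.passes_g20):>5} {str(verdict.passes_composition):>5}"
        f" {str(verdict.passes_structure):>6} {verdict.consensus_votes:>5}  {verdict.accepted}"
    )
# A guide needs at least two method votes; the per-method booleans are
# always recorded so a rejection can be audited.
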