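"""Build an evolutionary profile from a structure family.

Generates a 40-residue helical scaffold plus 15 structural neighbours
(0.5 A coordinate jitter, 10% sequence mutations), aligns each neighbour
to the scaffold, and builds the position-specific log-odds profile that
guides the sequence search.
"""
import numpy as np

from profdesign import AA_ALPHABET, FamilySpec, make_family, profile_from_library

scaffold, members, _ = make_family(FamilySpec(n_members=15, length=40, seed=0))
profile, threshold = profile_from_library(scaffold, members)

print(f"scaffold sequence : {scaffold.sequence}")
print(f"TM-score threshold: {threshold:.2f}  "
      f"(relaxed from 0.7 toward 0.5 until >10 homologs pass)")
print(f"MSA rows used     : {profile.n_homologs} (self + accepted homologs)")

consensus = "".join(AA_ALPHABET[i] for i in profile.log_odds.argmax(axis=1))
print(f"profile consensus : {consensus}")
ident = np.mean([a == b for a, b in zip(consensus, scaffold.sequence)])
print(f"consensus identity to scaffold: {100 * ident:.0f}%")
print("(high identity is expected: members are mild mutants of the scaffold,")
print(" so the per-position argmax of the log-odds recovers the native residue)")
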