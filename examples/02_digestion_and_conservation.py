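"""In-silico tryptic digestion and the cross-species conserved-peptide index.

Only peptides whose sequence is identical in every compared species have
comparable mass-spectrometric response across samples, so the comparison is
restricted to peptides found in the in-silico digest of every species'
protein database (trypsin blocked by proline, length >= 6, up to two missed
cleavages).
"""

from swathcomp import (
    DigestParams,
    IbaqParams,
    Proteome,
    ProteinEntry,
    build_conserved_index,
    count_observable_peptides,
    digest_sequence,
)

sequence = "MAGKRTESTKLLP"
print(f"digest of {sequence} (<=2 missed cleavages, length >= 6):")
for pep in digest_sequence(sequence, DigestParams()):
    print(f"  {pep.sequence:<12} missed={pep.missed_cleavages} start={pep.start}")

# iBAQ denominator: fully-tryptic peptides of detectable length (7-30)
seq = "MKAAAAAAKLLLLLLLRGGGGGK"
n_obs = count_observable_peptides(seq, IbaqParams())
print(f"\n{seq}: {n_obs} theoretically observable peptides (iBAQ denominator)")

# a single substitution breaks conservation for that peptide only
mouse = Proteome("mouse", [ProteinEntry("P1_MOUSE", "GENE1", "MAAAAAKLLLLLLR")])
human = Proteome("human", [ProteinEntry("P1_HUMAN", "GENE1", "MAAAAAKLLLLLIR")])
index = build_conserved_index([mouse, human], DigestParams())
for pep in ("MAAAAAK", "LLLLLLR"):
    status = "conserved" if index.is_conserved(pep, ["mouse", "human"]) else "mouse-only"
    print(f"{pep}: {status} (found in {sorted(index.species_of(pep))})")
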