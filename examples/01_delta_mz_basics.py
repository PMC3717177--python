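"""Precursor delta-m/z arithmetic: mass, m/z, signatures, charge inference.

The delta m/z of a peptide-spectrum match — measured precursor m/z minus
the value computed from sequence, modifications and charge — is the core
diagnostic: near zero when the annotation is right, systematically offset
when it is not.
"""

from idmigrate import delta_mz, infer_charge, peptide_mass, theoretical_mz

seq = "PEPTIDE"
mass = peptide_mass(seq)
print(f"monoisotopic mass of {seq}:        {mass:.6f} Da")

mz2 = theoretical_mz(mass, 2)
print(f"[M+2H]2+ theoretical m/z:          {mz2:.6f} Th")

# a methionine-oxidised peptide whose oxidation annotation went missing
ox = 15.994915
observed = theoretical_mz(mass + ox, 2)  # instrument saw the oxidised ion
d = delta_mz(observed, mz2)
print(f"delta m/z with missing Met-ox:     {d:+.6f} Th  (= +15.994915/2)")

# recover a missing charge from mass and measured m/z
z = infer_charge(mass, mz2)
print(f"charge inferred from mass and m/z: {z}")

# The offsets mean: 0 -> annotation consistent; +7.997 at z=2 -> one
# oxidation unannotated; a wrong charge would be off by hundreds of Th.
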