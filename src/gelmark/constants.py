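"""Physical constants and pipeline-wide defaults.

All m/z values are in thomson (Th), masses in Da, retention times in
minutes, intensities in detector counts.
"""

#: Mass of a proton (Da); used for every m/z <-> neutral-mass conversion.
PROTON_MASS = 1.007276

#: Mass difference between successive isotopologue peaks in neutral mass
#: (13C - 12C, Da). Envelope spacing in m/z is this divided by the charge.
ISOTOPE_SPACING = 1.00335

#: MS1 scan range used to build ion inventories (Th), inclusive bounds.
SCAN_RANGE = (100.0, 1200.0)

#: Detection criterion: an ion counts as present only at or above this
#: intensity (counts).
MIN_INTENSITY = 1.0e4

#: Charge states retained when building peptide ion inventories. Singly
#: charged ions are treated as non-peptide contaminants.
PEPTIDE_CHARGES = frozenset({2, 3, 4})

#: Widest charge considered when reading isotope spacing.
MAX_CHARGE = 6

#: Cross-run EIC matching accuracy (Th).
MZ_TOL = 0.1

#: Cross-run retention-time matching tolerance (min).
RT_TOL = 0.5

#: Within-run tolerances used when chaining centroid peaks into envelopes.
MZ_LINK_TOL = 0.02
RT_LINK_TOL = 0.05
SPACING_TOL = 0.01

#: Species-presence threshold on gelatin content (%): a marker content of
#: no more than this is reported as "not detected".
CONTENT_THRESHOLD = 5.0

#: Mass of sample powder digested per assay (mg); contents are expressed
#: as mg marker-equivalent gelatin per mg sample x 100.
SAMPLE_MASS_MG = 5.0

SPECIES = ("donkey", "horse", "cattle", "pig")
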