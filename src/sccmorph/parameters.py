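"""Canonical names of the nine semicircular-canal shape parameters."""

CANALS = ("lateral", "superior", "posterior")

SIDES = ("R", "L")

#: The nine per-side parameters compared between groups: three inter-canal
#: plane angles (degrees), the signed lateral-canal inclination versus the
#: axial plane (degrees), horizontal distances from the sagittal midline to
#: the lateral-most aspect of the lateral and posterior canals (mm), and the
#: minimum cross-sectional area of each canal (mm^2).
PARAMETERS = (
    "angle_lateral_superior",
    "angle_superior_posterior",
    "angle_lateral_posterior",
    "lateral_inclination",
    "midline_distance_lateral",
    "midline_distance_posterior",
    "min_csa_lateral",
    "min_csa_superior",
    "min_csa_posterior",
)
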