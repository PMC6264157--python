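"""Residue-range presets for the CpxA cytoplasmic dimer (4BIV numbering).

Three closely related HAMP residue sets circulate in the source material and
are deliberately kept distinct (no silent unification):

* ``CV``         — 188-201 / 219-234, the collective-variable helix set;
* ``DESCRIPTOR`` — 189-204 / 217-232, the piston/rotation helix set;
* ``DISTANCE``   — 189-203 / 217-231, the inter-monomer-distance and
  helix-content set.

Two DHp sets are likewise retained verbatim: the CV set (235-266 / 272-299)
and the architecture set (240-268 / 271-298) used for the domain-angle
geometric centers, whose CA span is 305-453.
"""

from __future__ import annotations

# --- HAMP alpha-helix residue sets (per chain) -----------------------------
HAMP_CV_RANGES = ((188, 201), (219, 234))
HAMP_DESCRIPTOR_RANGES = ((189, 204), (217, 232))
HAMP_DISTANCE_RANGES = ((189, 203), (217, 231))

#: rotation reference (anchor) residues, Calpha centroids; chain-matched
ROTATION_ANCHORS_N = (283, 287, 291, 295)   # for helices N1, N2 (DHp helix 2)
ROTATION_ANCHORS_C = (313, 317, 321, 325)   # for helices C1, C2 (CA domain)

# --- DHp / CA domain sets --------------------------------------------------
DHP_CV_RANGES = ((235, 266), (272, 299))
DHP_ARCHITECTURE_RANGES = ((240, 268), (271, 298))
CA_ARCHITECTURE_RANGE = (305, 453)
CA_CV_RANGE = (306, 452)

# --- enzymatic-state markers ----------------------------------------------
GRIPPER_RANGE = (420, 430)        # gripper helix, G420-Q430
DHP_COMPANION_RANGE = (235, 255)  # companion DHp helix 1, M235-T255
MARKER_HIS = 248                  # phospho-accepting histidine (DHp)
MARKER_ASN = 360                  # N360 (CA), paired with H248 across chains
MARKER_ASP = 386                  # D386 (CA, ATP contact)
MARKER_ARG = 363                  # R363 (CA, ATP contact)

# --- Table-3-style HAMP inter-monomer restraints ---------------------------
# Each entry: (pairs, ambiguous, force constant kcal/(mol A^2), lower A, upper A)
# Pairs are ((chain, resid), (chain, resid)) on Calpha atoms.
RESTRAINTS_DBL = (
    ((((("A", 190)), ("B", 190)), (("A", 219), ("B", 219))), True, 1.0, 7.0, 11.0),
    (((("A", 204), ("B", 204)), (("A", 230), ("B", 230))), True, 1.0, 13.0, 17.0),
)

RESTRAINTS_MID = (
    (((("A", 221), ("A", 194)),), False, 1.0, 10.3, 14.3),
    (((("A", 221), ("B", 194)),), False, 1.0, 2.2, 6.2),
    (((("B", 194), ("B", 221)),), False, 1.0, 10.3, 14.3),
    (((("A", 194), ("B", 221)),), False, 1.0, 2.2, 6.2),
)

RESTRAINTS_TET = (
    (((("A", 190), ("A", 219)),), False, 1.0, 10.0, 14.0),
    (((("B", 190), ("B", 219)),), False, 1.0, 10.0, 14.0),
    (((("A", 190), ("B", 219)),), False, 1.0, 7.0, 11.0),
    (((("A", 219), ("B", 190)),), False, 1.0, 7.0, 11.0),
    (((("A", 204), ("A", 230)),), False, 1.0, 9.0, 13.0),
    (((("B", 204), ("B", 230)),), False, 1.0, 9.0, 13.0),
    (((("A", 204), ("B", 230)),), False, 1.0, 13.0, 17.0),
    (((("B", 204), ("A", 230)),), False, 1.0, 13.0, 17.0),
)

RESTRAINT_SETS = {"dbl": RESTRAINTS_DBL, "mid": RESTRAINTS_MID, "tet": RESTRAINTS_TET}

# --- TAMD thermostat / spring constants ------------------------------------
KAPPA = 100.0            # kcal/(mol A^2), CV restraining spring
GAMMA = 0.5              # ps^-1, physical Langevin friction
BETA_INV = 0.6           # kcal/mol, physical thermal energy (300 K)
GAMMA_BAR_CALIBRATED = 0.02   # ps^-1 convention, all-atom calibration outcome
BETA_BAR_INV_VALUES = (15.0, 20.0)  # kcal/mol, artificial thermal energies

# --- 4BIV architecture reference values ------------------------------------
THETA_HAD_4BIV = 116.6       # deg, HAMP - CA(-) - DHp
THETA_HASTARD_4BIV = 105.5   # deg, HAMP - CA(*) - DHp
RATIO_4BIV = 1.1
INTER_MONOMER_RANGE_4BIV = (8.4, 10.3)  # A, observed envelope
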