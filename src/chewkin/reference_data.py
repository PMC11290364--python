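"""Reference in vivo amplitude summary used to parameterise the simulator.

These are published summary values of 6-DOF chewing kinematics in three
adult rats measured with marker-based biplanar videoradiography: per
individual, the mean absolute amplitude (max - min over the normalised
chew cycle) of 15 variables — six TMJ (condylar) degrees of freedom,
three lower-molar translations, six symphyseal degrees of freedom —
with between-cycle 95% CIs, plus the workflow-precision CIs measured on
frozen (zero-relative-motion) specimens.  Rotations are degrees,
translations millimetres.

They serve two roles here: the default amplitudes injected by the
synthetic proal-chewing generator (so the default synthetic study
parallels a realistic rat), and inputs to the report arithmetic
(across-individual ranges and grouped grand means).  They are study
conditions, not assertions the simulator re-derives.
"""

from __future__ import annotations

#: Report order of the 15 kinematic variables.
VARIABLES = (
    "condylar_Rx",
    "condylar_Ry",
    "condylar_Rz",
    "condylar_Tx",
    "condylar_Ty",
    "condylar_Tz",
    "molar_Tx",
    "molar_Ty",
    "molar_Tz",
    "symphyseal_Rx",
    "symphyseal_Ry",
    "symphyseal_Rz",
    "symphyseal_Tx",
    "symphyseal_Ty",
    "symphyseal_Tz",
)

#: Mean absolute amplitude per individual (deg / mm).
IN_VIVO_AMPLITUDES = {
    "rat_A": {
        "condylar_Rx": 0.80, "condylar_Ry": 2.86, "condylar_Rz": 18.10,
        "condylar_Tx": 2.13, "condylar_Ty": 1.40, "condylar_Tz": 0.19,
        "molar_Tx": 0.50, "molar_Ty": 4.73, "molar_Tz": 0.49,
        "symphyseal_Rx": 1.10, "symphyseal_Ry": 1.13, "symphyseal_Rz": 1.55,
        "symphyseal_Tx": 0.18, "symphyseal_Ty": 0.62, "symphyseal_Tz": 0.41,
    },
    "rat_B": {
        "condylar_Rx": 1.19, "condylar_Ry": 1.63, "condylar_Rz": 11.60,
        "condylar_Tx": 2.08, "condylar_Ty": 0.37, "condylar_Tz": 0.18,
        "molar_Tx": 0.99, "molar_Ty": 2.51, "molar_Tz": 0.39,
        "symphyseal_Rx": 2.09, "symphyseal_Ry": 0.60, "symphyseal_Rz": 0.63,
        "symphyseal_Tx": 0.04, "symphyseal_Ty": 0.36, "symphyseal_Tz": 0.20,
    },
    "rat_C": {
        "condylar_Rx": 0.81, "condylar_Ry": 1.11, "condylar_Rz": 10.00,
        "condylar_Tx": 2.31, "condylar_Ty": 0.10, "condylar_Tz": 0.27,
        "molar_Tx": 1.06, "molar_Ty": 2.22, "molar_Tz": 0.40,
        "symphyseal_Rx": 0.99, "symphyseal_Ry": 1.50, "symphyseal_Rz": 0.82,
        "symphyseal_Tx": 0.04, "symphyseal_Ty": 0.06, "symphyseal_Tz": 0.08,
    },
}

#: Average between-cycle 95% CI half-width per individual (deg / mm).
IN_VIVO_BETWEEN_CYCLE_CI = {
    "rat_A": {
        "condylar_Rx": 1.48, "condylar_Ry": 0.65, "condylar_Rz": 1.04,
        "condylar_Tx": 0.02, "condylar_Ty": 0.31, "condylar_Tz": 0.24,
        "molar_Tx": 0.04, "molar_Ty": 0.31, "molar_Tz": 0.23,
        "symphyseal_Rx": 1.03, "symphyseal_Ry": 0.50, "symphyseal_Rz": 0.55,
        "symphyseal_Tx": 0.05, "symphyseal_Ty": 0.24, "symphyseal_Tz": 0.12,
    },
    "rat_B": {
        "condylar_Rx": 0.17, "condylar_Ry": 0.24, "condylar_Rz": 0.93,
        "condylar_Tx": 0.01, "condylar_Ty": 0.01, "condylar_Tz": 0.02,
        "molar_Tx": 0.01, "molar_Ty": 0.21, "molar_Tz": 0.06,
        "symphyseal_Rx": 1.23, "symphyseal_Ry": 0.32, "symphyseal_Rz": 0.54,
        "symphyseal_Tx": 0.02, "symphyseal_Ty": 0.29, "symphyseal_Tz": 0.08,
    },
    "rat_C": {
        "condylar_Rx": 0.46, "condylar_Ry": 0.69, "condylar_Rz": 0.99,
        "condylar_Tx": 0.10, "condylar_Ty": 0.07, "condylar_Tz": 0.08,
        "molar_Tx": 0.14, "molar_Ty": 0.27, "molar_Tz": 0.10,
        "symphyseal_Rx": 1.11, "symphyseal_Ry": 0.60, "symphyseal_Rz": 0.32,
        "symphyseal_Tx": 0.04, "symphyseal_Ty": 0.03, "symphyseal_Tz": 0.07,
    },
}

#: Workflow-precision 95% CI from frozen-specimen trials; reported for the
#: six TMJ degrees of freedom only (deg / mm).
IN_VIVO_WORKFLOW_CI = {
    "condylar_Rx": 0.07,
    "condylar_Ry": 0.017,
    "condylar_Rz": 0.021,
    "condylar_Tx": 0.00097,
    "condylar_Ty": 0.0012,
    "condylar_Tz": 0.0016,
}

#: Number of analysed chew cycles per individual (38 total).
IN_VIVO_CYCLE_COUNTS = {"rat_A": 13, "rat_B": 7, "rat_C": 18}

#: Variable groups used for grand-mean reporting.
VARIABLE_GROUPS = {
    "symphyseal_rotations": ("symphyseal_Rx", "symphyseal_Ry", "symphyseal_Rz"),
    "symphyseal_translations": ("symphyseal_Tx", "symphyseal_Ty", "symphyseal_Tz"),
}
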