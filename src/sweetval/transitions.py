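"""Built-in SRM transition definitions for the nine steviol glycosides.

Negative-mode ESI on a triple quadrupole: each analyte is monitored by a
precursor ion ([M-H]- or an adduct), one quantifier product ion (the most
intense transition, used for quantitation) and two qualifier product ions
(used to confirm identity).  Reference retention times are for a 13-min
reversed-phase (C18) gradient on which all nine compounds elute within
about 7 minutes.

Note the isobaric pair: stevioside and rebaudioside B share the precursor
m/z 803.458 (both C38H60O18) and are distinguished only by retention time
(4.895 vs 6.347 min), as are rubusoside and steviolbioside at nominal
precursor 641 (both C32H50O13).
"""

from __future__ import annotations

from .srm import TransitionRecord

ANALYTES = (
    "rebaudioside A",
    "rebaudioside B",
    "rebaudioside C",
    "rebaudioside D",
    "rebaudioside F",
    "rubusoside",
    "dulcoside A",
    "stevioside",
    "steviolbioside",
)

#: Molecular formulas of the glycosides (free acids, neutral molecules).
FORMULAS = {
    "rebaudioside A": "C44H70O23",
    "rebaudioside B": "C38H60O18",
    "rebaudioside C": "C44H70O22",
    "rebaudioside D": "C50H80O28",
    "rebaudioside F": "C43H68O22",
    "rubusoside": "C32H50O13",
    "dulcoside A": "C38H60O17",
    "stevioside": "C38H60O18",
    "steviolbioside": "C32H50O13",
}

DEFAULT_TRANSITIONS: tuple[TransitionRecord, ...] = (
    TransitionRecord(
        analyte="rebaudioside A", formula="C44H70O23", reference_rt=4.856,
        precursor_mz=965.5, quantifier_mz=803.45,
        qualifier_mzs=(641.36, 317.29), collision_energies=(27.87, 55.0, 55.0),
    ),
    TransitionRecord(
        analyte="rebaudioside B", formula="C38H60O18", reference_rt=6.347,
        precursor_mz=803.458, quantifier_mz=641.29,
        qualifier_mzs=(413.08, 317.17), collision_energies=(47.42, 54.07, 53.65),
    ),
    TransitionRecord(
        analyte="rebaudioside C", formula="C44H70O22", reference_rt=5.214,
        precursor_mz=949.508, quantifier_mz=787.38,
        qualifier_mzs=(641.29, 479.24), collision_energies=(32.2, 55.0, 55.0),
    ),
    TransitionRecord(
        analyte="rebaudioside D", formula="C50H80O28", reference_rt=4.139,
        precursor_mz=1127.558, quantifier_mz=803.35,
        qualifier_mzs=(641.32, 623.30), collision_energies=(51.93, 55.0, 55.0),
    ),
    TransitionRecord(
        analyte="rebaudioside F", formula="C43H68O22", reference_rt=5.113,
        precursor_mz=935.4, quantifier_mz=773.35,
        qualifier_mzs=(611.292, 641.321), collision_energies=(26.9, 55.0, 55.0),
    ),
    TransitionRecord(
        analyte="rubusoside", formula="C32H50O13", reference_rt=5.693,
        precursor_mz=641.348, quantifier_mz=478.92,
        qualifier_mzs=(521.45, 317.15), collision_energies=(14.14, 23.07, 46.95),
    ),
    TransitionRecord(
        analyte="dulcoside A", formula="C38H60O17", reference_rt=5.303,
        precursor_mz=787.458, quantifier_mz=625.45,
        qualifier_mzs=(479.29, 317.25), collision_energies=(18.1, 55.0, 55.0),
    ),
    TransitionRecord(
        analyte="stevioside", formula="C38H60O18", reference_rt=4.895,
        precursor_mz=803.458, quantifier_mz=641.39,
        qualifier_mzs=(479.22, 317.34), collision_energies=(19.66, 55.0, 55.0),
    ),
    TransitionRecord(
        analyte="steviolbioside", formula="C32H50O13", reference_rt=6.478,
        precursor_mz=641.448, quantifier_mz=479.17,
        qualifier_mzs=(461.29, 317.37), collision_energies=(42.32, 48.39, 42.49),
    ),
)

REFERENCE_RT = {t.analyte: t.reference_rt for t in DEFAULT_TRANSITIONS}
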