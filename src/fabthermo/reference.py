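"""Published kinetic and stability constants for the anti-insulin Fab panel.

The package was developed around a panel of light-chain framework-3 charge
variants of an anti-insulin Fab: the wild type, basic mutants (R3, R5, K5)
and acidic mutants (D5, E5), named for the residue introduced and the
number of substituted positions (sequential VL positions 63, 65, 67, 70
and 72).  The kinetic constants below are the globally fitted SPR values
at 25 degC (rates as mean +/- SE); they serve as realistic inputs for the
fit-bypass reporting mode and as anchors for the synthetic-data presets.
"""

from __future__ import annotations

import pandas as pd

#: Panel variant names in display order.
VARIANTS = ["wild-type", "R3", "R5", "K5", "D5", "E5"]

#: SPR kinetic constants at 298.15 K: Kd (M), kon +/- SE (M^-1 s^-1), koff +/- SE (s^-1).
KINETICS_25C: dict[str, dict[str, float]] = {
    "wild-type": {"kd": 2.22e-10, "kon": 2.48e6, "kon_se": 0.01e6, "koff": 5.49e-4, "koff_se": 0.01e-4},
    "R3": {"kd": 5.49e-11, "kon": 8.79e6, "kon_se": 0.02e6, "koff": 4.83e-4, "koff_se": 0.01e-4},
    "R5": {"kd": 2.03e-12, "kon": 7.19e6, "kon_se": 0.05e6, "koff": 1.46e-5, "koff_se": 0.01e-5},
    "K5": {"kd": 8.04e-12, "kon": 5.44e7, "kon_se": 0.04e7, "koff": 4.37e-4, "koff_se": 0.01e-4},
    "D5": {"kd": 9.69e-10, "kon": 7.64e5, "kon_se": 0.04e5, "koff": 7.40e-4, "koff_se": 0.02e-4},
    "E5": {"kd": 1.52e-9, "kon": 2.79e5, "kon_se": 0.01e5, "koff": 4.24e-4, "koff_se": 0.01e-4},
}

#: DSC melting temperatures, degC (K5 aggregated before measurement).
TM_C: dict[str, float | None] = {
    "wild-type": 76.8, "R3": 74.4, "R5": 71.1, "K5": None, "D5": 66.9, "E5": 69.5,
}

#: Mutated sequential VL positions (all serines in the wild type).
MUTATED_POSITIONS_5 = (63, 65, 67, 70, 72)
MUTATED_POSITIONS_3 = (63, 65, 67)

#: Residue introduced by each mutant family.
MUTANT_RESIDUE = {"R3": "R", "R5": "R", "K5": "K", "D5": "D", "E5": "E"}


def kinetics_table() -> pd.DataFrame:
    """The 25 degC kinetic panel as a DataFrame indexed by variant."""
    return pd.DataFrame.from_dict(KINETICS_25C, orient="index").loc[VARIANTS]


def mutation_tokens(variant: str) -> list[str]:
    """Mutation labels (e.g. ``['S63R', 'S65R', ...]``) for a panel variant."""
    if variant == "wild-type":
        return []
    if variant not in MUTANT_RESIDUE:
        raise KeyError(f"unknown panel variant {variant!r}")
    positions = MUTATED_POSITIONS_3 if variant == "R3" else MUTATED_POSITIONS_5
    res = MUTANT_RESIDUE[variant]
    return [f"S{p}{res}" for p in positions]
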