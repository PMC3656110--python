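"""Van der Waals radii used for surface-distance computations.

The default table is the Bondi set with the Rowland & Taylor revision for H.
Force-field-specific radii can be supplied as overrides wherever a structure
is loaded; at a fixed 5 A solvation cutoff the preferential interaction
coefficient is only weakly sensitive to the exact radius set, but the table
is pinned here so results are reproducible.
"""

from __future__ import annotations

# Bondi (1964) vdW radii in Angstrom; H from Rowland & Taylor (1996).
DEFAULT_RADII: dict[str, float] = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "ZN": 1.39,
    "FE": 1.40,
    "MG": 1.73,
    "CA": 1.70,
    "NA": 2.27,
    "K": 2.75,
}


def radius_for(element: str, overrides: dict[str, float] | None = None) -> float:
    """Return the vdW radius for ``element`` (case-insensitive).

    Raises
    ------
    KeyError
        If the element is in neither the override table nor the default set.
    """
    key = element.strip().upper()
    if overrides:
        upper = {k.strip().upper(): v for k, v in overrides.items()}
        if key in upper:
            return float(upper[key])
    return float(DEFAULT_RADII[key])
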