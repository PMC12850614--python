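"""Built-in tissue dielectric table.

Representative relative permittivity and conductivity values for a handful
of tissue classes, tabulated at the eight proton Larmor frequencies of the
B0 grid {0.55, 1.5, 3, 5, 7, 10.5, 11.7, 14} T. The numbers follow the
well-known dispersive trends of biological tissue (permittivity falls and
conductivity rises with frequency; fat and cortical bone are low-water,
low-conductivity; muscle and liver are high-water) but are configuration,
not measurement: any study that needs a specific database should load its
own table with :func:`uisnr.phantom.load_tissue_table`.

Label 0 is reserved for air everywhere in the package.
"""

from __future__ import annotations

import numpy as np

#: Default proton gyromagnetic ratio over 2*pi, Hz/T.
GAMMA_OVER_2PI_1H = 42.577478e6

#: Gyromagnetic ratio over 2*pi (Hz/T) for common MR-active nuclei,
#: used for converting frequency windows into per-nucleus B0 ranges.
GAMMA_OVER_2PI = {
    "1H": GAMMA_OVER_2PI_1H,
    "2H": 6.536e6,
    "13C": 10.7084e6,
    "17O": -5.772e6,
    "19F": 40.078e6,
    "23Na": 11.262e6,
    "31P": 17.235e6,
    "129Xe": -11.777e6,
}

#: The eight proton Larmor frequencies (Hz) at which the built-in table is
#: tabulated, matching the B0 grid {0.55, 1.5, 3, 5, 7, 10.5, 11.7, 14} T.
TABLE_B0_GRID_T = np.array([0.55, 1.5, 3.0, 5.0, 7.0, 10.5, 11.7, 14.0])
TABLE_FREQUENCIES_HZ = GAMMA_OVER_2PI_1H * TABLE_B0_GRID_T

# name -> (tissue_id, eps_r per frequency, sigma [S/m] per frequency)
_BUILTIN = {
    "fat": (1,
            [12.4, 6.5, 5.9, 5.7, 5.6, 5.5, 5.5, 5.4],
            [0.025, 0.035, 0.037, 0.040, 0.042, 0.045, 0.046, 0.048]),
    "muscle": (2,
               [95.0, 72.0, 63.5, 60.0, 58.2, 56.5, 56.1, 55.3],
               [0.62, 0.68, 0.72, 0.75, 0.77, 0.82, 0.84, 0.87]),
    "lung_inflated": (3,
                      [45.0, 27.0, 21.8, 20.8, 20.5, 20.0, 19.9, 19.6],
                      [0.20, 0.27, 0.30, 0.32, 0.33, 0.35, 0.36, 0.37]),
    "liver": (4,
              [95.0, 64.0, 51.0, 46.0, 44.0, 42.0, 41.5, 41.0],
              [0.41, 0.45, 0.51, 0.55, 0.58, 0.63, 0.65, 0.68]),
    "bone_cortical": (5,
                      [18.0, 14.4, 13.4, 13.0, 12.8, 12.5, 12.4, 12.3],
                      [0.035, 0.060, 0.067, 0.072, 0.077, 0.085, 0.087,
                       0.092]),
    "saline": (6,
               [78.0, 77.9, 77.5, 77.0, 76.5, 75.5, 75.2, 74.5],
               [0.99, 1.00, 1.00, 1.01, 1.02, 1.05, 1.06, 1.09]),
}


def builtin_tissue(name: str):
    """Return a :class:`~uisnr.phantom.TissueDielectric` from the built-in table.

    ``name="air"`` returns the reserved air entry (label 0, eps_r=1,
    sigma=0, valid at every frequency).
    """
    from .phantom import TissueDielectric

    if name == "air":
        return TissueDielectric.air()
    try:
        tissue_id, eps, sig = _BUILTIN[name]
    except KeyError:
        raise KeyError(
            f"unknown built-in tissue {name!r}; "
            f"available: air, {', '.join(sorted(_BUILTIN))}") from None
    return TissueDielectric(
        tissue_id=tissue_id, name=name,
        frequencies=TABLE_FREQUENCIES_HZ.copy(),
        eps_r=np.asarray(eps, dtype=float),
        sigma=np.asarray(sig, dtype=float),
    )


def builtin_table():
    """All built-in tissues (including air) keyed by tissue id."""
    table = {0: builtin_tissue("air")}
    for name in _BUILTIN:
        t = builtin_tissue(name)
        table[t.tissue_id] = t
    return table
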