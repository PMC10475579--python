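"""Independent scalar reimplementation of the 15 vegetation-index formulas.

Written directly from the index table, separately from the package code, to
serve as the oracle in formula-agreement tests.  Deliberately naive: plain
Python arithmetic, one expression per index, no vectorization or NaN policy.
"""

import math


def oracle_indices(b, g, r, e, n):
    lr, lb, lg = 650.0, 450.0, 560.0
    return {
        "NDVI": (n - r) / (n + r),
        "OSAVI": (n - r) * (1 + 0.16) / (n + r + 0.16),
        "GNDVI": (n - g) / (n + g),
        "SAVI": (n - r) * (1 + 0.5) / (n + r + 0.5),
        "MSAVI": (2 * n + 1 - math.sqrt((2 * n + 1) ** 2 - 8 * (n - r))) / 2,
        "TGI": -0.5 * ((lr - lb) * (r - g) - (lr - lg) * (r - b)),
        "GLI": (2 * g - r - b) / (2 * g + r + b),
        "TVI": 0.5 * (120 * (n - g) - 200 * (r - g)),
        "RECI": n / e - 1,
        "LCI": (n - e) / (n + r),
        "ARI": g / n,
        "MGRVI": (g**2 - r**2) / (g**2 + r**2),
        "MARI": (1 / g - 1 / e) / n,
        "NDRE": (n - e) / (n + e),
        "RGBVI": (g**2 - r * b) / (g**2 + r * b),
    }
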