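"""Life-stage classification shared by the simulator and the TPC pipeline."""

from __future__ import annotations

import numpy as np

__all__ = ["STAGES", "classify_stage"]

#: Ontogenetic order used everywhere: early life (< 1 year), juvenile
#: (>= 1 year, immature), adult (mature).
STAGES = ("early", "juvenile", "adult")


def classify_stage(age, mature):
    """Life stage from age and maturity.

    ``early`` below age 1 (larvae mouth opening to one year), ``juvenile``
    from age 1 until sexual maturation, ``adult`` after maturation.  Accepts
    scalars or arrays; returns a scalar string or an object array.
    """
    age_arr = np.asarray(age, dtype=float)
    mature_arr = np.asarray(mature, dtype=bool)
    if np.any(age_arr < 0):
        raise ValueError("age must be nonnegative")
    out = np.where(age_arr < 1.0, "early", np.where(mature_arr, "adult", "juvenile"))
    if np.isscalar(age) or (age_arr.ndim == 0):
        return str(out)
    return out
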