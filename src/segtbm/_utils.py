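"""Small shared helpers."""

import numpy as np


def _as_matrix(obj) -> np.ndarray:
    """Accept either a JacobianCohort or a plain subjects x voxels array.

    ndarray inputs are returned unchanged (note ndarrays expose a ``.data``
    buffer attribute, so a plain ``getattr`` probe would misfire).
    """
    if isinstance(obj, np.ndarray):
        return obj
    return np.asarray(obj.data, dtype=float)
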