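"""Relative qPCR quantification (the 2^-ddCt method)."""

from __future__ import annotations

import numpy as np


def ddct_fold_change(ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
    """Fold change by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per condition; ddCt = dCt(case) -
    dCt(control); the returned fold change is 2^(-ddCt).  Accepts scalars
    or broadcastable arrays of cycle-threshold values.
    """
    args = [np.asarray(a, dtype=float) for a in
            (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)]
    if any(not np.all(np.isfinite(a)) for a in args):
        raise ValueError("all Ct values must be finite")
    dct_case = args[0] - args[1]
    dct_ctrl = args[2] - args[3]
    fold = 2.0 ** -(dct_case - dct_ctrl)
    return float(fold) if fold.ndim == 0 else fold
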