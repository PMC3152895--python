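"""Small shared numeric helpers."""

import numpy as np


def round_half_up(x):
    """Round to nearest integer with .5 always going up.

    ``np.rint`` rounds half-to-even; the quantization steps here use the
    conventional half-up rule instead so that e.g. 64.5 -> 65.
    """
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)
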