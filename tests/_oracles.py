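"""Independent reference implementations used by several test modules."""

import numpy as np

from gtenet.inference import discretize


def standard_te_oracle(y, x, k, b):
    """Dictionary-based conventional Transfer Entropy (no same-bin, no
    conditioning), independent of the package's vectorized code paths."""
    ys = discretize(np.asarray(y, float), b)
    xs = discretize(np.asarray(x, float), b)
    joint, c_sp, c_pf, c_p = {}, {}, {}, {}
    n = 0
    for t in range(k, len(ys)):
        fut = ys[t]
        past = tuple(ys[t - m] for m in range(1, k + 1))
        src = tuple(xs[t - m] for m in range(1, k + 1))
        n += 1
        joint[(src, past, fut)] = joint.get((src, past, fut), 0) + 1
        c_sp[(src, past)] = c_sp.get((src, past), 0) + 1
        c_pf[(past, fut)] = c_pf.get((past, fut), 0) + 1
        c_p[past] = c_p.get(past, 0) + 1
    te = 0.0
    for (src, past, fut), c in joint.items():
        te += c / n * np.log2(c * c_p[past] / (c_sp[(src, past)] * c_pf[(past, fut)]))
    return te
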