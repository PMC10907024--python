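"""Independent reference implementations used as test oracles."""

import numpy as np


def dense_poisson_oracle(source, target, mask, location):
    """Independent dense-solve reference for Poisson blending.

    Assembles the Dirichlet-interior Laplacian system pixel by pixel and
    solves it with numpy's dense solver; written independently of the
    production sparse path.
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    r0, c0 = location
    region = target[r0:r0 + h, c0:c0 + w]
    pix = [(r, c) for r in range(h) for c in range(w) if mask[r, c]]
    index = {p: i for i, p in enumerate(pix)}
    n = len(pix)
    A = np.zeros((n, n))
    b = np.zeros(n)
    for (r, c), i in index.items():
        A[i, i] = 4.0
        b[i] += 4.0 * source[r, c]
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            q = (r + dr, c + dc)
            b[i] -= source[q]
            if q in index:
                A[i, index[q]] = -1.0
            else:
                b[i] += region[q]
    f = np.linalg.solve(A, b)
    out = target.copy()
    for (r, c), i in index.items():
        out[r0 + r, c0 + c] = f[i]
    return out
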