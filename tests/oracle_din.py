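"""Independent hand-computation oracle for the DIN 32645 limit formulas,
kept separate from the library implementation it checks."""

import math

import numpy as np
from scipy import stats


def din_oracle(x, y, alpha=0.01, k=3.0, m=1):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    xb = x.mean()
    qx = np.sum((x - xb) ** 2)
    b = np.sum((x - xb) * (y - y.mean())) / qx
    a = y.mean() - b * xb
    syx = math.sqrt(np.sum((y - a - b * x) ** 2) / (n - 2))
    t = stats.t.ppf(1 - alpha, n - 2)
    lod = syx / b * t * math.sqrt(1 / m + 1 / n + xb ** 2 / qx)
    loq = 3 * lod
    for _ in range(400):
        loq_new = k * syx / b * t * math.sqrt(1 / m + 1 / n + (loq - xb) ** 2 / qx)
        if abs(loq_new - loq) < 1e-13:
            break
        loq = loq_new
    return lod, loq
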