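"""Independent brute-force oracles used by the test suite only.

These deliberately avoid the code paths they validate: the coherence oracle
evaluates |P_xy|^2 / (P_xx P_yy) from explicitly averaged segment
periodograms, and the Holm oracle enumerates the step-down procedure
directly.
"""

import numpy as np
from scipy.signal import get_window


def coherence_oracle(x, y, fs, nperseg, noverlap, window="hann"):
    """Direct periodogram-averaging evaluation of magnitude-squared coherence.

    Segments follow the same layout as the Welch estimator (constant detrend
    per segment, periodic window); normalization constants cancel in the
    coherence ratio.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    win = get_window(window, nperseg, fftbins=True)
    step = nperseg - noverlap
    starts = range(0, x.size - nperseg + 1, step)
    pxx = pyy = pxy = 0.0
    for s in starts:
        xs = x[s : s + nperseg]
        ys = y[s : s + nperseg]
        fx = np.fft.rfft((xs - xs.mean()) * win)
        fy = np.fft.rfft((ys - ys.mean()) * win)
        pxx = pxx + np.abs(fx) ** 2
        pyy = pyy + np.abs(fy) ** 2
        pxy = pxy + np.conj(fx) * fy
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return freqs, np.abs(pxy) ** 2 / (pxx * pyy)


def holm_oracle(pvals):
    """Step-down Holm adjustment by direct enumeration."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, j in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[j]))
        adj[j] = running
    return adj
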