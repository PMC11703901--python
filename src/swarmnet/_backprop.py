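"""Compiled inner loop for online backpropagation with momentum.

All randomness (weight init, partitioning, within-epoch sample order) happens
in the caller; this kernel is purely deterministic floating-point work, which
keeps bit-identical reproducibility trivial to reason about.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# stop codes returned by the kernel
STOP_MAX_EPOCHS = 0
STOP_PATIENCE = 1
STOP_THRESHOLD = 2
STOP_NONFINITE = 3


@njit(cache=True)
def train_backprop(Xtr, ytr, Xval, yval, W1, b1, W2, b2, lr, mom,
                   max_epochs, patience, improve_thresh, mse_target):
    """Train a sigmoid N-H-1 perceptron by per-sample backprop with momentum.

    ``Xtr`` rows must already be in the desired within-epoch presentation
    order.  Weights are updated in place; the *returned* weights are those of
    the best-validation-MSE epoch.  Early stopping: training halts when the
    best validation MSE has not improved by more than ``improve_thresh``
    within the last ``patience`` epochs; if ``mse_target`` >= 0, also as soon
    as the validation MSE falls to ``mse_target`` or below.
    """
    n_in, H = W1.shape
    ntr = Xtr.shape[0]
    nval = Xval.shape[0]

    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = 0.0

    bW1 = W1.copy()
    bb1 = b1.copy()
    bW2 = W2.copy()
    bb2 = b2

    best_val = 1.0e300
    last_signif = 0
    epochs_run = 0
    stop = STOP_MAX_EPOCHS

    h = np.empty(H)
    dj = np.empty(H)

    for epoch in range(max_epochs):
        for s in range(ntr):
            # forward pass
            z2 = b2
            for j in range(H):
                z = b1[j]
                for i in range(n_in):
                    z += Xtr[s, i] * W1[i, j]
                hj = 1.0 / (1.0 + np.exp(-z))
                h[j] = hj
                z2 += hj * W2[j]
            o = 1.0 / (1.0 + np.exp(-z2))
            d2 = (o - ytr[s]) * o * (1.0 - o)
            # hidden deltas from pre-update output weights
            for j in range(H):
                dj[j] = d2 * W2[j] * h[j] * (1.0 - h[j])
            for j in range(H):
                vW2[j] = mom * vW2[j] - lr * d2 * h[j]
                W2[j] += vW2[j]
                vb1[j] = mom * vb1[j] - lr * dj[j]
                b1[j] += vb1[j]
                for i in range(n_in):
                    vW1[i, j] = mom * vW1[i, j] - lr * dj[j] * Xtr[s, i]
                    W1[i, j] += vW1[i, j]
            vb2 = mom * vb2 - lr * d2
            b2 += vb2

        # validation MSE at current weights
        sse = 0.0
        for s in range(nval):
            z2 = b2
            for j in range(H):
                z = b1[j]
                for i in range(n_in):
                    z += Xval[s, i] * W1[i, j]
                z2 += W2[j] / (1.0 + np.exp(-z))
            o = 1.0 / (1.0 + np.exp(-z2))
            sse += (o - yval[s]) * (o - yval[s])
        val = sse / nval
        epochs_run = epoch + 1

        if not np.isfinite(val):
            stop = STOP_NONFINITE
            break
        if val < best_val:
            if best_val - val > improve_thresh:
                last_signif = epoch
            best_val = val
            bW1[:, :] = W1
            bb1[:] = b1
            bW2[:] = W2
            bb2 = b2
        if mse_target >= 0.0 and best_val <= mse_target:
            stop = STOP_THRESHOLD
            break
        if epoch - last_signif >= patience:
            stop = STOP_PATIENCE
            break

    return bW1, bb1, bW2, bb2, best_val, epochs_run, stop
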