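"""Training objectives: adversarial loss, cycle-consistency loss, and their
weighted combination.

The adversarial term for a mapping G: X->Y with discriminator D_Y is the
batch mean of log D(y) + log(1 - D(G(x))); G minimizes it while D maximizes
it.  The cycle term is the per-pixel mean absolute error of both
reconstructions, |F(G(x)) - x| and |G(F(y)) - y| (per-pixel means keep the
loss magnitude resolution independent).  Discriminator outputs are clamped
away from 0 and 1 so the logs stay finite.
"""

from __future__ import annotations

import numpy as np

LOG_CLAMP = 1e-7


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, LOG_CLAMP, 1.0 - LOG_CLAMP)


def adversarial_loss(d_real_outputs, d_fake_outputs) -> float:
    """Mean over the batch of log D(real) + log(1 - D(fake)).

    The value the generator minimizes and the discriminator maximizes; its
    maximum, 0, is approached by a perfect discriminator (D(real)->1,
    D(fake)->0).  Inputs must lie in [0,1]; exact 0/1 are clamped before the
    log.
    """
    dr = np.asarray(d_real_outputs, dtype=np.float64)
    df = np.asarray(d_fake_outputs, dtype=np.float64)
    for name, v in (("d_real_outputs", dr), ("d_fake_outputs", df)):
        if v.size == 0:
            raise ValueError(f"{name} is empty")
        if v.min() < 0 or v.max() > 1:
            raise ValueError(f"{name} contains values outside [0,1]")
    return float(np.mean(np.log(_clamp(dr))) + np.mean(np.log(1.0 - _clamp(df))))


def cycle_loss(x, f_of_g_x, y, g_of_f_y) -> float:
    """Per-pixel mean |F(G(x)) - x| plus per-pixel mean |G(F(y)) - y|."""
    x = np.asarray(x, dtype=np.float64)
    fgx = np.asarray(f_of_g_x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    gfy = np.asarray(g_of_f_y, dtype=np.float64)
    if x.shape != fgx.shape:
        raise ValueError(f"shape mismatch: x {x.shape} vs F(G(x)) {fgx.shape}")
    if y.shape != gfy.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs G(F(y)) {gfy.shape}")
    return float(np.mean(np.abs(fgx - x)) + np.mean(np.abs(gfy - y)))


def total_objective(adv_xy: float, adv_yx: float, cyc: float,
                    cycle_weight: float) -> float:
    """Combined objective: both adversarial directions plus the weighted
    cycle term, linear in each."""
    if cycle_weight < 0:
        raise ValueError("cycle_weight must be >= 0")
    return float(adv_xy + adv_yx + cycle_weight * cyc)
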